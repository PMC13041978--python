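# oxhotspot

Residue-level scoring of **oxidative vulnerability** in protein structures and
**evolution-constrained substitution design** at the resulting hotspots.

Reactive oxygen species preferentially damage methionine, cysteine, tyrosine
and tryptophan side chains, but in most proteins only one or two of those
residues actually drive the loss of function — and the chemically most
reactive residue is not necessarily the one you can safely mutate. This
package is for protein engineers who need both answers at once: *which*
oxidation-prone residues matter in their structural and functional context,
and *what* can replace them without fighting the protein's evolutionary
record.

## The model

Every residue receives an **oxidation risk index**

```
ORI = wE·E + wC·C + wK·(1 − K) + wS·S
```

- **E** — relative solvent accessibility: Shrake–Rupley SASA over the
  residue's theoretical maximum accessible area, capped at 1,
- **C** — intrinsic chemical susceptibility of the amino acid (a calibrated
  0–1 scale with Cys = 1.00 and Met = 0.95 at the top),
- **K** — the native residue's frequency in a multiple-sequence-alignment
  profile (HSSP-style); conserved positions are *penalised* via 1 − K with a
  deliberately small weight so conservation tempers but never dominates risk,
- **S** — proximity to annotated catalytic/binding residues, decaying
  linearly to zero at 10 Å.

With weights summing to 1 (default 0.30, 0.30, 0.15, 0.25) the index lies in
[0, 1]. Residues are ranked at full precision; the **upper tier** is the
prefix of the ranking ending at the first consecutive score gap ≥ δ
(default 0.15). A small upper tier marks a *dominant* hotspot system, no
qualifying gap a *distributed* one — the distinction that decides whether
single-site engineering can work.

For each hotspot, candidate substitutions are restricted to the residues
actually observed at that alignment position above a frequency threshold
(the substitution spectrum), must reduce susceptibility relative to the
native residue, and are ranked by `evo_freq × (1 − candidate_C)`. Contact
neighbours (CB–CB ≤ 8 Å by default) are reported with their own
conservation and hydrophobicity so packing constraints stay visible.

## Worked example

`examples/score_structure.py` builds a synthetic two-methionine helix
scenario — one Met exposed, weakly conserved and adjacent to an annotated
functional residue, the other buried behind a packing cage and 96 %
conserved — and prints:

```
  res aa      E      C      K      S     ORI  rank tier
    6  M  0.289   0.95   0.13  0.867  0.7189     1 upper
   24  M  0.000   0.95   0.96  0.000  0.2910     2 lower
```

Both methionines are chemically identical (C = 0.95); everything that
separates them is context. The exposed, weakly conserved, site-adjacent Met6
scores 0.7189, the buried conserved Met24 0.2910, and the 0.43 gap puts Met6
alone in the upper tier. `examples/suggest_substitutions.py` then reads
Met6's alignment column (L 54 %, F 29 %, M 13 %, V 4 %) and proposes:

```
cand   freq     C    ΔC feasibility
   L   0.54  0.05  0.90       0.513
   F   0.29  0.20  0.75       0.232
```

Leucine — frequent in the family and far less oxidisable — is the top
candidate; valine is filtered out by the 5 % spectrum threshold, and a
cysteine would have been excluded outright for not reducing susceptibility.
`examples/replay_published_values.py` shows the tier rules reproducing the
dominant-vs-distributed distinction on published per-residue values, and
`examples/end_to_end_report.py` exports the TSV/JSON report bundle.

## Command line

```sh
oxhotspot fixtures --out demo              # emit the synthetic scenario
oxhotspot run --pdb demo/structure.pdb --chain A --hssp demo/profile.hssp \
    --sites demo/sites.tsv --out demo/report
oxhotspot score ...   # risk table to stdout
oxhotspot suggest ... # substitution candidates to stdout
```

Flags mirror the library's `PipelineConfig` (weights, cutoffs, thresholds);
a `key = value` config file is supported, with flags taking precedence.

## Layout

- `src/oxhotspot/structure.py` — PDB parsing, SASA/RSA, secondary
  structure, contacts, functional-site proximity
- `src/oxhotspot/profile.py` — HSSP-style profile parsing, conservation,
  substitution spectra, sequence↔structure mapping
- `src/oxhotspot/risk.py` — the index, ranking, tier separation, pattern
  classification
- `src/oxhotspot/feasibility.py` — substitution enumeration and neighbour
  context
- `src/oxhotspot/fixtures.py` — deterministic synthetic structures,
  profiles and planted scenarios
- `src/oxhotspot/pipeline.py`, `cli.py` — orchestration, reports, CLI

See `docs/methods.md` for the full account of the model, its defaults and
its limitations.
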