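# Methods

## The risk model

Oxidative damage to a folded protein is residue-selective twice over:
chemistry picks the candidate side chains (Met, Cys, Trp, Tyr), but
structural and functional context decides which of them actually matter.
The package models per-residue oxidative vulnerability as a weighted sum of
four normalised determinants,

    ORI = wE·E + wC·C + wK·(1 − K) + wS·S ,

all in [0, 1]. The model is deliberately linear and interpretable: every
score decomposes into its four contributions, which the report tables
preserve. The assumptions worth stating explicitly:

- the four factors act additively — no interaction terms;
- conservation enters only as a *penalty* (1 − K) with the smallest default
  weight, so a conserved residue can still surface as a hotspot when
  exposure, chemistry and functional proximity all point at it, while
  conservation alone never creates one;
- solvent accessibility is a static, single-conformer quantity; transient
  exposure from breathing motions is outside the model;
- functional coupling is proxied purely by spatial proximity to annotated
  sites.

Substitution design is kept strictly separate from risk: a residue's high
susceptibility never by itself makes it a mutation target. Candidates at a
hotspot must (a) occur in the alignment column above a frequency threshold
and (b) strictly lower susceptibility; they are ranked by
`evo_freq × (1 − candidate_C)`, a product chosen because it preserves
monotonicity in both criteria without introducing tunable constants.
Candidates failing (b) are excluded rather than down-weighted — a
replacement that cannot reduce susceptibility has no claim to the list.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| weights wE, wC, wK, wS | 0.30, 0.30, 0.15, 0.25 | – | exposure and chemistry lead; conservation smallest by design; normalisable on load |
| susceptibility C | C 1.00, M 0.95, W 0.70, Y 0.60, H 0.40, F 0.20, others 0.05 | – | ordering follows relative ROS reactivity (sulfur > oxidisable aromatics); an explicit calibration, overridable via config |
| prone set | {C, M, W, Y} | – | the classically oxidation-prone side chains; reports filter to it by default |
| SASA probe / mesh | 1.4 Å / 960 points | – | water probe; deterministic golden-spiral mesh (≈0.5 % isolated-sphere error) |
| van der Waals radii | Bondi: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å | Å | hydrogens ignored by default (rare in deposited structures) |
| max-ASA reference | Tien et al. 2013 theoretical | Å² | RSA = SASA / maxASA, capped at 1 |
| contact metric / cutoff | CB–CB (CA for Gly) / 8 Å | Å | standard side-chain-proximity convention; sequence-adjacent pairs are kept — they are genuine packing neighbours |
| site decay cutoff | 10 Å, linear decay, min heavy-atom distance | Å | S = max(0, 1 − d/10); an annotated residue scores 1 for itself; no annotations ⇒ S = 0 |
| spectrum threshold | 0.05 | fraction | removes alignment noise while keeping minor observed variants |
| tier gap δ | 0.15 | ORI units | see ranking below |
| max dominant tier | 2 | residues | one or two separated hotspots count as a dominant system |
| missing-K policy | K = 1, flagged | – | an unmapped residue is treated as fully conserved, conservatively lowering its risk |
| mapping coverage floor / mismatch tolerance | 0.8 / 2 % | – | hard failure below; small discrepancies (engineered tags, point variants) tolerated and listed |

## Structural stage

SASA is computed with the Shrake–Rupley algorithm: each heavy atom is
inflated by the probe radius, sampled on a deterministic golden-spiral
lattice, and the unoccluded fraction of sample points gives the atom's
accessible area; residue SASA is the exact sum over its atoms. The mesh is
fixed, so results are bit-reproducible; tests validate against the
isolated-sphere closed form and an independent dense random-sampling
oracle. Unknown elements fall back to 1.70 Å with a warning (an error in
strict mode).

Secondary structure is an annotation only — it never enters the score — so
a light dihedral-region assignment suffices: helix for φ ∈ [−100, −30] and
ψ ∈ [−80, −5], strand for φ ∈ [−180, −45] and ψ ∈ [45, 180], with minimum
run lengths 4 (helix) and 3 (strand) smoothing isolated labels to coil, and
coil wherever a dihedral is undefined. A full hydrogen-bond-based
assignment would add a dependency surface for no scoring benefit.

Parsing reads legacy PDB text through gemmi, keeps the first model only,
drops waters and heteroatoms (a flag re-admits heteroatoms as SASA
occluders), resolves alternate locations per atom name by highest
occupancy (ties by altloc letter), and preserves author numbering —
`(chain, resnum, icode)` is the public residue identity throughout; nothing
is ever renumbered.

## Evolutionary stage

The profile reader targets the per-position percentage block of HSSP-style
files (position, chain, wild-type residue, twenty integer percentage
columns, NOCC); other sections are skipped rather than rejected, since real
files carry many blocks this method does not use. Percentages become
fractions; alignment gaps appear implicitly as column sums below 1. K is
the raw wild-type fraction — no gap renormalisation — so a heavily gapped
column reads as weakly conserved, which is the conservative direction for a
risk penalty.

Profile-to-structure mapping first tries a pure renumbering (identical
sequences, one constant offset, no insertion codes), because real
case-study inputs are usually exactly that; otherwise a global pairwise
alignment (identity scoring 1/0, gap open −2, extend −0.5, via Biopython)
supplies the mapping, of which only the aligned pairs are consumed.
Coverage is the mapped fraction of the longer of the two sequences, so
truncation on either side counts against it; below 0.8 the run fails hard
rather than silently scoring a mismatched profile.

## Ranking, tiers, patterns

Residues are sorted by ORI at full precision, ties broken by higher C and
then lower residue number. Scanning from the top, the upper tier ends at
the *first* consecutive gap ≥ δ. First-gap was chosen over global max-gap
deliberately: with a clearly separated pair on top, max-gap can jump to a
larger gap further down and absorb mid-ranked residues into the "tier",
which contradicts what a separated upper tier means. δ = 0.15 is the
calibration that cleanly separates two-hotspot from narrow-band systems on
the published value sets the tests replay. With no qualifying gap —
including the single-residue case — there is no upper tier.

One consequence worth knowing: raising δ disqualifies early gaps, so the
tier cut moves *down* the ranking (the tier grows) until no gap qualifies
and the tier vanishes. The property tests assert exactly this behaviour.

A system is *dominant* when the upper tier exists and holds at most
`max_dominant` (2) residues, *distributed* otherwise, *undefined* below two
scored residues. Narrow-band systems whose top residue leads by only a few
hundredths classify as distributed; the top-ranked residue is still
reported separately, and substitution candidates are generated for it when
no tier exists.

## The synthetic generators

The generators exist so the whole pipeline is exercisable without any
external download, and they are first-class tested code. The backbone
builder chains canonical internal coordinates (NeRF construction) at
user-chosen (φ, ψ) — scalar or per-residue — emitting N, CA, C, O, CB
atoms as byte-deterministic PDB text; requested torsions are realised to
within numerical noise. The profile generator writes percentage columns
whose wild-type entry is round(100·K) with the remainder multinomially
spread over seeded alternatives, returning the exact written fractions as a
truth table.

The planted scenario puts two methionines in one helix: the hotspot
exposed, 13 % conserved (its column fixed to the leucine-dominated spectrum
L 54 / F 29 / M 13 / V 4), one position away from an annotated functional
residue; the protected residue 96 % conserved, far from any site, and
buried behind a cage of alanines packed on a 4.8 Å sphere around it. Cage
residues continue the chain numbering and the profile covers them, so the
mapping stays a clean offset-0 bijection. The generator *verifies* that the
hotspot beats the protected residue strictly on E, K and S (C ties — both
are Met) and refuses to emit a violating scenario; with all four factors
aligned, rank 1 for the hotspot is forced for every strictly positive
weight vector, which is what makes the recovery test independent of the
default weights.

What the toys do not emulate: real side chains beyond CB, packing-quality
geometry, β-sheet topology, correlated columns or phylogenetic structure in
the profile, alignment gaps, or annotation noise. Passing the planted test
therefore demonstrates that the implementation ranks a factor-dominant
residue first — a correctness property — not that the default calibration
is optimal for real proteins.

## Numerical choices and degenerate inputs

- The sphere mesh, candidate sort (feasibility desc, then alphabetical),
  contact storage (canonical pair order) and TSV formatting (9 decimals)
  are all deterministic; two identical runs produce byte-identical output,
  and the JSON report reconstructs the in-memory report exactly.
- ORI factors are validated to [0, 1]; violations raise rather than clamp.
- Residues of unknown type ('X'), or with undefined RSA, are excluded from
  scoring with a warning; missing backbone atoms degrade secondary
  structure to coil; Gly contact metric falls back CB → CA.
- Empty annotation set ⇒ S = 0 everywhere and undefined site distances; an
  annotated identity absent from the structure is skipped with a warning.
- An empty scored set (e.g. a structure with no prone residues under the
  default filter) yields an empty table, pattern "undefined", and a normal
  exit.

Problem sizes used by the test and acceptance runs — 1000 draws for the
index property sweep, a 20 000-point oracle mesh for SASA, twenty 50-residue
configurations for the contact oracle, 100 weight draws for planted
recovery — were chosen as the smallest sizes at which the checked
properties are stable, and run in seconds.

## Known limitations

- Legacy PDB input only; no mmCIF, no hydrogens, no multi-model averaging,
  occupancy-weighted ensembles, or inter-chain annotation transfer.
- The susceptibility scale is an explicit calibration, not a fitted or
  measured quantity; absolute ORI values are therefore comparable within a
  configuration, not across different scales or weight choices.
- Feasibility ranks single-site substitutions only; it does not predict
  ΔΔG, repack side chains, or optimise multi-site combinations (for
  distributed systems it reports the classification and per-residue
  candidates, leaving coordination to the engineer).
- K uses the raw alignment fraction; positions dominated by gaps read as
  unconserved.
- Secondary-structure labels are coarse 3-state annotations and should not
  be consumed as DSSP equivalents.
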