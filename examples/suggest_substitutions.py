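"""Propose evolution-constrained substitutions at a hotspot.

The hotspot's alignment column (L 54%, F 29%, M 13%, V 4%) bounds the
search space; candidates must also lower chemical susceptibility
relative to methionine, and are ranked by evo_freq × (1 − candidate C).
The local contact environment is reported alongside.
"""

from oxhotspot import (
    compute_contacts,
    compute_features,
    enumerate_candidates,
    generate_planted_scenario,
    map_profile_to_structure,
    neighbor_context,
    parse_hssp,
    parse_structure,
    rank_and_tier,
    score_all,
)

scenario = generate_planted_scenario()
residues = parse_structure(scenario.structure_text, "A")
features = compute_features(residues, {("A", p, "") for p in scenario.spec.annotated_sites})
profile = parse_hssp(scenario.profile_text)
mapping = map_profile_to_structure(profile, residues)
ranked = rank_and_tier(score_all(features, profile, mapping))
hotspot = ranked[0]

pos = profile.by_seq_pos(mapping.inverse()[hotspot.residue])
print(f"hotspot: {hotspot.aa}{hotspot.residue[1]} (ORI {hotspot.ori:.3f})")
print(f"{'cand':>4} {'freq':>6} {'C':>5} {'ΔC':>5} {'feasibility':>11}")
for c in enumerate_candidates(hotspot, pos, min_freq=0.05):
    print(f"{c.candidate_aa:>4} {c.evo_freq:6.2f} {c.candidate_C:5.2f} "
          f"{c.delta_C:5.2f} {c.feasibility:11.3f}")

contacts = compute_contacts(residues, cutoff=8.0, metric="CB")
ctx = neighbor_context(hotspot, contacts, profile, mapping, residues)
print(f"\ncontact neighbours within 8 Å: {len(ctx.neighbors)} "
      f"(hydrophobic fraction {ctx.fraction_hydrophobic:.2f})")
for n in ctx.neighbors:
    print(f"  {n.aa}{n.residue[1]:<4} at {n.distance:4.1f} Å, K="
          f"{'?' if n.wt_freq is None else f'{n.wt_freq:.2f}'}, "
          f"{'hydrophobic' if n.hydrophobic else 'polar/charged'}")

print()
print("Leucine wins: highest observed frequency and a large susceptibility drop.")
print("Cysteine-like candidates (C ≥ native) would be excluded outright.")
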