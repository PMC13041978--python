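"""Evolution-constrained substitution design at oxidation hotspots.

Once a hotspot is identified, candidate replacements are drawn only
from the substitution spectrum — the residues actually observed at
that alignment position above a frequency threshold — and must lower
the intrinsic chemical susceptibility relative to the native residue.
Candidates are ranked by ``evo_freq × (1 − candidate_C)``: a product
keeps the score monotone in both evolutionary support and
susceptibility reduction without extra constants.

The local structural context of each hotspot (its contact partners,
their conservation, spectra and hydrophobicity) is reported alongside
so that packing constraints around a proposed substitution are visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .errors import OxhotspotError
from .profile import (
    EvolutionaryProfile,
    ProfilePosition,
    SeqStructMapping,
    substitution_spectrum,
    wt_frequency,
)
from .risk import DEFAULT_SCALE, ResidueRisk, SusceptibilityScale, lookup_susceptibility
from .structure import ContactMap, ResidueId, ResidueRecord

logger = logging.getLogger(__name__)

#: side chains counted as hydrophobic in context reports (never scored)
HYDROPHOBIC = frozenset("AVLIMFWP")


@dataclass
class SubstitutionCandidate:
    """One evolutionarily observed, susceptibility-reducing replacement."""

    residue: ResidueId
    native_aa: str
    candidate_aa: str
    evo_freq: float
    candidate_C: float
    delta_C: float  # native C − candidate C; > 0 by construction
    feasibility: float
    rank: int | None = None


@dataclass
class NeighborInfo:
    residue: ResidueId
    aa: str
    distance: float  # Å, from the contact map
    wt_freq: float | None  # K of the neighbour; None when unmapped
    spectrum: list[tuple[str, float]]
    hydrophobic: bool


@dataclass
class NeighborContext:
    """Contact partners of a hotspot with their evolutionary summaries."""

    hotspot: ResidueId
    neighbors: list[NeighborInfo] = field(default_factory=list)

    @property
    def fraction_hydrophobic(self) -> float | None:
        if not self.neighbors:
            return None
        return sum(n.hydrophobic for n in self.neighbors) / len(self.neighbors)


def feasibility_score(candidate: SubstitutionCandidate) -> float:
    """``evo_freq × (1 − candidate_C)``: in [0, 1], monotone in both terms."""
    return candidate.evo_freq * (1.0 - candidate.candidate_C)


def enumerate_candidates(
    hotspot: ResidueRisk,
    position: ProfilePosition | None,
    min_freq: float = 0.05,
    scale: SusceptibilityScale = DEFAULT_SCALE,
) -> list[SubstitutionCandidate]:
    """Substitutions for one hotspot, ordered by decreasing feasibility.

    Candidates are the spectrum members at ``min_freq`` minus the native
    residue, keeping only those with strictly lower susceptibility than
    the native. Ties in feasibility break alphabetically, so the
    ordering is independent of input order.
    """
    if position is None:
        raise OxhotspotError(
            f"hotspot {hotspot.residue} has no mapped profile position; "
            "consult the mapping report"
        )
    native_c = lookup_susceptibility(hotspot.aa, scale)
    out: list[SubstitutionCandidate] = []
    for aa, freq in substitution_spectrum(position, min_freq):
        if aa == hotspot.aa:
            continue
        cand_c = lookup_susceptibility(aa, scale)
        if cand_c >= native_c:
            continue
        cand = SubstitutionCandidate(
            residue=hotspot.residue,
            native_aa=hotspot.aa,
            candidate_aa=aa,
            evo_freq=freq,
            candidate_C=cand_c,
            delta_C=native_c - cand_c,
            feasibility=0.0,
        )
        cand.feasibility = feasibility_score(cand)
        out.append(cand)
    out.sort(key=lambda c: (-c.feasibility, c.candidate_aa))
    for i, c in enumerate(out, start=1):
        c.rank = i
    return out


def neighbor_context(
    hotspot: ResidueRisk,
    contacts: ContactMap,
    profile: EvolutionaryProfile,
    mapping: SeqStructMapping,
    residues: Sequence[ResidueRecord],
    min_freq: float = 0.05,
) -> NeighborContext:
    """Describe the structural neighbourhood of a hotspot.

    One entry per contact partner: distance, the partner's conservation
    K (None when it has no mapped profile position), its substitution
    spectrum at ``min_freq``, and whether its side chain is hydrophobic.
    """
    by_id = {r.id: r for r in residues}
    inv = mapping.inverse()
    by_pos = {p.seq_pos: p for p in profile.positions}
    entries = contacts.neighbors(hotspot.residue)
    if not entries:
        logger.warning("hotspot %s has no contacts under the cutoff", hotspot.residue)
    ctx = NeighborContext(hotspot.residue)
    for rid, dist in entries:
        res = by_id.get(rid)
        aa = res.aa1 if res is not None else "X"
        seq_pos = inv.get(rid)
        pos = by_pos.get(seq_pos) if seq_pos is not None else None
        k = wt_frequency(pos) if pos is not None else None
        spectrum = substitution_spectrum(pos, min_freq) if pos is not None else []
        ctx.neighbors.append(
            NeighborInfo(rid, aa, dist, k, spectrum, aa in HYDROPHOBIC)
        )
    return ctx
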