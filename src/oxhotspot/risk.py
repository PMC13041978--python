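"""The oxidation risk index (ORI) and hotspot ranking.

Each residue is scored as a weighted sum of four normalised factors:

    ORI = wE·E + wC·C + wK·(1−K) + wS·S

where E is relative solvent accessibility, C the intrinsic chemical
susceptibility of the amino acid to reactive oxygen species, K the
evolutionary frequency of the native residue (conserved positions are
penalised via 1−K), and S the proximity to annotated functional sites.
With weights summing to 1 the index lies in [0, 1]; 0 means low and 1
high oxidative vulnerability.

Ranking by ORI is followed by a tier split: the upper tier is the
prefix of the ranking that ends at the first consecutive score gap of
at least ``gap_delta``. A small upper tier (≤ ``max_dominant``) marks a
dominant-hotspot protein; otherwise vulnerability is distributed over
several comparable residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import OxhotspotError
from .profile import EvolutionaryProfile, SeqStructMapping, wt_frequency
from .structure import STANDARD_AA, ResidueId, StructuralFeatures

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SusceptibilityScale:
    """Intrinsic chemical susceptibility C per amino acid, in [0, 1].

    The default ordering follows relative ROS reactivity — sulfur-
    containing residues highest, then the oxidisable aromatics — and is
    an explicit calibration, overridable via configuration. The
    ``prone_set`` defines which residues count as oxidation-prone for
    reporting; every prone residue must score strictly above every
    non-prone one.
    """

    table: Mapping[str, float] = field(
        default_factory=lambda: {
            "C": 1.00, "M": 0.95, "W": 0.70, "Y": 0.60, "H": 0.40, "F": 0.20,
        }
    )
    prone_set: frozenset[str] = frozenset("CMWY")
    baseline: float = 0.05

    def __post_init__(self) -> None:
        vals = dict(self.table)
        for aa, v in vals.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"susceptibility for {aa} outside [0, 1]")
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline susceptibility outside [0, 1]")
        prone_min = min(vals.get(aa, self.baseline) for aa in self.prone_set)
        other_max = max(
            (vals.get(aa, self.baseline) for aa in STANDARD_AA - self.prone_set),
            default=0.0,
        )
        if prone_min <= other_max:
            raise ValueError(
                "every prone-set susceptibility must strictly exceed every "
                "non-prone value"
            )

    def value(self, aa1: str) -> float:
        return self.table.get(aa1, self.baseline)


DEFAULT_SCALE = SusceptibilityScale()


@dataclass(frozen=True)
class RiskWeights:
    """The four ORI coefficients; non-negative with positive sum."""

    wE: float = 0.30
    wC: float = 0.30
    wK: float = 0.15
    wS: float = 0.25

    def __post_init__(self) -> None:
        t = self.as_tuple()
        if any(w < 0 for w in t):
            raise ValueError("weights must be non-negative")
        if sum(t) <= 0:
            raise ValueError("weights must have positive sum")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.wE, self.wC, self.wK, self.wS)

    @property
    def is_normalized(self) -> bool:
        return math.isclose(sum(self.as_tuple()), 1.0, abs_tol=1e-9)

    def normalized(self) -> "RiskWeights":
        s = sum(self.as_tuple())
        return RiskWeights(self.wE / s, self.wC / s, self.wK / s, self.wS / s)


DEFAULT_WEIGHTS = RiskWeights()


@dataclass
class ResidueRisk:
    """Scored residue: the four factors, the index, and its place in the ranking."""

    residue: ResidueId
    aa: str
    E: float
    C: float
    K: float
    S: float
    ori: float
    rank: int | None = None
    tier: str | None = None  # "upper" / "lower" once tiered; None before/untiered
    k_missing: bool = False  # True when no profile position mapped here


def lookup_susceptibility(aa1: str, scale: SusceptibilityScale = DEFAULT_SCALE) -> float:
    """C for one residue type; non-tabulated standard residues get the baseline."""
    if aa1 not in STANDARD_AA:
        raise OxhotspotError(f"unknown residue {aa1!r}: susceptibility undefined")
    return scale.value(aa1)


def oxidation_risk_index(
    E: float, C: float, K: float, S: float, weights: RiskWeights = DEFAULT_WEIGHTS
) -> float:
    """Weighted combination of the four normalised factors."""
    for name, v in (("E", E), ("C", C), ("K", K), ("S", S)):
        if not 0.0 <= v <= 1.0:
            raise OxhotspotError(f"factor {name}={v} outside [0, 1]")
    return weights.wE * E + weights.wC * C + weights.wK * (1.0 - K) + weights.wS * S


def score_all(
    features: Mapping[ResidueId, StructuralFeatures],
    profile: EvolutionaryProfile,
    mapping: SeqStructMapping,
    scale: SusceptibilityScale = DEFAULT_SCALE,
    weights: RiskWeights = DEFAULT_WEIGHTS,
    prone_only: bool = True,
    missing_k_value: float = 1.0,
) -> list[ResidueRisk]:
    """Score every (by default oxidation-prone) residue of the structure.

    Residues with no mapped profile position receive ``missing_k_value``
    (default 1: treated as fully conserved, conservatively lowering
    their risk) and are flagged. Residues of unknown type or undefined
    RSA are skipped with a warning.
    """
    inv = mapping.inverse()
    by_pos = {p.seq_pos: p for p in profile.positions}
    out: list[ResidueRisk] = []
    for rid, feat in features.items():
        if feat.aa1 not in STANDARD_AA:
            logger.warning("residue %s has unknown type; excluded from scoring", rid)
            continue
        if prone_only and feat.aa1 not in scale.prone_set:
            continue
        if feat.rsa is None:
            logger.warning("residue %s has undefined RSA; excluded from scoring", rid)
            continue
        k_missing = False
        seq_pos = inv.get(rid)
        if seq_pos is None or seq_pos not in by_pos:
            k = missing_k_value
            k_missing = True
            logger.warning("residue %s has no mapped profile position; K=%.2f", rid, k)
        else:
            k = wt_frequency(by_pos[seq_pos], feat.aa1)
        c = lookup_susceptibility(feat.aa1, scale)
        ori = oxidation_risk_index(feat.rsa, c, k, feat.site_score, weights)
        out.append(ResidueRisk(rid, feat.aa1, feat.rsa, c, k, feat.site_score, ori,
                               k_missing=k_missing))
    return out


def risk_from_value(
    resnum: int,
    aa: str,
    ori: float,
    chain: str = "A",
    scale: SusceptibilityScale = DEFAULT_SCALE,
) -> ResidueRisk:
    """Wrap an externally computed index value for ranking/classification.

    Useful for replaying published per-residue scores through the tier
    and pattern rules. Only the index, the susceptibility tie-breaker C
    and the residue identity participate in ranking; the unknown
    factors are stored as zeros and are not meaningful.
    """
    return ResidueRisk(
        residue=(chain, resnum, ""),
        aa=aa,
        E=0.0,
        C=lookup_susceptibility(aa, scale),
        K=0.0,
        S=0.0,
        ori=float(ori),
    )


def _sort_key(r: ResidueRisk):
    # ORI desc, then susceptibility desc, then author numbering asc
    return (-r.ori, -r.C, r.residue[0], r.residue[1], r.residue[2])


def rank_and_tier(
    risks: Sequence[ResidueRisk], gap_delta: float = 0.15
) -> list[ResidueRisk]:
    """Sort by ORI (full precision) and mark the separated upper tier.

    Ties break by higher susceptibility C, then lower residue number.
    Scanning from the top, the upper tier ends at the first consecutive
    ORI gap >= ``gap_delta``; if no gap qualifies (including the single-
    residue case) no upper tier exists and all tiers are None.
    """
    if not risks:
        raise OxhotspotError("rank_and_tier requires at least one scored residue")
    ranked = [replace(r) for r in sorted(risks, key=_sort_key)]
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    cut = None
    for i in range(len(ranked) - 1):
        if ranked[i].ori - ranked[i + 1].ori >= gap_delta:
            cut = i
            break
    for i, r in enumerate(ranked):
        r.tier = None if cut is None else ("upper" if i <= cut else "lower")
    return ranked


def upper_tier(ranked: Sequence[ResidueRisk]) -> list[ResidueRisk]:
    return [r for r in ranked if r.tier == "upper"]


def classify_pattern(
    risks: Sequence[ResidueRisk],
    gap_delta: float = 0.15,
    max_dominant: int = 2,
) -> str:
    """Label the vulnerability pattern of the protein.

    ``dominant`` when a separated upper tier exists and holds at most
    ``max_dominant`` residues (one or two clearly separated hotspots);
    ``distributed`` when risk spreads over several comparable residues;
    ``undefined`` with fewer than two scored residues.
    """
    if len(risks) < 2:
        logger.warning("fewer than 2 scored residues: pattern undefined")
        return "undefined"
    ranked = rank_and_tier(risks, gap_delta)
    tier = upper_tier(ranked)
    if tier and len(tier) <= max_dominant:
        return "dominant"
    return "distributed"
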