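"""Deterministic synthetic inputs for the whole pipeline.

Three generators mirror the three input kinds the tool consumes:

* ``generate_backbone`` / ``generate_helix_structure`` — poly-peptide
  backbones (N, CA, C, O, CB) built from internal coordinates at chosen
  (φ, ψ), written as legacy PDB text; byte-identical for equal inputs.
* ``generate_synthetic_profile`` — an HSSP-style percentage block whose
  wild-type column equals a per-position conservation target, with the
  remaining mass spread over a seeded draw of alternatives; the exact
  fractions are returned as a truth table for round-trip tests.
* ``generate_planted_scenario`` — a structure/profile/annotation triple
  in which one oxidation-prone residue (exposed, weakly conserved,
  beside an annotated site) dominates a second one (buried behind a
  cage of alanines, strongly conserved, far from any site) on every
  risk factor, so it outranks the protected residue for any strictly
  positive weight vector. The generator verifies this dominance and
  refuses to emit a scenario that violates it.

These are geometric toys, not physically realistic proteins: side
chains stop at CB and the burial cage is a scaffold, not a fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ScenarioError
from .structure import (
    AA1_TO_3,
    STANDARD_AA,
    compute_rsa,
    compute_sasa,
    functional_site_score,
    parse_structure,
    sphere_points,
)
from .profile import HSSP_AA_ORDER

# backbone internal coordinates (Engh–Huber-like canonical values)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd|=bond, angle(b,c,d)=angle, dihedral(a,b,c,d)=torsion."""
    ang, tor = math.radians(angle_deg), -math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _per_residue(value, n: int) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    vals = [float(v) for v in value]
    if len(vals) != n:
        raise ValueError("per-residue torsion list must match sequence length")
    return vals


def build_backbone_coords(
    sequence: str,
    phi: float | list[float],
    psi: float | list[float],
    omega: float = 180.0,
) -> list[dict[str, np.ndarray]]:
    """Atom coordinates (N, CA, C, O, and CB except Gly) per residue.

    ``phi`` and ``psi`` may be scalars (a uniform backbone) or
    per-residue sequences.
    """
    if len(sequence) < 4:
        raise ValueError("sequence must have at least 4 residues")
    for aa in sequence:
        if aa not in STANDARD_AA:
            raise ValueError(f"invalid one-letter code {aa!r}")
    phis = _per_residue(phi, len(sequence))
    psis = _per_residue(psi, len(sequence))

    coords: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    c = _nerf(np.array([0.0, 1.0, 0.0]), n, ca, _B_CA_C, _A_N_CA_C, 0.0)
    coords.append({"N": n, "CA": ca, "C": c})
    for i in range(1, len(sequence)):
        prev = coords[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        ca = _nerf(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, omega)
        c = _nerf(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phis[i])
        coords.append({"N": n, "CA": ca, "C": c})
    for i, (res, aa) in enumerate(zip(coords, sequence)):
        # carbonyl O anti to the next amide N; CB by tetrahedral branch
        res["O"] = _nerf(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psis[i] + 180.0)
        if aa != "G":
            res["CB"] = _nerf(res["C"], res["N"], res["CA"], _B_CA_CB, 110.5, 122.5)
    return coords


_ATOM_ORDER = ("N", "CA", "C", "O", "CB")


def _format_pdb(
    residues: list[tuple[int, str, dict[str, np.ndarray]]], chain: str = "A"
) -> str:
    """Fixed-column ATOM records; deterministic formatting."""
    lines = []
    serial = 1
    for resnum, aa1, atoms in residues:
        aa3 = AA1_TO_3[aa1]
        for name in _ATOM_ORDER:
            if name not in atoms:
                continue
            x, y, z = atoms[name]
            elem = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {aa3:>3s} {chain:1s}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {elem:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_backbone(
    sequence: str,
    phi: float,
    psi: float,
    chain: str = "A",
    resnum_start: int = 1,
) -> str:
    """PDB text for a uniform-(φ, ψ) backbone of the given sequence."""
    coords = build_backbone_coords(sequence, phi, psi)
    residues = [
        (resnum_start + i, aa, atoms)
        for i, (aa, atoms) in enumerate(zip(sequence, coords))
    ]
    return _format_pdb(residues, chain)


def generate_helix_structure(
    sequence: str, chain: str = "A", resnum_start: int = 1
) -> str:
    """Ideal α-helix (φ=−57°, ψ=−47°; ~1.5 Å rise, ~100°/residue)."""
    return generate_backbone(sequence, *HELIX_PHI_PSI, chain, resnum_start)


# ---------------------------------------------------------------------------
# synthetic profiles

def generate_synthetic_profile(
    sequence: str,
    conservation: list[float],
    seed: int = 0,
    overrides: dict[int, dict[str, int]] | None = None,
    chain: str = "A",
) -> tuple[str, list[dict[str, float]]]:
    """HSSP-style percentage block plus its exact truth table.

    The wild-type percentage at position *i* is ``round(100·K_i)``; the
    remainder is split over 1–4 seeded alternative residues via a
    multinomial draw. ``overrides`` (1-based position → full percentage
    column) pins designated columns exactly. Returns the file text and
    the true fractions actually written.
    """
    if len(conservation) != len(sequence):
        raise ValueError("conservation must give one K target per position")
    overrides = overrides or {}
    rng = np.random.default_rng(seed)
    rows: list[str] = []
    truth: list[dict[str, float]] = []
    for i, (aa, k) in enumerate(zip(sequence, conservation), start=1):
        if not 0.0 <= k <= 1.0:
            raise ValueError("conservation targets must lie in [0, 1]")
        if i in overrides:
            col = dict(overrides[i])
            if sum(col.values()) > 100:
                raise ValueError(f"override at position {i} exceeds 100%")
        else:
            wt_pct = round(100 * k)
            col = {aa: wt_pct}
            rem = 100 - wt_pct
            if rem > 0:
                others = sorted(STANDARD_AA - {aa})
                n_alt = int(rng.integers(1, 5))
                alts = rng.choice(others, size=n_alt, replace=False)
                counts = rng.multinomial(rem, rng.dirichlet(np.ones(n_alt)))
                for alt, cnt in zip(alts, counts):
                    if cnt > 0:
                        col[str(alt)] = int(cnt)
        nocc = int(rng.integers(100, 1000))
        cells = "".join(f"{col.get(a, 0):4d}" for a in HSSP_AA_ORDER)
        rows.append(f"{i:6d} {chain:>5s} {aa:>3s}{cells}{nocc:6d}")
        truth.append({a: p / 100.0 for a, p in sorted(col.items()) if p > 0})
    header = (
        " SeqNo Chain  AA"
        + "".join(f"{a:>4s}" for a in HSSP_AA_ORDER)
        + "  NOCC"
    )
    text = (
        "SYNTHETIC HSSP-STYLE PROFILE\n"
        "## SEQUENCE PROFILE AND ENTROPY\n"
        + header + "\n"
        + "\n".join(rows) + "\n"
        "//\n"
    )
    return text, truth


# ---------------------------------------------------------------------------
# planted scenario

_DEFAULT_SEQUENCE = "AELKAMDALKAEALKAEALKAGAMALKAEA"  # M at 6 and 24, D at 7
_HOTSPOT_SPECTRUM = {"M": 13, "L": 54, "F": 29, "V": 4}
_PROTECTED_SPECTRUM = {"M": 96, "L": 4}


@dataclass
class ScenarioSpec:
    """Declarative description of the planted two-methionine scenario."""

    sequence: str = _DEFAULT_SEQUENCE
    planted_hotspot: int = 6  # 1-based position; exposed, weakly conserved
    planted_protected: int = 24  # buried behind the cage, strongly conserved
    annotated_sites: tuple[int, ...] = (7,)
    conservation: dict[int, float] = field(
        default_factory=lambda: {6: 0.13, 7: 0.95, 24: 0.96}
    )
    default_conservation: float = 0.70
    cage_size: int = 26  # alanines packed around the protected residue
    cage_radius: float = 4.8  # Å from the protected-residue centroid
    seed: int = 0
    chain: str = "A"

    def __post_init__(self) -> None:
        for pos in (self.planted_hotspot, self.planted_protected):
            if not 1 <= pos <= len(self.sequence):
                raise ValueError("planted positions must index the sequence")
            if self.sequence[pos - 1] not in "CMWY":
                raise ValueError("planted positions must carry oxidation-prone residues")


@dataclass
class PlantedScenario:
    spec: ScenarioSpec
    structure_text: str
    profile_text: str
    annotations_text: str
    profile_truth: list[dict[str, float]]
    hotspot: tuple[str, int, str]
    protected: tuple[str, int, str]
    expected_ranking: list[tuple[str, int, str]]
    expected_top_candidate: str


def generate_planted_scenario(spec: ScenarioSpec | None = None) -> PlantedScenario:
    """Emit the planted scenario and verify its factor-wise dominance.

    The hotspot must beat the protected residue strictly on exposure E,
    conservation penalty (lower K) and site proximity S, and at least
    tie on susceptibility C; that forces a higher risk index under any
    strictly positive weights, independent of their exact values.
    """
    spec = spec or ScenarioSpec()
    seq = spec.sequence
    chain = spec.chain
    hot_i, prot_i = spec.planted_hotspot, spec.planted_protected

    coords = build_backbone_coords(seq, *HELIX_PHI_PSI)
    residues = [(i + 1, aa, atoms) for i, (aa, atoms) in enumerate(zip(seq, coords))]

    # burial cage: alanines on a sphere around the protected residue, with
    # contiguous numbering so the profile covers them (offset-0 mapping)
    prot_atoms = coords[prot_i - 1]
    center = np.mean(list(prot_atoms.values()), axis=0)
    template = {
        "N": np.array([-1.46, 0.0, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.75, 1.3, 0.0]),
        "O": np.array([1.95, 1.35, 0.0]),
        "CB": np.array([0.6, -1.0, 1.0]),
    }
    cage_seq = "A" * spec.cage_size
    for j, unit in enumerate(sphere_points(spec.cage_size)):
        ca_pos = center + spec.cage_radius * unit
        atoms = {name: ca_pos + off for name, off in template.items()}
        residues.append((len(seq) + j + 1, "A", atoms))

    structure_text = _format_pdb(residues, chain)

    full_seq = seq + cage_seq
    conservation = [
        spec.conservation.get(i + 1, spec.default_conservation)
        for i in range(len(seq))
    ] + [0.90] * spec.cage_size
    overrides = {hot_i: dict(_HOTSPOT_SPECTRUM), prot_i: dict(_PROTECTED_SPECTRUM)}
    profile_text, truth = generate_synthetic_profile(
        full_seq, conservation, seed=spec.seed, overrides=overrides, chain=chain
    )

    annotations_text = "chain\tresnum\ticode\tlabel\n" + "".join(
        f"{chain}\t{pos}\t\tfunctional\n" for pos in spec.annotated_sites
    )

    hotspot_id = (chain, hot_i, "")
    protected_id = (chain, prot_i, "")

    _verify_dominance(spec, structure_text, truth, hotspot_id, protected_id)

    return PlantedScenario(
        spec=spec,
        structure_text=structure_text,
        profile_text=profile_text,
        annotations_text=annotations_text,
        profile_truth=truth,
        hotspot=hotspot_id,
        protected=protected_id,
        expected_ranking=[hotspot_id, protected_id],
        expected_top_candidate=max(
            (aa for aa in _HOTSPOT_SPECTRUM if aa != seq[hot_i - 1]),
            key=lambda aa: _HOTSPOT_SPECTRUM[aa],
        ),
    )


def _verify_dominance(spec, structure_text, truth, hotspot_id, protected_id) -> None:
    parsed = parse_structure(structure_text, spec.chain)
    by_id = {r.id: r for r in parsed}
    sasa = compute_sasa(parsed)
    e = {
        rid: compute_rsa(sasa.per_residue[rid], by_id[rid].aa1)
        for rid in (hotspot_id, protected_id)
    }
    sites = {(spec.chain, p, "") for p in spec.annotated_sites}
    s = {
        rid: functional_site_score(by_id[rid], sites, parsed)[1]
        for rid in (hotspot_id, protected_id)
    }
    k_hot = truth[spec.planted_hotspot - 1].get(spec.sequence[spec.planted_hotspot - 1], 0.0)
    k_prot = truth[spec.planted_protected - 1].get(spec.sequence[spec.planted_protected - 1], 0.0)
    checks = {
        "E (exposure)": e[hotspot_id] > e[protected_id],
        "K (conservation)": k_hot < k_prot,
        "S (site proximity)": s[hotspot_id] > s[protected_id],
    }
    failed = [name for name, ok in checks.items() if not ok]
    if failed:
        raise ScenarioError(
            "planted scenario violates dominance on: " + ", ".join(failed)
        )
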