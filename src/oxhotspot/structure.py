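"""Structural determinants of residue-level oxidation risk.

This module turns a legacy-PDB coordinate file into the per-residue
quantities the risk model consumes:

* solvent-accessible surface area (Shrake–Rupley) and relative solvent
  accessibility (RSA, the exposure factor E),
* a 3-state secondary-structure label from backbone dihedrals
  (annotation only — it never enters the risk score),
* a residue contact map under a configurable metric and cutoff,
* proximity to annotated functional (catalytic/binding) residues,
  converted to the site-context factor S by a linear decay.

Residues are identified everywhere by their author-assigned
``(chain_id, resnum, icode)`` triple; no renumbering is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import ChainNotFoundError, StructureParseError

logger = logging.getLogger(__name__)

#: (chain_id, author residue number, insertion code or "")
ResidueId = tuple[str, int, str]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = frozenset(AA3_TO_1.values())

# Bondi van der Waals radii, Å. Hydrogens are ignored by default because
# most deposited structures lack them.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
FALLBACK_RADIUS = 1.70

# Theoretical maximum accessible surface areas, Å² (Tien et al. 2013),
# used to normalise SASA into RSA. Configurable at call sites.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class AtomRecord:
    """One atom after alternate-location resolution."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class ResidueRecord:
    """One polymer residue of the selected chain, in file order."""

    chain_id: str
    resnum: int
    icode: str
    aa3: str
    aa1: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def id(self) -> ResidueId:
        return (self.chain_id, self.resnum, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.position

    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for a in self.atoms if a.element != "H"]
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass
class StructuralFeatures:
    """Per-residue structural inputs to the risk score."""

    residue_id: ResidueId
    aa1: str
    sasa: float
    rsa: float | None  # E; None when the residue identity is unknown ('X')
    ss: str  # one of H, E, C
    site_distance: float | None  # Å; None when no annotations were given
    site_score: float  # S in [0, 1]


class ContactMap:
    """Symmetric set of residue pairs within a distance cutoff."""

    def __init__(self, cutoff: float, metric: str):
        self.cutoff = float(cutoff)
        self.metric = metric
        self._dist: dict[tuple[ResidueId, ResidueId], float] = {}
        self._adj: dict[ResidueId, dict[ResidueId, float]] = {}

    def add(self, a: ResidueId, b: ResidueId, distance: float) -> None:
        if a == b:
            raise ValueError("self-contacts are not stored")
        key = (a, b) if a <= b else (b, a)
        self._dist[key] = float(distance)
        self._adj.setdefault(a, {})[b] = float(distance)
        self._adj.setdefault(b, {})[a] = float(distance)

    def __len__(self) -> int:
        return len(self._dist)

    def __contains__(self, pair: tuple[ResidueId, ResidueId]) -> bool:
        a, b = pair
        key = (a, b) if a <= b else (b, a)
        return key in self._dist

    def distance(self, a: ResidueId, b: ResidueId) -> float:
        key = (a, b) if a <= b else (b, a)
        return self._dist[key]

    def pairs(self) -> set[tuple[ResidueId, ResidueId]]:
        """Unordered pairs, each reported once in canonical order."""
        return set(self._dist)

    def neighbors(self, rid: ResidueId) -> list[tuple[ResidueId, float]]:
        """Contact partners of ``rid`` sorted by increasing distance."""
        items = self._adj.get(rid, {})
        return sorted(items.items(), key=lambda kv: (kv[1], kv[0]))


# ---------------------------------------------------------------------------
# parsing

def parse_structure(
    coordinate_text: str,
    chain: str,
    *,
    include_het: bool = False,
) -> list[ResidueRecord]:
    """Read the polymer residues of one chain from legacy PDB text.

    Only the first model of a multi-model file is used. Heteroatom
    groups and waters are excluded unless ``include_het`` is set.
    Alternate locations are resolved per atom name by keeping the
    highest-occupancy copy (ties broken by altloc letter order).
    """
    try:
        st = gemmi.read_pdb_string(coordinate_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports line context itself
        raise StructureParseError(f"cannot parse coordinate text: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError("no models in coordinate text")
    if len(st) > 1:
        logger.warning("multi-model file: using first model only (%d models)", len(st))
    model = st[0]

    available = [ch.name for ch in model]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ChainNotFoundError(chain, available)

    residues: list[ResidueRecord] = []
    seen: set[ResidueId] = set()
    for res in target:
        if res.is_water():
            continue
        if not include_het and res.het_flag != "A":
            continue
        icode = res.seqid.icode.strip()
        rid = (chain, res.seqid.num, icode)
        if rid in seen:
            logger.warning("duplicate residue identity %s: keeping first occurrence", rid)
            continue
        seen.add(rid)
        aa3 = res.name
        aa1 = AA3_TO_1.get(aa3, "X")
        # altloc resolution: per atom name keep max occupancy, tie by letter
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            prev = best.get(atom.name)
            alt = atom.altloc if atom.altloc not in ("\x00", " ") else ""
            if prev is None:
                best[atom.name] = atom
                continue
            prev_alt = prev.altloc if prev.altloc not in ("\x00", " ") else ""
            if (atom.occ, _alt_rank(alt)) > (prev.occ, _alt_rank(prev_alt)):
                best[atom.name] = atom
        atoms = []
        for atom in res:  # preserve file order of the kept atoms
            if best.get(atom.name) is not atom:
                continue
            alt = atom.altloc if atom.altloc not in ("\x00", " ") else ""
            atoms.append(
                AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    altloc=alt,
                )
            )
        residues.append(ResidueRecord(chain, res.seqid.num, icode, aa3, aa1, atoms))
    if not residues:
        raise StructureParseError(f"chain {chain!r} contains no polymer residues")
    return residues


def _alt_rank(alt: str) -> float:
    # blank altloc outranks lettered ones at equal occupancy; among letters,
    # earlier in the alphabet wins (rank is compared with max())
    return math.inf if alt == "" else -ord(alt)


def sequence_of(residues: Sequence[ResidueRecord]) -> str:
    return "".join(r.aa1 for r in residues)


# ---------------------------------------------------------------------------
# SASA

@dataclass
class SasaResult:
    probe: float
    n_points: int
    per_atom: dict[ResidueId, dict[str, float]]
    per_residue: dict[ResidueId, float]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere mesh (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(
    residues: Sequence[ResidueRecord],
    probe: float = 1.4,
    n_points: int = 960,
    *,
    include_hydrogens: bool = False,
    fallback_radius: float = FALLBACK_RADIUS,
    strict: bool = False,
    extra_occluders: Sequence[ResidueRecord] = (),
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area, Å².

    Each atom is inflated by the probe radius and sampled on an
    ``n_points`` deterministic mesh; the exposed fraction times the
    inflated-sphere area is the atom's SASA. Per-residue SASA is the sum
    over its atoms. ``extra_occluders`` contribute occlusion but receive
    no area of their own (e.g. another chain).
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable mesh")

    owners: list[tuple[ResidueId, str]] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []

    def _collect(rs: Iterable[ResidueRecord], scored: bool) -> None:
        for res in rs:
            for a in res.atoms:
                if a.element == "H" and not include_hydrogens:
                    continue
                r = VDW_RADII.get(a.element)
                if r is None:
                    if strict:
                        raise StructureParseError(
                            f"unknown element {a.element!r} in residue {res.id}"
                        )
                    logger.warning(
                        "unknown element %r in residue %s: using fallback radius %.2f",
                        a.element, res.id, fallback_radius,
                    )
                    r = fallback_radius
                owners.append((res.id, a.name) if scored else (None, a.name))
                coords.append(a.position)
                radii.append(r)

    _collect(residues, True)
    _collect(extra_occluders, False)

    xyz = np.array(coords, dtype=float).reshape(-1, 3)
    rad = np.array(radii, dtype=float) + probe
    mesh = sphere_points(n_points)

    per_atom: dict[ResidueId, dict[str, float]] = {res.id: {} for res in residues}
    if len(xyz) == 0:
        return SasaResult(probe, n_points, per_atom, {res.id: 0.0 for res in residues})

    tree = cKDTree(xyz)
    max_reach = 2.0 * rad.max()
    for i, (owner, aname) in enumerate(owners):
        if owner is None:
            continue
        ri = rad[i]
        pts = xyz[i] + ri * mesh
        exposed = np.ones(len(pts), dtype=bool)
        for j in tree.query_ball_point(xyz[i], ri + max_reach):
            if j == i:
                continue
            rj = rad[j]
            if np.linalg.norm(xyz[j] - xyz[i]) >= ri + rj:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > rj * rj
            if not exposed.any():
                break
        area = 4.0 * math.pi * ri * ri * exposed.sum() / n_points
        per_atom[owner][aname] = area

    per_residue = {rid: float(sum(d.values())) for rid, d in per_atom.items()}
    return SasaResult(probe, n_points, per_atom, per_residue)


def compute_rsa(
    residue_sasa: float,
    aa1: str,
    max_asa_table: Mapping[str, float] | None = None,
) -> float:
    """Relative solvent accessibility: SASA over the reference maximum, capped at 1."""
    table = MAX_ASA if max_asa_table is None else max_asa_table
    if aa1 not in table:
        raise ValueError(f"no reference area for residue type {aa1!r}; RSA undefined")
    if residue_sasa < 0:
        raise ValueError("SASA must be non-negative")
    return min(1.0, residue_sasa / table[aa1])


# ---------------------------------------------------------------------------
# secondary structure

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -45.0)
STRAND_PSI = (45.0, 180.0)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle in degrees for four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(
    residues: Sequence[ResidueRecord],
) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; None where flanking backbone atoms are missing."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(residues):
        n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
        phi = psi = None
        if n is not None and ca is not None and c is not None:
            if i > 0:
                c_prev = residues[i - 1].coord("C")
                if c_prev is not None:
                    phi = dihedral(c_prev, n, ca, c)
            if i < len(residues) - 1:
                n_next = residues[i + 1].coord("N")
                if n_next is not None:
                    psi = dihedral(n, ca, c, n_next)
        else:
            logger.warning("residue %s lacks backbone atoms; labelled C", res.id)
        out.append((phi, psi))
    return out


def assign_secondary_structure(
    residues: Sequence[ResidueRecord],
    *,
    min_helix_run: int = 4,
    min_strand_run: int = 3,
) -> dict[ResidueId, str]:
    """3-state secondary structure (H/E/C) from backbone dihedral regions.

    Raw per-residue region labels are smoothed by a minimum run length:
    helix runs shorter than ``min_helix_run`` and strand runs shorter
    than ``min_strand_run`` revert to coil. Residues without both
    dihedrals (chain termini, broken backbone) are coil.
    """
    labels = []
    for phi, psi in backbone_dihedrals(residues):
        if phi is None or psi is None:
            labels.append("C")
        elif HELIX_PHI[0] <= phi <= HELIX_PHI[1] and HELIX_PSI[0] <= psi <= HELIX_PSI[1]:
            labels.append("H")
        elif STRAND_PHI[0] <= phi <= STRAND_PHI[1] and STRAND_PSI[0] <= psi <= STRAND_PSI[1]:
            labels.append("E")
        else:
            labels.append("C")

    smoothed = labels[:]
    i = 0
    while i < len(smoothed):
        j = i
        while j < len(smoothed) and smoothed[j] == smoothed[i]:
            j += 1
        run, length = smoothed[i], j - i
        if (run == "H" and length < min_helix_run) or (run == "E" and length < min_strand_run):
            for k in range(i, j):
                smoothed[k] = "C"
        i = j
    return {res.id: lab for res, lab in zip(residues, smoothed)}


# ---------------------------------------------------------------------------
# contacts

def _representative_coord(res: ResidueRecord, metric: str) -> np.ndarray | None:
    if metric == "CA":
        return res.coord("CA")
    if metric == "CB":
        cb = res.coord("CB")
        if cb is not None:
            return cb
        ca = res.coord("CA")
        if ca is not None and res.aa1 != "G":
            logger.warning("residue %s lacks CB; falling back to CA", res.id)
        return ca
    raise ValueError(f"unknown contact metric {metric!r}")


def compute_contacts(
    residues: Sequence[ResidueRecord],
    cutoff: float = 8.0,
    metric: str = "CB",
) -> ContactMap:
    """Residue contact map: pairs whose metric distance is <= cutoff.

    Metrics: ``CA`` (alpha-carbon), ``CB`` (beta-carbon, CA for Gly) or
    ``heavy`` (minimum heavy-atom distance). Sequence-adjacent pairs are
    kept — they are genuine structural neighbours for context analysis.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cmap = ContactMap(cutoff, metric)

    if metric == "heavy":
        owner_idx: list[int] = []
        coords: list[np.ndarray] = []
        for k, res in enumerate(residues):
            for a in res.atoms:
                if a.element == "H":
                    continue
                owner_idx.append(k)
                coords.append(a.position)
        if not coords:
            return cmap
        xyz = np.array(coords)
        tree = cKDTree(xyz)
        best: dict[tuple[int, int], float] = {}
        for i, j in tree.query_pairs(cutoff):
            a, b = owner_idx[i], owner_idx[j]
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d < best.get(key, math.inf):
                best[key] = d
        for (a, b), d in best.items():
            cmap.add(residues[a].id, residues[b].id, d)
        return cmap

    kept: list[ResidueRecord] = []
    coords = []
    for res in residues:
        p = _representative_coord(res, metric)
        if p is None:
            logger.warning("residue %s has no %s-metric atom; skipped in contacts", res.id, metric)
            continue
        kept.append(res)
        coords.append(p)
    if not coords:
        return cmap
    xyz = np.array(coords)
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(cutoff):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        cmap.add(kept[i].id, kept[j].id, d)
    return cmap


# ---------------------------------------------------------------------------
# functional-site proximity

def min_heavy_distance(res_a: ResidueRecord, res_b: ResidueRecord) -> float:
    a, b = res_a.heavy_coords(), res_b.heavy_coords()
    if len(a) == 0 or len(b) == 0:
        return math.inf
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.sum(diff * diff, axis=-1)).min())


def functional_site_score(
    residue: ResidueRecord,
    functional_residues: Iterable[ResidueId],
    residues: Sequence[ResidueRecord],
    decay_cutoff: float = 10.0,
    metric: str = "heavy",
) -> tuple[float | None, float]:
    """Distance to the nearest annotated residue and the site factor S.

    S decays linearly from 1 at distance 0 to 0 at ``decay_cutoff``. An
    annotated residue scores S = 1 for itself. With no annotations the
    factor is 0 and the distance undefined.
    """
    if decay_cutoff <= 0:
        raise ValueError("decay_cutoff must be positive")
    sites = set(functional_residues)
    if not sites:
        return None, 0.0
    if residue.id in sites:
        return 0.0, 1.0
    by_id = {r.id: r for r in residues}
    d = math.inf
    for sid in sorted(sites):
        target = by_id.get(sid)
        if target is None:
            logger.warning("annotated residue %s absent from structure; skipped", sid)
            continue
        if metric == "heavy":
            dist = min_heavy_distance(residue, target)
        else:
            pa = _representative_coord(residue, metric)
            pb = _representative_coord(target, metric)
            dist = math.inf if pa is None or pb is None else float(np.linalg.norm(pa - pb))
        d = min(d, dist)
    if math.isinf(d):
        return None, 0.0
    return d, max(0.0, 1.0 - d / decay_cutoff)


def read_annotations(text: str) -> set[ResidueId]:
    """Parse the functional-residue TSV (header: chain, resnum, [icode], label)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return set()
    header = [h.strip().lower() for h in lines[0].split("\t")]
    try:
        ci, ri = header.index("chain"), header.index("resnum")
    except ValueError as exc:
        raise StructureParseError(
            "annotation file must have a header with 'chain' and 'resnum' columns"
        ) from exc
    ii = header.index("icode") if "icode" in header else None
    out: set[ResidueId] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) < len(header) - (0 if ii is not None else 0):
            # tolerate missing trailing cells (e.g. empty label)
            cells = cells + [""] * (len(header) - len(cells))
        try:
            resnum = int(cells[ri].strip())
        except ValueError as exc:
            raise StructureParseError(f"annotation line {lineno}: bad residue number") from exc
        icode = cells[ii].strip() if ii is not None and ii < len(cells) else ""
        out.add((cells[ci].strip(), resnum, icode))
    return out


def compute_features(
    residues: Sequence[ResidueRecord],
    functional_residues: Iterable[ResidueId] = (),
    *,
    probe: float = 1.4,
    n_points: int = 960,
    decay_cutoff: float = 10.0,
    site_metric: str = "heavy",
    max_asa_table: Mapping[str, float] | None = None,
    strict: bool = False,
) -> dict[ResidueId, StructuralFeatures]:
    """Convenience wrapper: SASA + RSA + secondary structure + site factor."""
    sasa = compute_sasa(residues, probe, n_points, strict=strict)
    ss = assign_secondary_structure(residues)
    sites = set(functional_residues)
    out: dict[ResidueId, StructuralFeatures] = {}
    for res in residues:
        area = sasa.per_residue[res.id]
        try:
            rsa = compute_rsa(area, res.aa1, max_asa_table)
        except ValueError:
            logger.warning("residue %s has unknown type; RSA undefined", res.id)
            rsa = None
        d, s = functional_site_score(res, sites, residues, decay_cutoff, site_metric)
        out[res.id] = StructuralFeatures(res.id, res.aa1, area, rsa, ss[res.id], d, s)
    return out
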