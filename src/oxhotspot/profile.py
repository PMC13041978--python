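"""Per-position evolutionary profiles and sequence↔structure mapping.

A profile gives, for every alignment position, the fraction of
homologous sequences carrying each amino acid. Two quantities are read
off it: the wild-type frequency K (how conserved the native residue is;
the risk model uses 1−K) and the substitution spectrum (the residues
observed above a frequency threshold, which bounds the mutation search
space).

The supported on-disk dialect is the per-position percentage block of
HSSP-style files: a header line naming the 20 amino-acid columns,
followed by one row per position with integer percentages. Sections the
method does not use are skipped, not rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .errors import MappingError, ProfileFormatError
from .structure import STANDARD_AA, ResidueId, ResidueRecord, sequence_of

logger = logging.getLogger(__name__)

#: canonical HSSP amino-acid column order
HSSP_AA_ORDER = "VLIMFWYGAPSTCHRKQEND"


@dataclass
class ProfilePosition:
    """Amino-acid frequency vector at one alignment position."""

    seq_pos: int  # 1-based profile index
    wt_aa: str
    freqs: dict[str, float]  # one-letter code -> fraction in [0, 1]
    n_aligned: int | None = None

    def __post_init__(self) -> None:
        for aa in STANDARD_AA:
            self.freqs.setdefault(aa, 0.0)


@dataclass
class EvolutionaryProfile:
    positions: list[ProfilePosition]

    @property
    def source_sequence(self) -> str:
        return "".join(p.wt_aa for p in self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def by_seq_pos(self, seq_pos: int) -> ProfilePosition | None:
        for p in self.positions:
            if p.seq_pos == seq_pos:
                return p
        return None


@dataclass
class SeqStructMapping:
    """Injective map from profile positions to structure residue identities."""

    pairs: dict[int, ResidueId]  # seq_pos -> (chain, resnum, icode)
    coverage: float  # mapped positions over max(structure length, profile length)
    offset: int | None  # resnum − seq_pos when constant-offset mode applied
    mismatches: list[tuple[int, ResidueId, str, str]] = field(default_factory=list)

    def inverse(self) -> dict[ResidueId, int]:
        return {rid: pos for pos, rid in self.pairs.items()}


# ---------------------------------------------------------------------------
# parsing

def parse_hssp(profile_text: str) -> EvolutionaryProfile:
    """Parse the per-position percentage block of an HSSP-style file.

    The block is located by its header line (the one naming all 20
    amino-acid columns); everything before it and any later ``##``
    section is ignored. Percentages are converted to fractions.
    """
    lines = profile_text.splitlines()
    header_idx = None
    aa_cols: dict[int, str] = {}
    layout: dict[str, int] = {}
    for i, ln in enumerate(lines):
        toks = ln.split()
        single = [t for t in toks if len(t) == 1 and t in STANDARD_AA]
        if len(set(single)) == 20:
            header_idx = i
            for col, t in enumerate(toks):
                if len(t) == 1 and t in STANDARD_AA:
                    aa_cols[col] = t
                else:
                    layout[t.upper()] = col
            break
    if header_idx is None:
        raise ProfileFormatError("no per-position profile block found")

    pos_col = None
    for key in ("SEQNO", "POS", "POSITION"):
        if key in layout:
            pos_col = layout[key]
            break
    aa_col = layout.get("AA")
    nocc_col = layout.get("NOCC")
    ncols = len(lines[header_idx].split())

    positions: list[ProfilePosition] = []
    for ln in lines[header_idx + 1:]:
        stripped = ln.strip()
        if not stripped or stripped.startswith("##") or stripped.startswith("//"):
            break
        toks = ln.split()
        if len(toks) != ncols:
            raise ProfileFormatError(
                f"profile row at position {len(positions) + 1}: expected "
                f"{ncols} columns, found {len(toks)}"
            )
        try:
            seq_pos = int(toks[pos_col]) if pos_col is not None else len(positions) + 1
            freqs = {aa: int(toks[col]) / 100.0 for col, aa in aa_cols.items()}
            n_aligned = int(toks[nocc_col]) if nocc_col is not None else None
        except ValueError as exc:
            raise ProfileFormatError(
                f"profile row at position {len(positions) + 1}: {exc}"
            ) from exc
        wt = toks[aa_col] if aa_col is not None else max(freqs, key=freqs.get)
        positions.append(ProfilePosition(seq_pos, wt, freqs, n_aligned))
    if not positions:
        raise ProfileFormatError("profile block contains no positions")
    positions.sort(key=lambda p: p.seq_pos)
    return EvolutionaryProfile(positions)


# ---------------------------------------------------------------------------
# frequency queries

def wt_frequency(position: ProfilePosition, wt_aa: str | None = None) -> float:
    """K: the alignment frequency of the (by default native) residue."""
    aa = position.wt_aa if wt_aa is None else wt_aa
    if aa not in STANDARD_AA:
        raise ValueError(f"non-standard residue code {aa!r}")
    return position.freqs.get(aa, 0.0)


def substitution_spectrum(
    position: ProfilePosition, min_freq: float = 0.05
) -> list[tuple[str, float]]:
    """Residues observed at the position with frequency >= ``min_freq``.

    Sorted by descending frequency, ties alphabetically; shrinks
    monotonically as the threshold grows.
    """
    if not 0.0 <= min_freq <= 1.0:
        raise ValueError("min_freq must lie in [0, 1]")
    items = [(aa, f) for aa, f in position.freqs.items() if f >= min_freq and f > 0.0]
    return sorted(items, key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# sequence <-> structure mapping

def map_profile_to_structure(
    profile: EvolutionaryProfile,
    residues: list[ResidueRecord],
    *,
    coverage_floor: float = 0.8,
    mismatch_tolerance: float = 0.02,
) -> SeqStructMapping:
    """Reconcile profile numbering with author residue numbering.

    A pure renumbering (identical sequences, one constant offset, no
    insertion codes) is detected first; otherwise a global pairwise
    alignment (identity scoring, affine gaps) supplies the mapping.
    Fails hard when the mapped fraction of structure residues falls
    below ``coverage_floor`` or aligned mismatches exceed
    ``mismatch_tolerance`` of the aligned length.
    """
    if not profile.positions or not residues:
        raise MappingError("profile and structure must both be non-empty")

    struct_seq = sequence_of(residues)
    prof_seq = profile.source_sequence

    # constant-offset fast path
    if len(prof_seq) == len(struct_seq) and prof_seq == struct_seq:
        if all(r.icode == "" for r in residues):
            offsets = {r.resnum - p.seq_pos for p, r in zip(profile.positions, residues)}
            if len(offsets) == 1:
                off = offsets.pop()
                pairs = {p.seq_pos: r.id for p, r in zip(profile.positions, residues)}
                logger.info("profile maps to structure by constant offset %+d", off)
                return SeqStructMapping(pairs, 1.0, off, [])

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-2.0,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(prof_seq, struct_seq)[0]
    pairs: dict[int, ResidueId] = {}
    mismatches: list[tuple[int, ResidueId, str, str]] = []
    aligned_len = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            p = profile.positions[t0 + k]
            r = residues[q0 + k]
            pairs[p.seq_pos] = r.id
            aligned_len += 1
            if p.wt_aa != r.aa1:
                mismatches.append((p.seq_pos, r.id, p.wt_aa, r.aa1))

    coverage = len(pairs) / max(len(residues), len(profile.positions))
    if coverage < coverage_floor:
        raise MappingError(
            f"profile does not match structure: coverage {coverage:.2f} "
            f"below floor {coverage_floor:.2f}"
        )
    if aligned_len and len(mismatches) > mismatch_tolerance * aligned_len:
        raise MappingError(
            f"profile does not match structure: {len(mismatches)} mismatches "
            f"over {aligned_len} aligned positions exceeds tolerance "
            f"{mismatch_tolerance:.0%}"
        )
    if mismatches:
        logger.warning("%d sequence/structure mismatches tolerated", len(mismatches))
    return SeqStructMapping(pairs, coverage, None, mismatches)


def mapping_to_tsv(
    mapping: SeqStructMapping,
    profile: EvolutionaryProfile,
    residues: list[ResidueRecord],
) -> str:
    """Serialise the mapping (seq_pos, chain, resnum, icode, wt codes)."""
    by_id = {r.id: r for r in residues}
    rows = ["seq_pos\tchain\tresnum\ticode\twt_profile\twt_structure"]
    for pos in profile.positions:
        rid = mapping.pairs.get(pos.seq_pos)
        if rid is None:
            continue
        rows.append(
            f"{pos.seq_pos}\t{rid[0]}\t{rid[1]}\t{rid[2]}\t{pos.wt_aa}\t{by_id[rid].aa1}"
        )
    return "\n".join(rows) + "\n"
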