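"""End-to-end orchestration: configuration, staged execution, reports.

The pipeline runs parse → structural features → profile mapping →
risk scoring → ranking/tiering → pattern classification → substitution
feasibility → neighbour context, collects warnings, and serialises the
result as fixed-column TSV tables and a JSON document that round-trips
exactly. Substitutions are proposed for the separated upper tier when
one exists, otherwise for the single top-ranked residue (reported as
such, not as a separated hotspot).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ._version import __version__
from .errors import OxhotspotError, PipelineError
from .feasibility import (
    NeighborContext,
    NeighborInfo,
    SubstitutionCandidate,
    enumerate_candidates,
    neighbor_context,
)
from .profile import mapping_to_tsv, map_profile_to_structure, parse_hssp
from .risk import (
    DEFAULT_SCALE,
    DEFAULT_WEIGHTS,
    ResidueRisk,
    RiskWeights,
    SusceptibilityScale,
    classify_pattern,
    rank_and_tier,
    score_all,
    upper_tier,
)
from .structure import (
    ResidueId,
    compute_contacts,
    compute_features,
    parse_structure,
    read_annotations,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """User-adjustable parameters of the whole analysis."""

    chain: str = "A"
    weights: RiskWeights = field(default_factory=lambda: DEFAULT_WEIGHTS)
    scale: SusceptibilityScale = field(default_factory=lambda: DEFAULT_SCALE)
    contact_cutoff: float = 8.0  # Å
    contact_metric: str = "CB"
    site_decay_cutoff: float = 10.0  # Å
    site_metric: str = "heavy"
    min_freq: float = 0.05
    gap_delta: float = 0.15
    max_dominant: int = 2
    prone_only: bool = True
    missing_k_value: float = 1.0
    coverage_floor: float = 0.8
    mismatch_tolerance: float = 0.02
    sasa_probe: float = 1.4  # Å
    sasa_points: int = 960
    normalize_weights: bool = False
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "site_decay_cutoff", "sasa_probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_freq", "gap_delta"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.normalize_weights:
            self.weights = self.weights.normalized()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights.as_tuple())
        d["scale"] = {
            "table": dict(self.scale.table),
            "prone_set": sorted(self.scale.prone_set),
            "baseline": self.scale.baseline,
        }
        return d


@dataclass
class MappingSummary:
    coverage: float
    offset: int | None
    n_mismatches: int


@dataclass
class Report:
    """Complete result of one pipeline run, JSON-serialisable."""

    version: str
    config: dict
    risks: list[ResidueRisk]
    pattern: str
    top: ResidueId | None
    hotspots: list[ResidueId]
    candidates: dict[str, list[SubstitutionCandidate]]  # key: "chain:resnum:icode"
    contexts: dict[str, NeighborContext]
    mapping: MappingSummary
    mapping_tsv: str
    warnings: list[str]


def id_str(rid: ResidueId) -> str:
    return f"{rid[0]}:{rid[1]}:{rid[2]}"


def parse_id(s: str) -> ResidueId:
    chain, resnum, icode = s.split(":")
    return (chain, int(resnum), icode)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(
    structure_path: str | Path,
    profile_path: str | Path,
    annotations_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> Report:
    """Run all stages on the given input files and return the full report."""
    cfg = config or PipelineConfig()
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("oxhotspot")
    pkg_logger.addHandler(collector)
    try:
        return _run(structure_path, profile_path, annotations_path, cfg, collector)
    finally:
        pkg_logger.removeHandler(collector)


def _read_text(path: str | Path, stage: str) -> str:
    try:
        return Path(path).read_text()
    except OSError as exc:
        raise PipelineError(stage, f"cannot read {path}: {exc}") from exc


def _run(structure_path, profile_path, annotations_path, cfg, collector) -> Report:
    def guard(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except (OxhotspotError, ValueError) as exc:
            raise PipelineError(stage, str(exc)) from exc

    residues = guard(
        "parse", parse_structure, _read_text(structure_path, "parse"), cfg.chain
    )

    if annotations_path is not None:
        sites = guard(
            "annotations", read_annotations, _read_text(annotations_path, "annotations")
        )
    else:
        sites = set()
        logger.warning("no annotation file supplied: site factor S is 0 everywhere")

    features = guard(
        "features",
        compute_features,
        residues,
        sites,
        probe=cfg.sasa_probe,
        n_points=cfg.sasa_points,
        decay_cutoff=cfg.site_decay_cutoff,
        site_metric=cfg.site_metric,
        strict=cfg.strict,
    )
    contacts = guard(
        "features", compute_contacts, residues, cfg.contact_cutoff, cfg.contact_metric
    )

    profile = guard("profile", parse_hssp, _read_text(profile_path, "profile"))
    mapping = guard(
        "mapping",
        map_profile_to_structure,
        profile,
        residues,
        coverage_floor=cfg.coverage_floor,
        mismatch_tolerance=cfg.mismatch_tolerance,
    )

    risks = guard(
        "score",
        score_all,
        features,
        profile,
        mapping,
        cfg.scale,
        cfg.weights,
        cfg.prone_only,
        cfg.missing_k_value,
    )

    if risks:
        ranked = guard("rank", rank_and_tier, risks, cfg.gap_delta)
        pattern = guard(
            "classify", classify_pattern, ranked, cfg.gap_delta, cfg.max_dominant
        )
        top = ranked[0].residue
        hotspots = [r.residue for r in upper_tier(ranked)]
    else:
        logger.warning("no residues scored (prone-only filter?): empty hotspot table")
        ranked, pattern, top, hotspots = [], "undefined", None, []

    targets = [r for r in ranked if r.residue in set(hotspots)] or ranked[:1]
    inv = {rid: pos for pos, rid in mapping.pairs.items()}
    by_pos = {p.seq_pos: p for p in profile.positions}
    candidates: dict[str, list[SubstitutionCandidate]] = {}
    contexts: dict[str, NeighborContext] = {}
    for r in targets:
        pos = by_pos.get(inv.get(r.residue))
        candidates[id_str(r.residue)] = guard(
            "feasibility", enumerate_candidates, r, pos, cfg.min_freq, cfg.scale
        )
        contexts[id_str(r.residue)] = guard(
            "context",
            neighbor_context,
            r,
            contacts,
            profile,
            mapping,
            residues,
            cfg.min_freq,
        )

    if cfg.strict and collector.messages:
        raise PipelineError(
            "strict", f"{len(collector.messages)} warnings escalated to errors: "
            + "; ".join(collector.messages[:5])
        )

    return Report(
        version=__version__,
        config=cfg.to_dict(),
        risks=ranked,
        pattern=pattern,
        top=top,
        hotspots=hotspots,
        candidates=candidates,
        contexts=contexts,
        mapping=MappingSummary(mapping.coverage, mapping.offset, len(mapping.mismatches)),
        mapping_tsv=mapping_to_tsv(mapping, profile, residues),
        warnings=list(collector.messages),
    )


# ---------------------------------------------------------------------------
# serialisation

RISK_COLUMNS = ["chain", "resnum", "icode", "aa", "E", "C", "K", "S", "ORI", "rank", "tier"]
CANDIDATE_COLUMNS = [
    "chain", "resnum", "native_aa", "candidate_aa", "evo_freq",
    "candidate_C", "delta_C", "feasibility", "rank",
]
NEIGHBOR_COLUMNS = ["hotspot", "neighbor", "distance", "K", "hydrophobic"]

_F = "{:.9f}".format  # ≥6 decimals so full-precision ties stay auditable


def risk_table_tsv(risks: list[ResidueRisk]) -> str:
    rows = ["\t".join(RISK_COLUMNS)]
    for r in risks:
        rows.append("\t".join([
            r.residue[0], str(r.residue[1]), r.residue[2], r.aa,
            _F(r.E), _F(r.C), _F(r.K), _F(r.S), _F(r.ori),
            str(r.rank or ""), r.tier or "",
        ]))
    return "\n".join(rows) + "\n"


def candidate_table_tsv(candidates: dict[str, list[SubstitutionCandidate]]) -> str:
    rows = ["\t".join(CANDIDATE_COLUMNS)]
    for key in sorted(candidates):
        for c in candidates[key]:
            rows.append("\t".join([
                c.residue[0], str(c.residue[1]), c.native_aa, c.candidate_aa,
                _F(c.evo_freq), _F(c.candidate_C), _F(c.delta_C),
                _F(c.feasibility), str(c.rank or ""),
            ]))
    return "\n".join(rows) + "\n"


def neighbor_table_tsv(contexts: dict[str, NeighborContext]) -> str:
    rows = ["\t".join(NEIGHBOR_COLUMNS)]
    for key in sorted(contexts):
        ctx = contexts[key]
        for n in ctx.neighbors:
            rows.append("\t".join([
                id_str(ctx.hotspot), id_str(n.residue), _F(n.distance),
                _F(n.wt_freq) if n.wt_freq is not None else "",
                str(int(n.hydrophobic)),
            ]))
    return "\n".join(rows) + "\n"


def report_to_dict(report: Report) -> dict:
    def risk_d(r: ResidueRisk) -> dict:
        d = dataclasses.asdict(r)
        d["residue"] = list(r.residue)
        return d

    def cand_d(c: SubstitutionCandidate) -> dict:
        d = dataclasses.asdict(c)
        d["residue"] = list(c.residue)
        return d

    def ctx_d(ctx: NeighborContext) -> dict:
        return {
            "hotspot": list(ctx.hotspot),
            "neighbors": [
                {
                    "residue": list(n.residue),
                    "aa": n.aa,
                    "distance": n.distance,
                    "wt_freq": n.wt_freq,
                    "spectrum": [[aa, f] for aa, f in n.spectrum],
                    "hydrophobic": n.hydrophobic,
                }
                for n in ctx.neighbors
            ],
        }

    return {
        "version": report.version,
        "config": report.config,
        "risks": [risk_d(r) for r in report.risks],
        "pattern": report.pattern,
        "top": list(report.top) if report.top else None,
        "hotspots": [list(h) for h in report.hotspots],
        "candidates": {k: [cand_d(c) for c in v] for k, v in report.candidates.items()},
        "contexts": {k: ctx_d(v) for k, v in report.contexts.items()},
        "mapping": dataclasses.asdict(report.mapping),
        "mapping_tsv": report.mapping_tsv,
        "warnings": report.warnings,
    }


def report_from_dict(d: dict) -> Report:
    def risk_o(r: dict) -> ResidueRisk:
        r = dict(r)
        r["residue"] = tuple(r["residue"])
        return ResidueRisk(**r)

    def cand_o(c: dict) -> SubstitutionCandidate:
        c = dict(c)
        c["residue"] = tuple(c["residue"])
        return SubstitutionCandidate(**c)

    def ctx_o(c: dict) -> NeighborContext:
        return NeighborContext(
            hotspot=tuple(c["hotspot"]),
            neighbors=[
                NeighborInfo(
                    residue=tuple(n["residue"]),
                    aa=n["aa"],
                    distance=n["distance"],
                    wt_freq=n["wt_freq"],
                    spectrum=[(aa, f) for aa, f in n["spectrum"]],
                    hydrophobic=n["hydrophobic"],
                )
                for n in c["neighbors"]
            ],
        )

    return Report(
        version=d["version"],
        config=d["config"],
        risks=[risk_o(r) for r in d["risks"]],
        pattern=d["pattern"],
        top=tuple(d["top"]) if d["top"] else None,
        hotspots=[tuple(h) for h in d["hotspots"]],
        candidates={k: [cand_o(c) for c in v] for k, v in d["candidates"].items()},
        contexts={k: ctx_o(v) for k, v in d["contexts"].items()},
        mapping=MappingSummary(**d["mapping"]),
        mapping_tsv=d["mapping_tsv"],
        warnings=list(d["warnings"]),
    )


def write_report(
    report: Report, outdir: str | Path, formats: tuple[str, ...] = ("tsv", "json")
) -> list[Path]:
    """Write the report tables/documents; returns the files written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "tsv" in formats:
        for name, text in [
            ("risk.tsv", risk_table_tsv(report.risks)),
            ("candidates.tsv", candidate_table_tsv(report.candidates)),
            ("neighbors.tsv", neighbor_table_tsv(report.contexts)),
            ("mapping.tsv", report.mapping_tsv),
        ]:
            p = out / name
            p.write_text(text)
            written.append(p)
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n")
        written.append(p)
    return written


def read_report_json(path: str | Path) -> Report:
    return report_from_dict(json.loads(Path(path).read_text()))
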