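"""End-to-end orchestration: universe -> screen -> score -> rank -> intersect.

A :class:`PipelineConfig` names the five input files and the per-cancer-type
cell-line pairs; :func:`run_pipeline` executes every stage deterministically
(all randomness lives in :mod:`golgiscreen.synth`) and optionally writes a
candidate TSV plus a JSON report that echoes every parameter that
influenced the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from golgiscreen import io
from golgiscreen.evidence import EvidenceRecord, NONE_REPORTED, PhenotypeContext, literature_score
from golgiscreen.network import DEFAULT_CHANNEL, DEFAULT_MIN_CONF, InteractionNetwork, count_golgi_interactors, filter_edges
from golgiscreen.rank import DEFAULT_CUTOFF, CandidateRecord, CandidateReport, combine_and_select, intersect_candidates
from golgiscreen.screen import EQUAL, CellLinePair, DEGTable, screen_degs
from golgiscreen.universe import build_universe, select_by_terms

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    annotation_path: str
    curated_path: str
    expression_path: str
    edges_path: str
    evidence_path: str
    pairs: tuple[CellLinePair, ...]
    terms: tuple[str, ...] = ("golgi organization",)
    channel: str = DEFAULT_CHANNEL
    min_conf: float = DEFAULT_MIN_CONF
    cutoff: int = DEFAULT_CUTOFF
    pseudocount: float = 0.01
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat-key YAML config; keyword arguments override file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        pairs = tuple(
            CellLinePair(
                cancer_type=p["cancer_type"],
                organized_line=p["organized_line"],
                disorganized_line=p["disorganized_line"],
                base_threshold=float(p["base_threshold"]),
                cap=int(p.get("cap", 50)),
            )
            for p in raw.pop("pairs")
        )
        if "terms" in raw:
            raw["terms"] = tuple(raw["terms"])
        return cls(pairs=pairs, **raw)

    def to_echo(self) -> dict:
        """Parameter echo for provenance: everything that shaped the result."""
        return {
            "inputs": {
                "annotation": self.annotation_path,
                "curated": self.curated_path,
                "expression": self.expression_path,
                "edges": self.edges_path,
                "evidence": self.evidence_path,
            },
            "terms": list(self.terms),
            "pairs": [
                {
                    "cancer_type": p.cancer_type,
                    "organized_line": p.organized_line,
                    "disorganized_line": p.disorganized_line,
                    "base_threshold": p.base_threshold,
                    "cap": p.cap,
                }
                for p in self.pairs
            ],
            "channel": self.channel,
            "min_conf": self.min_conf,
            "cutoff": self.cutoff,
            "pseudocount": self.pseudocount,
        }


@dataclass(frozen=True)
class PipelineResult:
    report: CandidateReport
    deg_tables: Mapping[str, DEGTable]
    scores1: Mapping[str, Mapping[str, int]]
    scores2: Mapping[str, Mapping[str, int]]
    universe_size: int


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run all stages for every cancer-type pair; optionally write outputs.

    Stage counts are logged as it goes: universe size, per-pair DEG counts,
    selected counts, and the intersection size.
    """
    annotation = io.read_annotation(cfg.annotation_path)
    curated = io.read_curated(cfg.curated_path)
    universe = build_universe(select_by_terms(annotation, cfg.terms), curated)
    if len(universe) == 0:
        logger.warning("gene universe is empty; report will be empty")
    logger.info("universe: %d genes", len(universe))

    expr = io.read_expression(cfg.expression_path)
    net = InteractionNetwork.from_edges(io.read_edges(cfg.edges_path))
    fnet = filter_edges(net, channel=cfg.channel, min_conf=cfg.min_conf)
    evidence = io.read_evidence(cfg.evidence_path)

    candidates: dict[str, tuple[CandidateRecord, ...]] = {}
    deg_tables: dict[str, DEGTable] = {}
    scores1_all: dict[str, dict[str, int]] = {}
    scores2_all: dict[str, dict[str, int]] = {}
    for pair in cfg.pairs:
        degs = screen_degs(expr, universe, pair, pseudocount=cfg.pseudocount)
        deg_tables[pair.cancer_type] = degs
        scores1: dict[str, int] = {}
        scores2: dict[str, int] = {}
        for rec in degs.passed:
            if rec.direction != EQUAL:
                ev = evidence.get(
                    rec.gene,
                    EvidenceRecord(gene=rec.gene, knockdown_phenotype=NONE_REPORTED, golgi_involvement=False),
                )
                ctx = PhenotypeContext(pair=pair, direction=rec.direction)
                scores1[rec.gene] = literature_score(ev, ctx).score1
            else:
                scores1[rec.gene] = 0
            scores2[rec.gene] = count_golgi_interactors(fnet, rec.gene, universe).score2
        scores1_all[pair.cancer_type] = scores1
        scores2_all[pair.cancer_type] = scores2
        selected = combine_and_select(degs, scores1, scores2, cutoff=cfg.cutoff)
        candidates[pair.cancer_type] = tuple(selected)
        logger.info(
            "%s: %d DEGs passed (effective threshold %.4g), %d selected",
            pair.cancer_type, len(degs.passed), degs.effective_threshold, len(selected),
        )

    if candidates:
        lists = list(candidates.values())
        common = {c.gene for c in lists[0]}
        for other in lists[1:]:
            common = intersect_candidates(common, other)
    else:
        common = set()
    logger.info("common to all cancer types: %d genes", len(common))

    report = CandidateReport(
        candidates=candidates, common_genes=frozenset(common), parameters=cfg.to_echo()
    )
    result = PipelineResult(
        report=report,
        deg_tables=deg_tables,
        scores1=scores1_all,
        scores2=scores2_all,
        universe_size=len(universe),
    )
    if write and cfg.out_dir is not None:
        write_outputs(result, cfg)
    return result


def write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = result.report
    io.write_candidates(report.candidates, set(report.common_genes), dict(report.parameters), out / "candidates.tsv")
    io.write_report_json(
        {
            "parameters": dict(report.parameters),
            "universe_size": result.universe_size,
            "stage_counts": {
                ct: {
                    "screened": len(result.deg_tables[ct].records),
                    "degs_passed": len(result.deg_tables[ct].passed),
                    "effective_threshold": result.deg_tables[ct].effective_threshold,
                    "selected": len(report.candidates[ct]),
                }
                for ct in report.candidates
            },
            "candidates": {
                ct: [
                    {
                        "rank": c.rank,
                        "gene": c.gene,
                        "fc": c.fc,
                        "direction": c.direction,
                        "score1": c.score1,
                        "score2": c.score2,
                        "combined": c.combined,
                    }
                    for c in report.candidates[ct]
                ]
                for ct in report.candidates
            },
            "common_genes": sorted(report.common_genes),
        },
        out / "report.json",
    )
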