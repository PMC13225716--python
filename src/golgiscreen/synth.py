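"""Seeded generators for the five pipeline inputs with planted ground truth.

The generators emulate the study layout: four cell lines forming a breast
pair (MDAMB231 organized vs MCF7 disorganized, fold-change threshold 10)
and a lung pair (A549 organized vs CALU1 disorganized, threshold 5); a
Golgi-associated gene universe split between an annotation table and a
curated list; a log-normal RPKM background with planted exact fold-change
ratios; a random interaction graph with planted Golgi-annotated neighbors;
and a knockdown-evidence table realizing requested literature scores.

Ground truth (which genes must survive screening, their score components,
and the selected set) is derivable from the configuration alone, which
requires two constructive guarantees:

* background fold-change ratios are kept strictly below the screen
  thresholds (per-gene rejection sampling against ``max_background_ratio``),
  so no background gene can pass; and
* background edges never touch planted genes, so a planted gene's
  Golgi-interactor count is exactly its configured ``n_golgi_neighbors``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from golgiscreen.evidence import (
    DISORGANIZED,
    NONE_REPORTED,
    ORGANIZED_OR_CONDENSED,
    PhenotypeContext,
    predicted_low_expression_phenotype,
)
from golgiscreen.screen import HIGHER_IN_DISORGANIZED, HIGHER_IN_ORGANIZED, CellLinePair
from golgiscreen.universe import GeneUniverse, build_universe

BREAST_PAIR = CellLinePair(
    cancer_type="breast",
    organized_line="MDAMB231",
    disorganized_line="MCF7",
    base_threshold=10.0,
)
LUNG_PAIR = CellLinePair(
    cancer_type="lung",
    organized_line="A549",
    disorganized_line="CALU1",
    base_threshold=5.0,
)

GOLGI_TERM = "golgi organization"


@dataclass(frozen=True)
class PlantedGene:
    """One planted signal (or decoy): its exact ratio, direction, and score setup."""

    gene: str
    fc_ratio: float
    direction: str  # higher_in_organized | higher_in_disorganized
    score1_setup: int  # requested literature score in {0, 1, 2}
    n_golgi_neighbors: int
    pairs: tuple[str, ...] = ("breast", "lung")  # cancer types where the ratio is planted

    def __post_init__(self) -> None:
        if self.fc_ratio < 1:
            raise ValueError("fc_ratio must be >= 1")
        if self.direction not in (HIGHER_IN_ORGANIZED, HIGHER_IN_DISORGANIZED):
            raise ValueError(f"invalid planted direction {self.direction!r}")
        if self.score1_setup not in (0, 1, 2):
            raise ValueError("score1_setup must be in {0, 1, 2}")
        if self.n_golgi_neighbors < 0:
            raise ValueError("n_golgi_neighbors must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    n_genes: int = 500
    n_universe: int = 120
    planted: tuple[PlantedGene, ...] = ()
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.8
    edge_density: float = 0.01
    bg_score_beta: tuple[float, float] = (2.0, 5.0)
    max_background_ratio: float | None = 4.0
    pairs: tuple[CellLinePair, ...] = (BREAST_PAIR, LUNG_PAIR)
    pseudocount: float = 0.01
    min_conf: float = 0.4
    channel: str = "experimental"
    cutoff: int = 3

    def __post_init__(self) -> None:
        if self.n_universe > self.n_genes:
            raise ValueError("n_universe cannot exceed n_genes")
        planted_names = [p.gene for p in self.planted]
        if len(planted_names) != len(set(planted_names)):
            raise ValueError("planted gene names must be unique")
        if len(planted_names) > self.n_universe:
            raise ValueError("planted genes must fit inside the universe")
        known = {p.cancer_type for p in self.pairs}
        for p in self.planted:
            missing = set(p.pairs) - known
            if missing:
                raise ValueError(f"planted gene {p.gene} references unknown pairs {missing}")
            if p.n_golgi_neighbors > self.n_universe - 1:
                raise ValueError(
                    f"planted gene {p.gene} requests more Golgi neighbors than the universe holds"
                )

    # -- deterministic layout -------------------------------------------------

    @property
    def cell_lines(self) -> tuple[str, ...]:
        lines: list[str] = []
        for p in self.pairs:
            lines.extend([p.organized_line, p.disorganized_line])
        return tuple(lines)

    @property
    def genes(self) -> tuple[str, ...]:
        """Planted genes first, then zero-padded background fillers."""
        planted = [p.gene for p in self.planted]
        fillers = []
        i = 0
        taken = set(planted)
        while len(planted) + len(fillers) < self.n_genes:
            name = f"G{i:04d}"
            if name not in taken:
                fillers.append(name)
            i += 1
        return tuple(planted + fillers)

    @property
    def universe_genes(self) -> tuple[str, ...]:
        return self.genes[: self.n_universe]

    def pair_by_type(self, cancer_type: str) -> CellLinePair:
        for p in self.pairs:
            if p.cancer_type == cancer_type:
                return p
        raise KeyError(cancer_type)


def default_config(seed: int) -> SynthConfig:
    """The default study-shaped bundle: three shared planted candidates plus decoys.

    Decoys each violate exactly one selection criterion: a sub-cutoff
    combined score, no evidence, a sub-threshold fold change, or presence
    in only one cancer type.
    """
    planted = (
        PlantedGene("CAND1", 20.0, HIGHER_IN_ORGANIZED, 2, 3),
        PlantedGene("CAND2", 15.0, HIGHER_IN_DISORGANIZED, 2, 1),
        PlantedGene("CAND3", 12.0, HIGHER_IN_ORGANIZED, 1, 2),
        PlantedGene("DECOYSCORE", 11.0, HIGHER_IN_ORGANIZED, 2, 0),  # combined 2 < 3
        PlantedGene("DECOYNODATA", 11.0, HIGHER_IN_DISORGANIZED, 0, 2),  # combined 2 < 3
        PlantedGene("DECOYLOWFC", 3.0, HIGHER_IN_ORGANIZED, 2, 5),  # fails both screens
        PlantedGene("BREASTONLY", 12.0, HIGHER_IN_ORGANIZED, 2, 2, pairs=("breast",)),
    )
    return SynthConfig(seed=seed, planted=planted)


# -- ground truth -------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline must recover, derived from the config before any run."""

    expected_degs: dict[str, frozenset[str]]  # cancer_type -> genes passing the screen
    expected_scores: dict[str, tuple[int, int]]  # planted gene -> (score1, score2)
    expected_selected: dict[str, frozenset[str]]  # cancer_type -> selected genes
    common_genes: frozenset[str]

    @classmethod
    def from_config(cls, cfg: SynthConfig) -> "GroundTruth":
        thresholds = [p.base_threshold for p in cfg.pairs]
        if cfg.max_background_ratio is None or cfg.max_background_ratio >= min(thresholds):
            raise ValueError(
                "ground truth requires background ratios bounded strictly below "
                "every screen threshold (set max_background_ratio accordingly)"
            )
        degs: dict[str, set[str]] = {p.cancer_type: set() for p in cfg.pairs}
        selected: dict[str, set[str]] = {p.cancer_type: set() for p in cfg.pairs}
        scores: dict[str, tuple[int, int]] = {}
        for pg in cfg.planted:
            scores[pg.gene] = (pg.score1_setup, pg.n_golgi_neighbors)
            for ct in pg.pairs:
                pair = cfg.pair_by_type(ct)
                if pg.fc_ratio >= pair.base_threshold:
                    degs[ct].add(pg.gene)
                    if pg.score1_setup + pg.n_golgi_neighbors >= cfg.cutoff:
                        selected[ct].add(pg.gene)
        for p in cfg.pairs:
            if len(degs[p.cancer_type]) > p.cap:
                raise ValueError(
                    f"{p.cancer_type}: more planted DEGs than the cap; ground truth undefined"
                )
        common = frozenset.intersection(*(frozenset(selected[ct]) for ct in selected)) if selected else frozenset()
        return cls(
            expected_degs={ct: frozenset(g) for ct, g in degs.items()},
            expected_scores=scores,
            expected_selected={ct: frozenset(g) for ct, g in selected.items()},
            common_genes=common,
        )


# -- generators ---------------------------------------------------------------


def _power_of_two_baseline(rng: np.random.Generator, cfg: SynthConfig) -> float:
    """Log-normal-ish baseline snapped to a power of two.

    Multiplying a power of two by the planted ratio and dividing back is
    exact in binary floating point, so planted ratios are recovered
    bit-exactly by the screen.
    """
    x = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd)
    return float(2.0 ** round(math.log2(x)))


def simulate_expression(cfg: SynthConfig) -> pd.DataFrame:
    """Genes x cell-lines RPKM matrix with exact planted fold changes.

    Background values are iid log-normal per cell line; when
    ``max_background_ratio`` is set, a background gene's pair of values is
    redrawn until its ratio falls strictly below the bound, guaranteeing no
    background gene can pass the screen.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    planted_by_gene = {p.gene: p for p in cfg.planted}
    values = np.empty((cfg.n_genes, len(cfg.cell_lines)))
    col = {line: j for j, line in enumerate(cfg.cell_lines)}

    for i, gene in enumerate(cfg.genes):
        pg = planted_by_gene.get(gene)
        for pair in cfg.pairs:
            jo, jd = col[pair.organized_line], col[pair.disorganized_line]
            if pg is not None and pair.cancer_type in pg.pairs:
                base = _power_of_two_baseline(rng, cfg)
                hi = base * pg.fc_ratio
                if pg.direction == HIGHER_IN_ORGANIZED:
                    values[i, jo], values[i, jd] = hi, base
                else:
                    values[i, jo], values[i, jd] = base, hi
            else:
                for _ in range(10_000):
                    a = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd)
                    b = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd)
                    if cfg.max_background_ratio is None:
                        break
                    if max(a, b) / min(a, b) < cfg.max_background_ratio:
                        break
                else:  # pragma: no cover - bound would have to be ~1
                    raise RuntimeError("could not draw background pair under the ratio bound")
                values[i, jo], values[i, jd] = a, b

    return pd.DataFrame(values, index=list(cfg.genes), columns=list(cfg.cell_lines)).rename_axis("gene")


def simulate_universe_inputs(cfg: SynthConfig) -> tuple[pd.DataFrame, list[str]]:
    """Annotation table and curated list whose merge recreates the universe.

    The universe genes are split roughly 2/3 into the annotation table and
    2/3 into the curated list with an overlapping middle third, exercising
    the union/provenance logic. A few non-universe genes get unrelated
    annotation terms.
    """
    uni = list(cfg.universe_genes)
    n = len(uni)
    ann_genes = uni[: max(1, (2 * n) // 3)] if n else []
    cur_genes = uni[n // 3 :] if n else []
    ann_rows = [(g, GOLGI_TERM) for g in ann_genes]
    # distractor rows: genes annotated with an unrelated term must not enter
    for g in cfg.genes[cfg.n_universe : cfg.n_universe + 5]:
        ann_rows.append((g, "mitotic spindle assembly"))
    annotation = pd.DataFrame(ann_rows, columns=["gene", "term"])
    return annotation, cur_genes


def build_synth_universe(cfg: SynthConfig) -> GeneUniverse:
    annotation, curated = simulate_universe_inputs(cfg)
    from golgiscreen.universe import select_by_terms

    return build_universe(select_by_terms(annotation, {GOLGI_TERM}), curated)


def simulate_network(cfg: SynthConfig, universe: GeneUniverse | None = None) -> pd.DataFrame:
    """STRING-style edge list with planted Golgi neighbors.

    Planted genes receive exactly ``n_golgi_neighbors`` edges to
    non-planted universe members with experimental confidence drawn uniform
    [min_conf, 1]; background edges (experimental confidence ~ Beta, mostly
    sub-threshold) connect only non-planted genes. Self-loops never occur.
    """
    if universe is None:
        universe = build_synth_universe(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    planted_names = {p.gene for p in cfg.planted}
    pool = sorted(set(universe.genes) - planted_names)
    rows: list[tuple[str, str, float, float]] = []

    for pg in cfg.planted:
        if pg.n_golgi_neighbors > len(pool):
            raise ValueError(
                f"planted gene {pg.gene}: only {len(pool)} eligible universe neighbors available"
            )
        neighbors = rng.choice(pool, size=pg.n_golgi_neighbors, replace=False)
        for nb in neighbors:
            exp = float(rng.uniform(cfg.min_conf, 1.0))
            rows.append((pg.gene, str(nb), exp, float(rng.uniform(exp, 1.0))))

    bg_genes = [g for g in cfg.genes if g not in planted_names]
    n_pairs = len(bg_genes) * (len(bg_genes) - 1) // 2
    n_bg_edges = int(round(cfg.edge_density * n_pairs))
    if n_bg_edges > 0:
        idx = rng.choice(n_pairs, size=min(n_bg_edges, n_pairs), replace=False)
        a_beta, b_beta = cfg.bg_score_beta
        for k in sorted(int(v) for v in idx):
            i, j = _pair_from_index(k, len(bg_genes))
            exp = float(rng.beta(a_beta, b_beta))
            rows.append((bg_genes[i], bg_genes[j], exp, float(rng.uniform(exp, 1.0))))

    return pd.DataFrame(rows, columns=["protein1", "protein2", "experimental", "combined_score"])


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    """Map a flat index to the k-th unordered pair (i < j) of range(n)."""
    i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * k)) // 2)
    j = k - i * (2 * n - i - 1) // 2 + i + 1
    # guard against float rounding at block boundaries
    while j >= n:
        i += 1
        j = k - i * (2 * n - i - 1) // 2 + i + 1
    while j <= i:
        i -= 1
        j = k - i * (2 * n - i - 1) // 2 + i + 1
    return i, j


def simulate_evidence(cfg: SynthConfig) -> pd.DataFrame:
    """Knockdown-evidence table realizing each planted gene's requested score.

    Inverts the scoring rubric: a concordant record (score 2) reports the
    phenotype of the gene's low-expression line; a discordant record
    (score 1) reports the opposite; score 0 means no data. Non-planted
    universe genes carry no-data records.
    """
    rows = []
    planted_names = set()
    for pg in cfg.planted:
        planted_names.add(pg.gene)
        if pg.score1_setup == 0:
            rows.append((pg.gene, NONE_REPORTED, False))
            continue
        ctx = PhenotypeContext(pair=cfg.pairs[0], direction=pg.direction)
        concordant = predicted_low_expression_phenotype(ctx)
        if pg.score1_setup == 2:
            rows.append((pg.gene, concordant, True))
        else:
            discordant = DISORGANIZED if concordant == ORGANIZED_OR_CONDENSED else ORGANIZED_OR_CONDENSED
            rows.append((pg.gene, discordant, True))
    for g in cfg.universe_genes:
        if g not in planted_names:
            rows.append((g, NONE_REPORTED, False))
    return pd.DataFrame(rows, columns=["gene", "knockdown_phenotype", "golgi_involvement"])


@dataclass(frozen=True)
class SynthBundle:
    """All five generated inputs plus the derived ground truth."""

    config: SynthConfig
    annotation: pd.DataFrame
    curated: list[str]
    expression: pd.DataFrame
    edges: pd.DataFrame
    evidence: pd.DataFrame
    ground_truth: GroundTruth


def write_bundle(bundle: SynthBundle, outdir) -> dict[str, str]:
    """Write the five input files, the ground-truth JSON, and a run config YAML.

    Returns the mapping of logical names to file paths.
    """
    import json
    from pathlib import Path

    import yaml

    from golgiscreen import io as gio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.tsv",
        "curated": out / "curated.txt",
        "expression": out / "expression.tsv",
        "edges": out / "edges.tsv",
        "evidence": out / "evidence.csv",
    }
    gio.write_annotation(bundle.annotation, paths["annotation"])
    gio.write_curated(bundle.curated, paths["curated"])
    gio.write_expression(bundle.expression, paths["expression"])
    gio.write_edges(bundle.edges, paths["edges"])
    gio.write_evidence(bundle.evidence, paths["evidence"])

    truth = bundle.ground_truth
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "expected_degs": {ct: sorted(g) for ct, g in truth.expected_degs.items()},
                "expected_scores": {g: list(s) for g, s in sorted(truth.expected_scores.items())},
                "expected_selected": {ct: sorted(g) for ct, g in truth.expected_selected.items()},
                "common_genes": sorted(truth.common_genes),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    cfg = bundle.config
    run_cfg = {
        "annotation_path": str(paths["annotation"]),
        "curated_path": str(paths["curated"]),
        "expression_path": str(paths["expression"]),
        "edges_path": str(paths["edges"]),
        "evidence_path": str(paths["evidence"]),
        "terms": [GOLGI_TERM],
        "channel": cfg.channel,
        "min_conf": cfg.min_conf,
        "cutoff": cfg.cutoff,
        "pseudocount": cfg.pseudocount,
        "pairs": [
            {
                "cancer_type": p.cancer_type,
                "organized_line": p.organized_line,
                "disorganized_line": p.disorganized_line,
                "base_threshold": p.base_threshold,
                "cap": p.cap,
            }
            for p in cfg.pairs
        ],
    }
    (out / "run_config.yaml").write_text(yaml.safe_dump(run_cfg, sort_keys=False))
    return {k: str(v) for k, v in paths.items()} | {
        "ground_truth": str(out / "ground_truth.json"),
        "run_config": str(out / "run_config.yaml"),
    }


def pipeline_config_for_bundle(bundle_paths: dict[str, str], cfg: SynthConfig, out_dir=None):
    """Build a PipelineConfig pointing at a written bundle."""
    from golgiscreen.pipeline import PipelineConfig

    return PipelineConfig(
        annotation_path=bundle_paths["annotation"],
        curated_path=bundle_paths["curated"],
        expression_path=bundle_paths["expression"],
        edges_path=bundle_paths["edges"],
        evidence_path=bundle_paths["evidence"],
        pairs=cfg.pairs,
        terms=(GOLGI_TERM,),
        channel=cfg.channel,
        min_conf=cfg.min_conf,
        cutoff=cfg.cutoff,
        pseudocount=cfg.pseudocount,
        out_dir=None if out_dir is None else str(out_dir),
    )


def simulate_bundle(cfg: SynthConfig) -> SynthBundle:
    """Generate all five inputs and the ground truth for one configuration."""
    truth = GroundTruth.from_config(cfg)
    annotation, curated = simulate_universe_inputs(cfg)
    universe = build_synth_universe(cfg)
    return SynthBundle(
        config=cfg,
        annotation=annotation,
        curated=curated,
        expression=simulate_expression(cfg),
        edges=simulate_network(cfg, universe),
        evidence=simulate_evidence(cfg),
        ground_truth=truth,
    )
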