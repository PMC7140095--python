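"""End-to-end orchestration: config validation, staged run, and reporting.

``run_all`` executes the full pipeline on on-disk inputs:

1. sample selection per assay availability,
2. probe filtering (cross-reactive, MAF > 5%, sex chromosomes),
3. differential methylation (binned-beta Fisher exact) on the
   methylation cohort,
4. expression filtering + negative-binomial differential expression on the
   expression cohort,
5. signature scores (when signature/centroid files are configured),
6. promoter/body quadrant integration and promoter delta-beta vs fold-change
   correlation on the cases with both assays,
7. enhancer-gene pairing,
8. a TSV/JSON report whose counts are cross-checked against each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io import (
    ValidationError,
    read_beta_matrix,
    read_count_matrix,
    read_manifest,
    read_sample_sheet,
    select_samples,
)
from .diffmeth import DifferentialMethylation, filter_probes
from .diffexpr import NegativeBinomialDE, cpm, filter_expressed, log_cpm
from .integrate import (
    correlate_promoter_fc,
    enhancer_pairs,
    promoter_median_delta_beta,
    promoter_quadrants,
)
from .scores import (
    braf_ras_score,
    read_centroids,
    read_signature,
    thyroid_differentiation_score,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds and input paths in one serializable place."""

    beta: str = ""
    counts: str = ""
    manifest: str = ""
    samples: str = ""
    outdir: str = "methx_out"
    alpha: float = 0.05
    min_delta_beta: float = 0.3
    bin_edges: tuple[float, float] = (0.3, 0.7)
    cpm_threshold: float = 1.0
    expressed_fraction: float = 0.8
    enhancer_window: int = 500_000
    enhancer_k_nearest: int = 10
    tds_signature: str = ""
    brs_centroids: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "min_delta_beta", "expressed_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        edges = tuple(float(e) for e in self.bin_edges)
        if len(edges) != 2 or not (0 <= edges[0] < edges[1] <= 1):
            raise ValidationError(
                f"bin_edges must be increasing within [0, 1], got {self.bin_edges}"
            )
        self.bin_edges = edges
        if self.cpm_threshold < 0:
            raise ValidationError("cpm_threshold must be >= 0")
        if self.enhancer_window <= 0 or self.enhancer_k_nearest <= 0:
            raise ValidationError("enhancer window and k_nearest must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges"] = list(self.bin_edges)
        return d


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config, applying defaults and rejecting unknown
    keys and out-of-range thresholds."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class RunReport:
    """Stage-by-stage counts of the full run; every number equals the
    cardinality of the corresponding stage output."""

    n_tumor_methylation: int = 0
    n_tumor_expression: int = 0
    n_tumor_both: int = 0
    n_normal: int = 0
    probes_input: int = 0
    probes_removed: dict[str, int] = field(default_factory=dict)
    probes_tested: int = 0
    dm_significant: int = 0
    dm_hyper: int = 0
    dm_hypo: int = 0
    genes_input: int = 0
    genes_expressed: int = 0
    de_significant: int = 0
    de_up: int = 0
    de_down: int = 0
    quadrant_probe_counts: dict[str, int] = field(default_factory=dict)
    quadrant_gene_counts: dict[str, int] = field(default_factory=dict)
    promoter_fc_pearson_r: float | None = None
    promoter_fc_n_genes: int = 0
    enhancer_pair_count: int = 0
    scores: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = [f"# methx v{__version__} run report", "metric\tvalue"]
        flat: list[tuple[str, object]] = []
        for key, value in dataclasses.asdict(self).items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    if isinstance(v, dict):
                        continue
                    flat.append((f"{key}.{sub}", v))
            else:
                flat.append((key, value))
        for key, value in flat:
            lines.append(f"{key}\t{value}")
        return "\n".join(lines) + "\n"


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in order, writing outputs under
    ``config.outdir``; raises a stage-labelled error on failure."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    stage = "load inputs"
    try:
        t0 = time.time()
        sheet = read_sample_sheet(config.samples)
        manifest = read_manifest(config.manifest)
        beta = read_beta_matrix(config.beta)
        counts = read_count_matrix(config.counts)
        logger.info("[%s] done in %.2fs", stage, time.time() - t0)

        stage = "select samples"
        meth_tum, meth_norm = select_samples(sheet, require_methylation=True)
        expr_tum, expr_norm = select_samples(sheet, require_expression=True)
        both_tum, both_norm = select_samples(
            sheet, require_expression=True, require_methylation=True
        )
        report.n_tumor_methylation = len(meth_tum)
        report.n_tumor_expression = len(expr_tum)
        report.n_tumor_both = len(both_tum)
        report.n_normal = len(sheet.normals())

        stage = "filter probes"
        report.probes_input = beta.shape[0]
        beta_f, removed = filter_probes(beta, manifest)
        report.probes_removed = removed

        stage = "differential methylation"
        t0 = time.time()
        dm_res = DifferentialMethylation(
            beta_f.subset_samples(meth_tum + meth_norm),
            sheet,
            alpha=config.alpha,
            min_delta_beta=config.min_delta_beta,
            bin_edges=config.bin_edges,
        ).fit()
        dm_res.to_tsv(outdir / "dm.tsv", seed=config.seed)
        ctx = dm_res.context_summary(manifest)
        ctx.island.to_csv(outdir / "context_island.tsv", sep="\t", float_format="%.8g")
        ctx.genic.to_csv(outdir / "context_genic.tsv", sep="\t", float_format="%.8g")
        report.probes_tested = dm_res.n_tested
        report.dm_significant = dm_res.n_significant
        report.dm_hyper = dm_res.n_hyper
        report.dm_hypo = dm_res.n_hypo
        logger.info("[%s] done in %.2fs", stage, time.time() - t0)

        stage = "differential expression"
        t0 = time.time()
        counts_e = counts.subset_samples(expr_tum + expr_norm)
        report.genes_input = len(counts_e.gene_ids)
        expressed = filter_expressed(
            cpm(counts_e), sheet, config.cpm_threshold, config.expressed_fraction
        )
        report.genes_expressed = len(expressed)
        from .io import CountMatrix

        counts_f = CountMatrix(counts_e.counts.loc[expressed])
        de_res = NegativeBinomialDE(counts_f, sheet, alpha=config.alpha).fit()
        de_res.to_tsv(outdir / "de.tsv", seed=config.seed)
        report.de_significant = de_res.n_significant
        report.de_up = de_res.n_up
        report.de_down = de_res.n_down
        logger.info("[%s] done in %.2fs", stage, time.time() - t0)

        stage = "signature scores"
        logexpr = log_cpm(counts_e)
        if config.tds_signature:
            tds = thyroid_differentiation_score(
                logexpr, read_signature(config.tds_signature), sheet
            )
            tds.to_csv(outdir / "tds.tsv", sep="\t", float_format="%.8g")
            report.scores["tds"] = {
                s: round(float(v), 6) for s, v in tds["score"].items()
            }
        if config.brs_centroids:
            brs = braf_ras_score(logexpr, read_centroids(config.brs_centroids), sheet)
            brs.to_csv(outdir / "brs.tsv", sep="\t", float_format="%.8g")
            report.scores["brs_class"] = dict(brs["class"])

        stage = "integration"
        t0 = time.time()
        # both-assay subset for integration stages
        both = both_tum + both_norm
        dm_both = DifferentialMethylation(
            beta_f.subset_samples(both),
            sheet,
            alpha=config.alpha,
            min_delta_beta=config.min_delta_beta,
            bin_edges=config.bin_edges,
        ).fit()
        counts_both = counts.subset_samples(both)
        expressed_b = filter_expressed(
            cpm(counts_both), sheet, config.cpm_threshold, config.expressed_fraction
        )
        de_both = NegativeBinomialDE(
            CountMatrix(counts_both.counts.loc[expressed_b]), sheet, alpha=config.alpha
        ).fit()
        quad = promoter_quadrants(dm_both.records, de_both.records, manifest)
        quad.summary().to_csv(outdir / "quadrants.tsv", sep="\t")
        quad.pairs.to_csv(outdir / "quadrant_pairs.tsv", sep="\t", index=False, float_format="%.8g")
        report.quadrant_probe_counts = {
            k: int(v) for k, v in quad.probe_counts().items()
        }
        report.quadrant_gene_counts = {k: int(v) for k, v in quad.gene_counts().items()}
        gene_db = promoter_median_delta_beta(dm_both.records, manifest)
        try:
            r, n_pairs = correlate_promoter_fc(gene_db, de_both.records)
            report.promoter_fc_pearson_r = round(float(r), 6)
            report.promoter_fc_n_genes = n_pairs
        except ValidationError as exc:
            logger.info("promoter correlation skipped: %s", exc)
        logger.info("[%s] done in %.2fs", stage, time.time() - t0)

        stage = "enhancer pairing"
        t0 = time.time()
        pairs = enhancer_pairs(
            dm_both.records,
            log_cpm(counts_both),
            manifest,
            sheet,
            window=config.enhancer_window,
            k_nearest=config.enhancer_k_nearest,
            q_threshold=config.alpha,
        )
        pairs.to_csv(outdir / "enhancer_pairs.tsv", sep="\t", index=False, float_format="%.8g")
        report.enhancer_pair_count = len(pairs)
        logger.info("[%s] done in %.2fs", stage, time.time() - t0)

        stage = "report"
        (outdir / "report.tsv").write_text(report.to_tsv(), encoding="utf-8")
        (outdir / "run_summary.json").write_text(report.to_json() + "\n", encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    return report
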