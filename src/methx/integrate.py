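"""Joining differential methylation with differential expression.

Two integration views are provided:

* **Quadrants** — each significant promoter or gene-body probe is paired
  with its mapped gene's DE result; concordant pairs fall into one of four
  labels: promoter hypomethylation with upregulation, promoter
  hypermethylation with downregulation, gene-body hypermethylation with
  upregulation, gene-body hypomethylation with downregulation (gene-body
  methylation tracks expression positively, the opposite of promoters).
  Quadrant membership requires both the probe's and the gene's significance;
  direction-mismatched pairs are counted as discordant, probes whose gene is
  missing from the DE table as unpaired.

* **Enhancer pairing** — a simplified supervised distal stage: for each
  significant probe flagged as enhancer, the k nearest genes within a
  window are tested (one-sided Mann-Whitney rank-sum on log expression,
  direction locked anti-concordant with the methylation change: hypo
  probes can only pair with upregulated genes, hyper only with
  downregulated ones), with BH adjustment across all probe-gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProbeAnnotation, SampleSheet, ValidationError
from .diffmeth import bh_adjust

logger = logging.getLogger(__name__)

QUADRANTS = (
    "promoter_hypo_up",
    "promoter_hyper_down",
    "body_hyper_up",
    "body_hypo_down",
)

_QUADRANT_OF = {
    ("promoter", "hypo", "up"): "promoter_hypo_up",
    ("promoter", "hyper", "down"): "promoter_hyper_down",
    ("body", "hyper", "up"): "body_hyper_up",
    ("body", "hypo", "down"): "body_hypo_down",
}


@dataclass
class QuadrantTable:
    """Concordant significant probe-gene pairs per integration quadrant.

    ``pairs`` columns: probe_id, gene_id, quadrant, delta_beta, log2fc.
    ``n_discordant`` counts significant pairs whose directions mismatch the
    expected pattern; ``n_unpaired`` significant genic probes whose gene is
    absent from the DE table or not significant.
    """

    pairs: pd.DataFrame
    n_discordant: int
    n_unpaired: int

    def probe_counts(self) -> pd.Series:
        out = self.pairs.groupby("quadrant")["probe_id"].nunique()
        return out.reindex(QUADRANTS, fill_value=0)

    def gene_counts(self) -> pd.Series:
        out = self.pairs.groupby("quadrant")["gene_id"].nunique()
        return out.reindex(QUADRANTS, fill_value=0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probes": self.probe_counts(), "genes": self.gene_counts()}
        )


def promoter_quadrants(
    dm: pd.DataFrame, de: pd.DataFrame, annotation: ProbeAnnotation
) -> QuadrantTable:
    """Classify significant probe-gene pairs into the four quadrants.

    ``dm`` and ``de`` are records tables from the fitted models, computed on
    the subset of cases with both assays available.
    """
    ann = annotation.table
    missing = dm.index.difference(ann.index)
    if len(missing):
        raise ValidationError(f"probes absent from annotation: {list(missing[:10])}")
    sig = dm[dm["significant"]]
    rows = []
    n_discordant = 0
    n_unpaired = 0
    for probe_id, rec in sig.iterrows():
        relation = ann.at[probe_id, "genic_relation"]
        if relation not in ("promoter", "body"):
            continue
        gene = ann.at[probe_id, "gene_symbol"]
        if gene not in de.index or not bool(de.at[gene, "significant"]):
            n_unpaired += 1
            continue
        quadrant = _QUADRANT_OF.get(
            (relation, rec["direction"], de.at[gene, "direction"])
        )
        if quadrant is None:
            n_discordant += 1
            continue
        rows.append(
            (probe_id, gene, quadrant, rec["delta_beta"], de.at[gene, "log2fc"])
        )
    pairs = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "quadrant", "delta_beta", "log2fc"]
    )
    return QuadrantTable(pairs=pairs, n_discordant=n_discordant, n_unpaired=n_unpaired)


def promoter_median_delta_beta(
    dm: pd.DataFrame, annotation: ProbeAnnotation
) -> pd.Series:
    """Per-gene promoter delta beta: for each gene with >= 1 significant
    promoter probe, the median of those probes' delta beta values."""
    ann = annotation.table
    sig = dm[dm["significant"]]
    sub = ann.loc[ann.index.intersection(sig.index)]
    sub = sub[sub["genic_relation"] == "promoter"]
    if sub.empty:
        return pd.Series(dtype=float, name="delta_beta")
    merged = pd.DataFrame(
        {
            "gene": sub["gene_symbol"],
            "delta_beta": sig.loc[sub.index, "delta_beta"],
        }
    )
    out = merged.groupby("gene")["delta_beta"].median()
    out.name = "delta_beta"
    return out


def correlate_promoter_fc(
    gene_delta_beta: pd.Series, de: pd.DataFrame
) -> tuple[float, int]:
    """Pearson correlation between per-gene promoter delta beta and the
    matched genes' log2 fold changes.  Returns (r, n matched genes)."""
    genes = [g for g in gene_delta_beta.index if g in de.index]
    if len(genes) < 3:
        raise ValidationError(f"need >= 3 matched genes, got {len(genes)}")
    x = gene_delta_beta.loc[genes].to_numpy(dtype=float)
    y = de.loc[genes, "log2fc"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("zero variance; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, len(genes)


def enhancer_pairs(
    dm: pd.DataFrame,
    logexpr: pd.DataFrame,
    annotation: ProbeAnnotation,
    sheet: SampleSheet,
    window: int = 500_000,
    k_nearest: int = 10,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Supervised enhancer-gene pairing over significant enhancer probes.

    For each significant differentially methylated probe with the enhancer
    flag, the ``k_nearest`` genes whose TSS lies within ``window`` bp on the
    same chromosome are tested with a one-sided exact Mann-Whitney rank-sum
    test on log expression: a hypomethylated probe may only pair with a gene
    expressed higher in tumors, a hypermethylated probe only with a gene
    expressed lower (direction lock).  P-values are BH-adjusted across all
    tested pairs; pairs with q < ``q_threshold`` are returned with signed
    distance (gene TSS - probe position).
    """
    ann = annotation.table
    if "position" not in ann.columns or ann["position"].isna().any():
        raise ValidationError("annotation lacks probe positions")
    groups = sheet.groups([s for s in logexpr.columns if s in sheet.table.index])
    tumor = list(groups.index[groups == "tumor"])
    normal = list(groups.index[groups == "normal"])
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError("need >= 2 samples per group for enhancer pairing")
    gene_pos = annotation.gene_positions()
    gene_pos = gene_pos.loc[gene_pos.index.isin(logexpr.index)]
    missing = dm.index.difference(ann.index)
    if len(missing):
        raise ValidationError(f"probes absent from annotation: {list(missing[:10])}")
    sig = dm[dm["significant"]]
    enh = sig.loc[ann.loc[sig.index, "enhancer_flag"].to_numpy(dtype=bool)]
    rows = []
    for probe_id, rec in enh.iterrows():
        chrom = ann.at[probe_id, "chromosome"]
        pos = int(ann.at[probe_id, "position"])
        cand = gene_pos[gene_pos["chromosome"] == chrom].copy()
        cand["distance"] = cand["position"] - pos
        cand = cand[cand["distance"].abs() <= window]
        cand = cand.reindex(cand["distance"].abs().sort_values(kind="stable").index)
        cand = cand.iloc[:k_nearest]
        direction = rec["direction"]
        alternative = "greater" if direction == "hypo" else "less"
        gene_dir = "up" if direction == "hypo" else "down"
        for gene, grow in cand.iterrows():
            x = logexpr.loc[gene, tumor].to_numpy(dtype=float)
            y = logexpr.loc[gene, normal].to_numpy(dtype=float)
            try:
                p = float(
                    stats.mannwhitneyu(x, y, alternative=alternative, method="exact").pvalue
                )
            except ValueError:
                p = 1.0
            rows.append(
                (probe_id, gene, direction, gene_dir, int(grow["distance"]), p)
            )
    out = pd.DataFrame(
        rows,
        columns=["probe_id", "gene_id", "probe_direction", "gene_direction", "distance", "p_raw"],
    )
    if out.empty:
        out["p_adj"] = []
        return out
    out["p_adj"] = bh_adjust(out["p_raw"].clip(lower=np.nextafter(0, 1)))
    kept = out[out["p_adj"] < q_threshold].reset_index(drop=True)
    logger.info("enhancer pairing: %d/%d pairs retained", len(kept), len(out))
    return kept
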