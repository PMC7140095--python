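"""Binned-beta Fisher-exact differential methylation caller.

Per probe, the beta values of each sample are binned into low (<= 0.3),
moderate (between the edges) and high (>= 0.7) methylation, a 2 (group) x 3
(bin) contingency table is formed, and a two-sided Fisher exact test is run
on it.  P-values are Benjamini-Hochberg adjusted across all tested probes,
and a probe is called significant when the adjusted p is below alpha AND the
effect |delta beta| = |median(tumor beta) - median(normal beta)| meets the
minimum effect size (default 0.3).  Significant probes with positive delta
beta are hypermethylated, negative ones hypomethylated.

A note on the test: with only bin memberships per group, no t statistic is
defined; the caller therefore uses Fisher's exact test on the 2x3 table.
The two-sided p-value follows the standard probability-mass rule for r x c
tables: the sum, over all tables with the observed margins, of the
multivariate hypergeometric probabilities that do not exceed the observed
table's probability.  The implementation works in exact integer arithmetic
(binomial-coefficient ratios), so tie comparison is exact and needs no
floating-point tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

BINS = ("low", "moderate", "high")
DEFAULT_BIN_EDGES = (0.3, 0.7)
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DELTA_BETA = 0.3


def bin_beta(
    value: float | np.ndarray, edges: tuple[float, float] = DEFAULT_BIN_EDGES
):
    """Assign beta values to the low / moderate / high methylation bins.

    Boundaries are closed as printed: beta <= low edge -> low, beta >= high
    edge -> high, strictly between -> moderate.
    """
    low, high = edges
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValidationError("beta value outside [0, 1]")
    out = np.where(arr <= low, "low", np.where(arr >= high, "high", "moderate"))
    if np.isscalar(value) or arr.ndim == 0:
        return str(out)
    return out


@lru_cache(maxsize=100_000)
def _fisher_2x3_cached(
    row1: tuple[int, int, int], row2: tuple[int, int, int]
) -> float:
    c = tuple(a + b for a, b in zip(row1, row2))
    r1 = sum(row1)
    n = r1 + sum(row2)
    # exact integer arithmetic: P(table) = prod_j C(c_j, x_1j) / C(N, r1)
    obs = comb(c[0], row1[0]) * comb(c[1], row1[1]) * comb(c[2], row1[2])
    denom = comb(n, r1)
    total = 0
    for a in range(min(r1, c[0]) + 1):
        rem = r1 - a
        for b in range(min(rem, c[1]) + 1):
            cc = rem - b
            if cc > c[2]:
                continue
            w = comb(c[0], a) * comb(c[1], b) * comb(c[2], cc)
            if w <= obs:
                total += w
    return total / denom


def fisher_exact_2x3(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test on a 2x3 contingency table.

    Returns the sum of multivariate hypergeometric probabilities, over all
    tables sharing the observed margins, that are <= the observed table's
    probability.  Computed in exact integer arithmetic; the result is in
    (0, 1].
    """
    arr = np.asarray(table)
    if arr.shape != (2, 3):
        raise ValidationError(f"expected a 2x3 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError("contingency table has a negative cell")
    if not np.all(arr == np.round(np.asarray(arr, dtype=float))):
        raise ValidationError("contingency table has a non-integer cell")
    arr = arr.astype(int)
    if arr[0].sum() < 1 or arr[1].sum() < 1:
        raise ValidationError("each group needs at least one sample")
    return _fisher_2x3_cached(tuple(arr[0]), tuple(arr[1]))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = p_(i) * m / i on the ascending order statistics, with
    monotonicity enforced from the largest rank down and values capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def filter_probes(
    beta: BetaMatrix, annotation: ProbeAnnotation
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove cross-reactive probes, probes at common polymorphic sites
    (MAF > 5%), and probes on the sex chromosomes.

    Returns the filtered matrix and per-reason removal counts (a probe
    counted once, under the first matching reason).
    """
    probes = beta.values.index
    missing = probes.difference(annotation.table.index)
    if len(missing):
        raise ValidationError(
            f"probes absent from annotation: {list(missing[:10])}"
        )
    ann = annotation.table.loc[probes]
    cross = ann["cross_reactive_flag"].to_numpy(dtype=bool)
    maf = ann["maf_over_5pct_flag"].to_numpy(dtype=bool)
    sex = ann["chromosome"].isin(["chrX", "chrY"]).to_numpy()
    counts = {
        "cross_reactive": int(cross.sum()),
        "maf_over_5pct": int((maf & ~cross).sum()),
        "sex_chromosome": int((sex & ~maf & ~cross).sum()),
    }
    keep = ~(cross | maf | sex)
    counts["retained"] = int(keep.sum())
    logger.info("probe filters removed %s", counts)
    return BetaMatrix(beta.values.loc[keep]), counts


@dataclass
class ContextSummary:
    """Proportion of probes per genomic-context category for the
    hypermethylated set, the hypomethylated set, and the background (all
    tested probes)."""

    island: pd.DataFrame  # rows: island_relation, cols: hyper/hypo/background
    genic: pd.DataFrame  # rows: genic_relation, cols: hyper/hypo/background


def summarize_context(
    dm: pd.DataFrame, annotation: ProbeAnnotation
) -> ContextSummary:
    """Context proportions for hyper / hypo / background probe sets.

    ``dm`` is the records table from :meth:`DifferentialMethylation.fit`;
    background means every tested probe, not only the significant ones.
    """
    ann = annotation.table.loc[dm.index]

    def _props(mask: pd.Series, column: str, categories: Sequence[str]) -> pd.Series:
        sub = ann.loc[mask, column]
        if len(sub) == 0:
            return pd.Series(np.nan, index=list(categories))
        return sub.value_counts(normalize=True).reindex(list(categories), fill_value=0.0)

    from .io import GENIC_RELATIONS, ISLAND_RELATIONS

    hyper = dm["direction"] == "hyper"
    hypo = dm["direction"] == "hypo"
    background = pd.Series(True, index=dm.index)
    island = pd.DataFrame(
        {
            "hyper": _props(hyper, "island_relation", ISLAND_RELATIONS),
            "hypo": _props(hypo, "island_relation", ISLAND_RELATIONS),
            "background": _props(background, "island_relation", ISLAND_RELATIONS),
        }
    )
    genic = pd.DataFrame(
        {
            "hyper": _props(hyper, "genic_relation", GENIC_RELATIONS),
            "hypo": _props(hypo, "genic_relation", GENIC_RELATIONS),
            "background": _props(background, "genic_relation", GENIC_RELATIONS),
        }
    )
    return ContextSummary(island=island, genic=genic)


class DifferentialMethylation:
    """Tumor-vs-normal differential methylation model on a beta matrix.

    Parameters
    ----------
    beta
        Probes x samples beta matrix (pre-filtered; see
        :func:`filter_probes`).  Probes with a missing value in any retained
        sample are dropped before testing, with a logged count.
    sample_sheet
        Sample metadata; only samples present in ``beta`` are used, and each
        group (tumor / normal) must keep at least two of them.
    alpha
        Adjusted-p significance level (default 0.05).
    min_delta_beta
        Minimum absolute difference of group median betas (default 0.3).
    bin_edges
        Low / high methylation bin boundaries (default 0.3, 0.7; boundaries
        closed outward).
    """

    def __init__(
        self,
        beta: BetaMatrix,
        sample_sheet: SampleSheet,
        alpha: float = DEFAULT_ALPHA,
        min_delta_beta: float = DEFAULT_MIN_DELTA_BETA,
        bin_edges: tuple[float, float] = DEFAULT_BIN_EDGES,
    ) -> None:
        if not 0 <= alpha <= 1:
            raise ValidationError("alpha must be in [0, 1]")
        if not 0 <= min_delta_beta <= 1:
            raise ValidationError("min_delta_beta must be in [0, 1]")
        if not (0 <= bin_edges[0] < bin_edges[1] <= 1):
            raise ValidationError("bin edges must be increasing within [0, 1]")
        self.beta = beta
        self.sample_sheet = sample_sheet
        self.alpha = alpha
        self.min_delta_beta = min_delta_beta
        self.bin_edges = tuple(bin_edges)
        groups = sample_sheet.groups(
            [s for s in beta.sample_ids if s in sample_sheet.table.index]
        )
        self.tumor_samples = list(groups.index[groups == "tumor"])
        self.normal_samples = list(groups.index[groups == "normal"])
        for name, members in (
            ("tumor", self.tumor_samples),
            ("normal", self.normal_samples),
        ):
            if len(members) < 2:
                raise ValidationError(
                    f"need >=2 {name} samples with beta values, got {len(members)}"
                )

    def fit(self) -> "DifferentialMethylationResults":
        values = self.beta.values[self.tumor_samples + self.normal_samples]
        complete = values.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropping %d probes with missing beta values", n_dropped)
        values = values.loc[complete]
        tum = values[self.tumor_samples].to_numpy(dtype=float)
        nor = values[self.normal_samples].to_numpy(dtype=float)
        low, high = self.bin_edges

        def _bins(arr: np.ndarray) -> np.ndarray:
            lo = (arr <= low).sum(axis=1)
            hi = (arr >= high).sum(axis=1)
            mod = arr.shape[1] - lo - hi
            return np.column_stack([lo, mod, hi])

        tbins = _bins(tum)
        nbins = _bins(nor)
        p_raw = np.array(
            [
                _fisher_2x3_cached(tuple(int(x) for x in t), tuple(int(x) for x in n))
                for t, n in zip(tbins, nbins)
            ]
        )
        p_adj = bh_adjust(p_raw)
        delta = np.median(tum, axis=1) - np.median(nor, axis=1)
        significant = (p_adj < self.alpha) & (np.abs(delta) >= self.min_delta_beta)
        direction = np.where(
            significant & (delta > 0),
            "hyper",
            np.where(significant & (delta < 0), "hypo", "none"),
        )
        records = pd.DataFrame(
            {
                "tumor_low": tbins[:, 0],
                "tumor_moderate": tbins[:, 1],
                "tumor_high": tbins[:, 2],
                "normal_low": nbins[:, 0],
                "normal_moderate": nbins[:, 1],
                "normal_high": nbins[:, 2],
                "p_raw": p_raw,
                "p_adj": p_adj,
                "delta_beta": delta,
                "significant": significant,
                "direction": direction,
            },
            index=values.index,
        )
        return DifferentialMethylationResults(self, records, n_dropped)


class DifferentialMethylationResults:
    """Fitted differential-methylation results.

    ``records`` has one row per tested probe with the per-group bin counts,
    raw and BH-adjusted p, delta beta (tumor median - normal median), the
    significance call and the direction (hyper / hypo / none).
    """

    def __init__(
        self, model: DifferentialMethylation, records: pd.DataFrame, n_dropped: int
    ) -> None:
        self.model = model
        self.records = records
        self.n_dropped_missing = n_dropped

    @property
    def n_tested(self) -> int:
        return len(self.records)

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].sum())

    @property
    def n_hyper(self) -> int:
        return int((self.records["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.records["direction"] == "hypo").sum())

    def context_summary(self, annotation: ProbeAnnotation) -> ContextSummary:
        return summarize_context(self.records, annotation)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Differential methylation (binned-beta Fisher exact test)",
            f"  samples: {len(m.tumor_samples)} tumor vs {len(m.normal_samples)} normal",
            f"  bins: low <= {m.bin_edges[0]}, high >= {m.bin_edges[1]}",
            f"  probes tested: {self.n_tested}"
            + (f" ({self.n_dropped_missing} dropped, missing values)" if self.n_dropped_missing else ""),
            f"  significant (BH p < {m.alpha}, |delta beta| >= {m.min_delta_beta}): "
            f"{self.n_significant}",
            f"    hypermethylated: {self.n_hyper}",
            f"    hypomethylated:  {self.n_hypo}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path, seed: int | None = None) -> None:
        from . import __version__

        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# methx v{__version__}" + (f" seed={seed}" if seed is not None else "") + "\n")
            self.records.to_csv(fh, sep="\t", index_label="probe_id", float_format="%.8g")


def call_dm(
    beta: BetaMatrix,
    sheet: SampleSheet,
    alpha: float = DEFAULT_ALPHA,
    min_delta_beta: float = DEFAULT_MIN_DELTA_BETA,
    bin_edges: tuple[float, float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Convenience wrapper: fit :class:`DifferentialMethylation` and return
    the per-probe records table."""
    return DifferentialMethylation(
        beta, sheet, alpha=alpha, min_delta_beta=min_delta_beta, bin_edges=bin_edges
    ).fit().records
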