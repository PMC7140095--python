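"""Expression filtering and negative-binomial differential expression.

The DE test is an in-repo negative-binomial Wald test: per gene, an NB GLM
(log link) with a group covariate and a log library-size offset.  The
gene-wise dispersion is estimated by method of moments on library-size
normalized counts (pooled across the two groups) and floored at 1e-8.  With
~10-15 samples the per-gene estimate is noisy and its downward errors make
the Wald test anticonservative, so two standard small-sample safeguards are
applied: each gene's dispersion is additionally floored at the median of
the per-gene estimates across the matrix (borrowing strength across genes,
in the spirit of edgeR/DESeq2 moderation but far simpler), and the Wald
statistic on the group coefficient is referred to a t distribution with
n_samples - 2 degrees of freedom.  No claim of equivalence with DESeq2's
shrinkage machinery is made; the contract is controlled type-I error plus
BH-adjusted calls at alpha.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import CountMatrix, SampleSheet, ValidationError
from .diffmeth import bh_adjust

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: count * 1e6 / library size (column sum)."""
    c = counts.counts
    lib = c.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValidationError(f"zero library size for sample(s) {bad}")
    return c * 1e6 / lib


def log_cpm(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount); the package-wide log expression measure."""
    return np.log2(cpm(counts) + pseudocount)


def filter_expressed(
    cpm_values: pd.DataFrame,
    sheet: SampleSheet,
    threshold: float = 1.0,
    fraction: float = 0.8,
) -> list[str]:
    """Genes expressed (CPM > threshold) in strictly more than ``fraction``
    of the samples of at least one group."""
    groups = sheet.groups([s for s in cpm_values.columns if s in sheet.table.index])
    keep = pd.Series(False, index=cpm_values.index)
    for name in ("tumor", "normal"):
        members = list(groups.index[groups == name])
        if not members:
            continue
        frac_expressed = (cpm_values[members] > threshold).sum(axis=1) / len(members)
        keep |= frac_expressed > fraction
    return list(cpm_values.index[keep])


def _mom_dispersion(z: np.ndarray, groups: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion from normalized counts.

    Per group g with mean m_g and (ddof=1) variance v_g, alpha_g =
    (v_g - m_g) / m_g^2; pooled by within-group degrees of freedom.
    """
    num = 0.0
    den = 0
    for g in np.unique(groups):
        x = z[groups == g]
        if len(x) < 2:
            continue
        m = x.mean()
        if m <= 0:
            continue
        v = x.var(ddof=1)
        num += (len(x) - 1) * (v - m) / m**2
        den += len(x) - 1
    alpha = num / den if den else 0.0
    return max(alpha, 1e-8)


class NegativeBinomialDE:
    """Tumor-vs-normal negative-binomial Wald differential expression.

    Parameters
    ----------
    counts
        Genes x samples raw counts, ideally pre-filtered with
        :func:`filter_expressed`.
    sample_sheet
        Sample metadata; samples present in ``counts`` are used and each
        group must keep >= 2.
    alpha
        BH-adjusted significance level (default 0.05).
    """

    def __init__(
        self,
        counts: CountMatrix,
        sample_sheet: SampleSheet,
        alpha: float = 0.05,
    ) -> None:
        if not 0 <= alpha <= 1:
            raise ValidationError("alpha must be in [0, 1]")
        self.counts = counts
        self.sample_sheet = sample_sheet
        self.alpha = alpha
        groups = sample_sheet.groups(
            [s for s in counts.sample_ids if s in sample_sheet.table.index]
        )
        self.tumor_samples = list(groups.index[groups == "tumor"])
        self.normal_samples = list(groups.index[groups == "normal"])
        for name, members in (
            ("tumor", self.tumor_samples),
            ("normal", self.normal_samples),
        ):
            if len(members) < 2:
                raise ValidationError(
                    f"need >=2 {name} samples with counts, got {len(members)}"
                )

    def fit(self) -> "NegativeBinomialDEResults":
        order = self.normal_samples + self.tumor_samples
        c = self.counts.counts[order]
        lib = c.sum(axis=0).to_numpy(dtype=float)
        if (lib == 0).any():
            raise ValidationError("zero library size")
        y_all = c.to_numpy(dtype=float)
        is_tumor = np.array([0] * len(self.normal_samples) + [1] * len(self.tumor_samples))
        X = sm.add_constant(is_tumor.astype(float))
        offset = np.log(lib)
        # normalized counts for dispersion: scale to the mean library size
        z_all = y_all / (lib / lib.mean())
        n = len(order)
        df_t = max(n - 2, 1)

        # per-gene MoM dispersions, then a genome-wide floor at their median:
        # with few samples the per-gene estimate is noisy, and its downward
        # errors alone would make the Wald test anticonservative
        disp_own = np.array([_mom_dispersion(z, is_tumor) for z in z_all])
        disp_floor = float(np.median(disp_own)) if len(disp_own) else 1e-8
        dispersions = np.maximum(disp_own, disp_floor)

        log2fc = np.zeros(len(c))
        p_raw = np.ones(len(c))
        converged = np.ones(len(c), dtype=bool)
        for i, y in enumerate(y_all):
            if y.max() == 0:
                converged[i] = False
                continue
            disp = dispersions[i]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.GLM(
                        y,
                        X,
                        family=sm.families.NegativeBinomial(alpha=disp),
                        offset=offset,
                    )
                    res = model.fit(maxiter=100, tol=1e-8)
                if not res.converged:
                    raise RuntimeError("IRLS did not converge")
                coef = res.params[1]
                se = res.bse[1]
                log2fc[i] = coef / _LN2
                if se > 0 and np.isfinite(se):
                    tstat = coef / se
                    p_raw[i] = 2 * stats.t.sf(abs(tstat), df=df_t)
                    p_raw[i] = min(max(p_raw[i], np.nextafter(0, 1)), 1.0)
                else:
                    p_raw[i] = 1.0
            except Exception:
                converged[i] = False
                log2fc[i] = 0.0
                p_raw[i] = 1.0
        n_failed = int((~converged).sum())
        if n_failed:
            logger.info("%d genes flagged non-converged (p set to 1)", n_failed)
        p_adj = bh_adjust(p_raw)
        significant = p_adj < self.alpha
        direction = np.where(
            significant & (log2fc > 0),
            "up",
            np.where(significant & (log2fc < 0), "down", "none"),
        )
        records = pd.DataFrame(
            {
                "log2fc": log2fc,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": significant,
                "direction": direction,
                "converged": converged,
            },
            index=c.index,
        )
        return NegativeBinomialDEResults(self, records)


class NegativeBinomialDEResults:
    """Fitted DE results: one row per gene with log2 fold change (tumor vs
    normal), raw and BH-adjusted p, the significance call and direction."""

    def __init__(self, model: NegativeBinomialDE, records: pd.DataFrame) -> None:
        self.model = model
        self.records = records

    @property
    def n_tested(self) -> int:
        return len(self.records)

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].sum())

    @property
    def n_up(self) -> int:
        return int((self.records["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.records["direction"] == "down").sum())

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "Differential expression (negative-binomial Wald test)",
                f"  samples: {len(m.tumor_samples)} tumor vs {len(m.normal_samples)} normal",
                f"  genes tested: {self.n_tested}",
                f"  significant (BH p < {m.alpha}): {self.n_significant}",
                f"    upregulated:   {self.n_up}",
                f"    downregulated: {self.n_down}",
            ]
        )

    def to_tsv(self, path, seed: int | None = None) -> None:
        from . import __version__

        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# methx v{__version__}"
                + (f" seed={seed}" if seed is not None else "")
                + "\n"
            )
            self.records.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.8g")


def test_de(
    counts: CountMatrix, sheet: SampleSheet, alpha: float = 0.05
) -> pd.DataFrame:
    """Convenience wrapper: fit :class:`NegativeBinomialDE` and return the
    per-gene records table."""
    return NegativeBinomialDE(counts, sheet, alpha=alpha).fit().records
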