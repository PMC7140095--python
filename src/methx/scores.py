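"""Expression signature scores, over-representation analysis and PCA.

Thyroid differentiation score (TDS): per sample, the mean over a
thyroid-function signature of the sample's log2 expression centered on the
normal-group mean; 0 means "like normal thyroid", negative values indicate
dedifferentiation.

BRAF-RAS score (BRS): per sample, Pearson correlation with a RAS-like
centroid minus Pearson correlation with a BRAF-like centroid over the genes
shared with the expression matrix; negative scores are BRAF-like, following
the convention that BRAF-V600E-like tumors score negative.  Centroid
profiles are user-supplied (a synthetic toy pair is packaged for tests);
their provenance is the caller's responsibility.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import GeneSetCollection, SampleSheet, ValidationError
from .diffmeth import bh_adjust

logger = logging.getLogger(__name__)


def read_signature(path: str | Path) -> list[str]:
    """One gene symbol per line (``#`` comments and blanks ignored)."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Three-column TSV: gene, BRAF centroid value, RAS centroid value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "braf" not in cols or "ras" not in cols:
        raise ValidationError(f"{path}: centroid file needs gene/BRAF/RAS columns")
    out = df.set_index(cols["gene"])[[cols["braf"], cols["ras"]]]
    out.columns = ["BRAF", "RAS"]
    return out


def load_synthetic_tds_signature() -> list[str]:
    """Packaged synthetic toy signature (for tests and examples only)."""
    with resources.as_file(
        resources.files("methx.data").joinpath("synthetic_tds_signature.txt")
    ) as p:
        return read_signature(p)


def load_synthetic_brs_centroids() -> pd.DataFrame:
    """Packaged synthetic toy BRAF/RAS centroids (tests and examples only)."""
    with resources.as_file(
        resources.files("methx.data").joinpath("synthetic_brs_centroids.tsv")
    ) as p:
        return read_centroids(p)


def thyroid_differentiation_score(
    logexpr: pd.DataFrame, signature: Sequence[str], sheet: SampleSheet
) -> pd.DataFrame:
    """TDS per sample: mean over signature genes of (log2 expression minus
    the normal-group mean log2 expression).

    Signature genes missing from the matrix are skipped and logged; it is an
    error if none remain.  Requires >= 2 normal samples in the matrix.
    """
    present = [g for g in signature if g in logexpr.index]
    skipped = [g for g in signature if g not in logexpr.index]
    if skipped:
        logger.info("TDS: %d signature genes absent from matrix", len(skipped))
    if not present:
        raise ValidationError("no signature genes present in expression matrix")
    groups = sheet.groups([s for s in logexpr.columns if s in sheet.table.index])
    normals = list(groups.index[groups == "normal"])
    if len(normals) < 2:
        raise ValidationError("TDS needs >= 2 normal samples")
    sub = logexpr.loc[present, list(groups.index)]
    centered = sub.sub(sub[normals].mean(axis=1), axis=0)
    return pd.DataFrame(
        {"sample_id": centered.columns, "score": centered.mean(axis=0).to_numpy()}
    ).set_index("sample_id")


def braf_ras_score(
    logexpr: pd.DataFrame, centroids: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """BRS per sample: corr(sample, RAS centroid) - corr(sample, BRAF
    centroid) over the shared genes; class BRAF_like iff score < 0.

    Requires >= 3 centroid genes present.  A sample with zero variance over
    the shared genes gets score NaN and class NA.
    """
    shared = [g for g in centroids.index if g in logexpr.index]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} centroid genes present; need >= 3"
        )
    groups = sheet.groups([s for s in logexpr.columns if s in sheet.table.index])
    braf = centroids.loc[shared, "BRAF"].to_numpy(dtype=float)
    ras = centroids.loc[shared, "RAS"].to_numpy(dtype=float)
    rows = []
    for sample in groups.index:
        x = logexpr.loc[shared, sample].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(braf) == 0 or np.std(ras) == 0:
            rows.append((sample, np.nan, "NA"))
            continue
        score = stats.pearsonr(x, ras).statistic - stats.pearsonr(x, braf).statistic
        cls = "BRAF_like" if score < 0 else "RAS_like"
        rows.append((sample, float(score), cls))
    return pd.DataFrame(rows, columns=["sample_id", "score", "class"]).set_index(
        "sample_id"
    )


def ora(
    query: Sequence[str],
    universe: Sequence[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    One-sided upper-tail p = P(overlap >= observed) with the universe as the
    urn; gene-set members outside the universe are ignored.  BH-adjusted q
    across sets.  Every query gene must be in the universe.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        raise ValidationError(f"query genes outside universe: {outside[:10]}")
    M, N = len(uni), len(q)
    rows = []
    for name in collection:
        members = [g for g in dict.fromkeys(collection[name]) if g in uni_set]
        n = len(members)
        k = len(set(members) & set(q))
        if n == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, n, N))
            p = min(max(p, np.nextafter(0, 1)), 1.0)
        expected = N * n / M if M else 0.0
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, n, k, fold, p))
    out = pd.DataFrame(
        rows, columns=["set_name", "n_set", "overlap", "fold_enrichment", "p"]
    ).set_index("set_name")
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out


def pca_embed(
    matrix: pd.DataFrame, n_components: int = 2, n_top_features: int = 1000
) -> pd.DataFrame:
    """PCA sample coordinates from a features x samples matrix.

    Uses the ``n_top_features`` highest-variance features, centers them, and
    fixes each component's sign so that its largest-magnitude loading is
    positive (deterministic orientation).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    n_components = min(n_components, matrix.shape[1] - 1, matrix.shape[0])
    var = matrix.var(axis=1)
    top = var.sort_values(ascending=False, kind="stable").index[:n_top_features]
    X = matrix.loc[top].to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
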