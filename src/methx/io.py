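"""Readers, writers and validation for the on-disk formats.

The package works with four tabular inputs:

* a normalized methylation beta-value matrix (probes x samples, TSV),
* a raw gene-level read-count matrix (genes x samples, TSV),
* a probe annotation manifest (CSV) giving each probe's genomic context
  (CpG island relation, genic relation, mapped gene, chromosome, position,
  quality-control flags),
* a sample sheet (CSV) with one row per case: group (tumor/normal) and
  per-assay availability flags,

plus GMT gene-set collections and small signature/centroid tables for the
expression scores.  All writers prepend a ``#``-comment header carrying the
tool version and, when a simulation produced the file, the seed; all readers
skip such comment lines.

Manifest positions are 1-based single-base probe coordinates and are used
directly for distance computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
GENIC_RELATIONS = ("promoter", "body", "intergenic")

# Illumina manifest vocabulary -> our enumerations.  Promoter covers the
# TSS-proximal manifest labels; Body/ExonBnd map to gene body; anything else
# (including 3'UTR and blanks) is treated as intergenic for probe context.
_ISLAND_ALIASES = {
    "island": "island",
    "n_shore": "shore",
    "s_shore": "shore",
    "shore": "shore",
    "n_shelf": "shelf",
    "s_shelf": "shelf",
    "shelf": "shelf",
    "opensea": "open_sea",
    "open_sea": "open_sea",
    "": "open_sea",
}
_GENIC_ALIASES = {
    "tss1500": "promoter",
    "tss200": "promoter",
    "5'utr": "promoter",
    "5utr": "promoter",
    "1stexon": "promoter",
    "promoter": "promoter",
    "body": "body",
    "exonbnd": "body",
    "3'utr": "intergenic",
    "3utr": "intergenic",
    "intergenic": "intergenic",
    "": "intergenic",
}

_TRUTHY = {"yes", "true", "1"}
_FALSY = {"no", "false", "0"}


class ValidationError(ValueError):
    """Raised when an input file violates its format contract."""


def _header_comment(seed: int | None = None) -> str:
    tag = f"# methx v{__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag + "\n"


# ---------------------------------------------------------------------------
# Beta matrix


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta-values in [0, 1].

    Missing values (NaN) are permitted on input; downstream callers drop
    probes with any missing value among retained samples before testing.
    """

    values: pd.DataFrame  # index: probe ids, columns: sample ids

    def __post_init__(self) -> None:
        self.values.index.name = "probe_id"
        self.values.columns.name = None
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in beta matrix: {missing}")
        return BetaMatrix(self.values.loc[:, list(sample_ids)])


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a TSV beta matrix (first column probe ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric beta value ({exc})") from exc
    return BetaMatrix(df)


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        beta.values.to_csv(fh, sep="\t", index_label="probe_id", float_format="%.8g")


# ---------------------------------------------------------------------------
# Count matrix


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            farr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(farr)) or np.any(farr != np.round(farr)):
                i, j = np.argwhere(farr != np.round(farr))[0]
                raise ValidationError(
                    f"non-integer count {farr[i, j]!r} at gene "
                    f"{c.index[i]!r}, sample {c.columns[j]!r}"
                )
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {c.index[i]!r}, sample {c.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"samples not in count matrix: {missing}")
        return CountMatrix(self.counts.loc[:, list(sample_ids)])


def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_count_matrix(
    counts: CountMatrix, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        counts.counts.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Probe annotation manifest


@dataclass
class ProbeAnnotation:
    """Per-probe genomic context.

    Columns of :attr:`table` (indexed by probe id): ``chromosome``,
    ``position`` (1-based), ``island_relation``, ``genic_relation``,
    ``gene_symbol`` (empty string when intergenic), ``enhancer_flag``,
    ``cross_reactive_flag``, ``maf_over_5pct_flag``.
    """

    table: pd.DataFrame

    REQUIRED = (
        "chromosome",
        "position",
        "island_relation",
        "genic_relation",
        "gene_symbol",
        "enhancer_flag",
        "cross_reactive_flag",
        "maf_over_5pct_flag",
    )

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if t.index.has_duplicates:
            raise ValidationError("duplicate probe ids in manifest")
        bad_island = set(t["island_relation"]) - set(ISLAND_RELATIONS)
        if bad_island:
            raise ValidationError(f"unknown island relation(s): {sorted(bad_island)}")
        bad_genic = set(t["genic_relation"]) - set(GENIC_RELATIONS)
        if bad_genic:
            raise ValidationError(f"unknown genic relation(s): {sorted(bad_genic)}")
        genic = t["genic_relation"] != "intergenic"
        sym = t["gene_symbol"].fillna("").astype(str)
        if (genic & (sym == "")).any():
            bad = t.index[genic & (sym == "")].tolist()
            raise ValidationError(f"genic probes without gene symbol: {bad[:5]}")
        if ((~genic) & (sym != "")).any():
            bad = t.index[(~genic) & (sym != "")].tolist()
            raise ValidationError(f"intergenic probes with gene symbol: {bad[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, probe_ids: Sequence[str]) -> "ProbeAnnotation":
        missing = [p for p in probe_ids if p not in self.table.index]
        if missing:
            raise ValidationError(f"probes absent from annotation: {missing[:10]}")
        return ProbeAnnotation(self.table.loc[list(probe_ids)])

    def gene_positions(self) -> pd.DataFrame:
        """Approximate per-gene TSS: chromosome and the minimum position of
        the gene's promoter probes (falling back to any of its probes)."""
        t = self.table[self.table["gene_symbol"] != ""]
        rows = []
        for gene, sub in t.groupby("gene_symbol", sort=True):
            prom = sub[sub["genic_relation"] == "promoter"]
            use = prom if len(prom) else sub
            idx = use["position"].idxmin()
            rows.append((gene, use.loc[idx, "chromosome"], int(use.loc[idx, "position"])))
        return pd.DataFrame(rows, columns=["gene", "chromosome", "position"]).set_index(
            "gene"
        )


def _normalize_enum(raw: object, aliases: Mapping[str, str], kind: str) -> str:
    key = str(raw).strip().lower() if raw is not None and raw == raw else ""
    if key in aliases:
        return aliases[key]
    raise ValidationError(f"unknown {kind} label: {raw!r}")


def _parse_bool(raw: object, column: str) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    key = str(raw).strip().lower()
    if key in _TRUTHY:
        return True
    if key in _FALSY or key == "":
        return False
    raise ValidationError(f"cannot parse boolean {raw!r} in column {column!r}")


def read_manifest(path: str | Path) -> ProbeAnnotation:
    """Read a probe-annotation CSV.

    Required columns: ``probe_id``, ``chromosome``, ``position``,
    ``island_relation``, ``genic_relation``, ``gene_symbol``,
    ``enhancer_flag``, ``cross_reactive_flag``, ``maf_over_5pct_flag``.
    Island and genic labels may use either this package's enumerations or the
    Illumina manifest vocabulary (``N_Shore``, ``TSS200``, ...); an empty
    island label means open sea, an empty genic label intergenic.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if "probe_id" not in df.columns:
        raise ValidationError(f"{path}: manifest needs a probe_id column")
    out = pd.DataFrame(index=pd.Index(df["probe_id"].astype(str), name="probe_id"))
    for col in ("chromosome", "position"):
        if col not in df.columns:
            raise ValidationError(f"{path}: manifest missing column {col!r}")
    out["chromosome"] = df["chromosome"].to_numpy()
    try:
        out["position"] = df["position"].astype(int).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer position ({exc})") from exc
    out["island_relation"] = [
        _normalize_enum(v, _ISLAND_ALIASES, "island relation")
        for v in df.get("island_relation", pd.Series([""] * len(df)))
    ]
    out["genic_relation"] = [
        _normalize_enum(v, _GENIC_ALIASES, "genic relation")
        for v in df.get("genic_relation", pd.Series([""] * len(df)))
    ]
    out["gene_symbol"] = (
        df.get("gene_symbol", pd.Series([""] * len(df))).fillna("").astype(str).to_numpy()
    )
    for col in ("enhancer_flag", "cross_reactive_flag", "maf_over_5pct_flag"):
        series = df.get(col, pd.Series(["No"] * len(df)))
        out[col] = [_parse_bool(v, col) for v in series]
    return ProbeAnnotation(out)


def write_manifest(
    annotation: ProbeAnnotation, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        annotation.table.to_csv(fh, index_label="probe_id")


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleSheet:
    """Per-sample metadata mirroring the cohort table: case id, group
    (tumor/normal), sex, age, survival, and per-assay availability flags."""

    table: pd.DataFrame  # indexed by case_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate case ids in sample sheet")
        for col in ("group", "has_expression", "has_methylation"):
            if col not in t.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        bad = set(t["group"]) - {"tumor", "normal"}
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")

    @property
    def case_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        g = self.table["group"]
        return g.loc[list(sample_ids)] if sample_ids is not None else g

    def tumors(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "tumor"])

    def normals(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "normal"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample-sheet CSV.

    Required columns: ``case_id``, ``group``, ``expression``, ``methylation``
    (Yes/No, case-insensitive).  Optional: ``sex``, ``age``,
    ``survival_months``.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for col in ("case_id", "group", "expression", "methylation"):
        if col not in df.columns:
            raise ValidationError(f"{path}: sample sheet missing column {col!r}")
    if (df["group"].str.strip() == "").any():
        bad = df.loc[df["group"].str.strip() == "", "case_id"].tolist()
        raise ValidationError(f"{path}: missing group for case(s) {bad}")
    out = pd.DataFrame(index=pd.Index(df["case_id"].astype(str), name="case_id"))
    out["group"] = df["group"].str.strip().str.lower().to_numpy()
    out["sex"] = df.get("sex", pd.Series([""] * len(df))).to_numpy()
    out["age"] = pd.to_numeric(
        df.get("age", pd.Series([""] * len(df))), errors="coerce"
    ).to_numpy()
    out["survival_months"] = pd.to_numeric(
        df.get("survival_months", pd.Series([""] * len(df))), errors="coerce"
    ).to_numpy()
    out["has_expression"] = [_parse_bool(v, "expression") for v in df["expression"]]
    out["has_methylation"] = [_parse_bool(v, "methylation") for v in df["methylation"]]
    return SampleSheet(out)


def write_sample_sheet(
    sheet: SampleSheet, path: str | Path, seed: int | None = None
) -> None:
    df = sheet.table.copy()
    df["expression"] = np.where(df.pop("has_expression"), "Yes", "No")
    df["methylation"] = np.where(df.pop("has_methylation"), "Yes", "No")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, index_label="case_id")


def load_table1() -> SampleSheet:
    """The packaged 18-row cohort sheet (14 tumors, 4 normal thyroid tissues)
    with per-assay availability flags."""
    with resources.as_file(
        resources.files("methx.data").joinpath("table1.csv")
    ) as path:
        return read_sample_sheet(path)


def select_samples(
    sheet: SampleSheet,
    require_expression: bool = False,
    require_methylation: bool = False,
) -> tuple[list[str], list[str]]:
    """Return (tumor case ids, normal case ids) satisfying the availability
    requirements, in stable input order."""
    t = sheet.table
    mask = pd.Series(True, index=t.index)
    if require_expression:
        mask &= t["has_expression"]
    if require_methylation:
        mask &= t["has_methylation"]
    tumors = list(t.index[mask & (t["group"] == "tumor")])
    normals = list(t.index[mask & (t["group"] == "normal")])
    return tumors, normals


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics: name, ignored description, members)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterable[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
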