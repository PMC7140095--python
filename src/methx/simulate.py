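"""Synthetic methylome + transcriptome generator with planted ground truth.

The generator emulates the study design that motivates the pipeline: a small
unpaired cohort (10 tumors vs 4 normal thyroid tissues by default) assayed
with a beta-value methylation array and gene-level RNA-seq counts.

* **Manifest** — genes are laid out along autosomes, each with a cluster of
  promoter probes and gene-body probes; intergenic probes (a configurable
  fraction flagged as enhancers) sit between genes; CpG-island relations are
  drawn from a configurable marginal distribution.  Positions are 1-based
  and strictly increasing per chromosome.
* **Methylation** — each probe gets a baseline mean from a bimodal prior
  (low mode around 0.15, high mode around 0.85, mimicking typical array
  bimodality); planted hypermethylated probes shift the tumor mean up by
  ``delta_effect`` (baselines drawn from the low mode so the shift fits in
  [0.02, 0.98]), hypomethylated probes down; per-sample noise is Beta with
  concentration ``beta_precision`` so ``delta_effect`` is an exact mean
  shift.  Differential methylation is planted at the gene level: all
  promoter (or body) probes of a chosen gene share one label, and a gene
  carries at most one differentially methylated probe block.
* **Counts** — gene baselines from a log-normal prior, per-sample library
  factors log-uniform over a 3-fold range, negative-binomial noise.  The
  linkage table plants concordant expression changes for differentially
  methylated genes (promoter hypo -> up, promoter hyper -> down, body hyper
  -> up, body hypo -> down, enhancer hypo -> nearest gene up), then tops up
  independent up/down genes to the configured fractions.

All randomness flows from the single config seed through named substreams,
so adding a later stage never perturbs an earlier stage's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, CountMatrix, ProbeAnnotation, SampleSheet, ValidationError

# named substreams off the config seed
_STREAMS = {"manifest": 0, "methylation": 1, "counts": 2, "sample_sheet": 3}

QUADRANT_LINKS = (
    "promoter_hypo_up",
    "promoter_hyper_down",
    "body_hyper_up",
    "body_hypo_down",
    "enhancer_hypo_up",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


def _default_linkage() -> dict[str, float]:
    return {q: 1.0 for q in QUADRANT_LINKS}


def _default_island_props() -> dict[str, float]:
    return {"island": 0.2, "shore": 0.2, "shelf": 0.1, "open_sea": 0.5}


def _default_genic_props() -> dict[str, float]:
    return {"promoter": 0.25, "body": 0.35, "intergenic": 0.4}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults encode the emulated design: 10 tumor vs 4 normal samples,
    10% hyper- and 10% hypomethylated probes, 10% up- and 10% downregulated
    genes, and full methylation-expression linkage.
    """

    n_probes: int = 2000
    n_genes: int = 2000
    n_tumor: int = 10
    n_normal: int = 4
    frac_hyper: float = 0.1
    frac_hypo: float = 0.1
    delta_effect: float = 0.5  # target |delta beta| of planted probes
    beta_precision: float = 300.0  # Beta noise concentration
    frac_de_up: float = 0.1
    frac_de_down: float = 0.1
    lfc_effect: float = 2.0  # planted |log2 fold change|
    nb_dispersion: float = 0.1
    linkage_table: dict[str, float] = field(default_factory=_default_linkage)
    island_props: dict[str, float] = field(default_factory=_default_island_props)
    genic_props: dict[str, float] = field(default_factory=_default_genic_props)
    enhancer_fraction: float = 0.25  # of intergenic probes flagged enhancer
    frac_cross_reactive: float = 0.0
    frac_maf_over_5pct: float = 0.0
    baseline_log_mean: float = math.log(150.0)  # log-normal count prior
    baseline_log_sigma: float = 1.0
    libsize_fold_range: float = 3.0
    enhancer_link_window: int = 100_000  # bp, probe to planted target TSS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 10:
            raise ValidationError("n_probes must be >= 10")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValidationError("need >= 2 samples per group")
        for name in (
            "frac_hyper",
            "frac_hypo",
            "frac_de_up",
            "frac_de_down",
            "enhancer_fraction",
            "frac_cross_reactive",
            "frac_maf_over_5pct",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.frac_hyper + self.frac_hypo > 1:
            raise ValidationError("frac_hyper + frac_hypo must be <= 1")
        if self.frac_de_up + self.frac_de_down > 1:
            raise ValidationError("frac_de_up + frac_de_down must be <= 1")
        if not 0 <= self.delta_effect <= 0.96:
            raise ValidationError(
                "delta_effect incompatible with beta baseline support [0.02, 0.98]"
            )
        if not self.beta_precision > 0:
            raise ValidationError("beta_precision must be positive")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        for name in ("island_props", "genic_props"):
            props = getattr(self, name)
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
            if any(v < 0 for v in props.values()):
                raise ValidationError(f"{name} has a negative proportion")
        unknown = set(self.linkage_table) - set(QUADRANT_LINKS)
        if unknown:
            raise ValidationError(f"unknown linkage quadrant(s): {sorted(unknown)}")
        if any(not 0 <= v <= 1 for v in self.linkage_table.values()):
            raise ValidationError("linkage fractions must be in [0, 1]")


def recovery_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default parameter-recovery conditions: 2,000 probes and genes,
    10 tumor vs 4 normal, delta_effect 0.6, beta_precision 300, lfc 2."""
    base = dict(
        n_probes=2000,
        n_genes=2000,
        n_tumor=10,
        n_normal=4,
        frac_hyper=0.1,
        frac_hypo=0.1,
        delta_effect=0.6,
        beta_precision=300.0,
        frac_de_up=0.1,
        frac_de_down=0.1,
        lfc_effect=2.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class GroundTruth:
    """Planted labels: per-probe (null/hyper/hypo), per-gene (null/up/down),
    and the planted probe-gene linkage pairs with their quadrant label."""

    probe_labels: pd.Series
    gene_labels: pd.Series
    pairs: pd.DataFrame  # columns: probe_id, gene_id, quadrant
    # per-sample library scale factors drawn by the count generator; kept so
    # planted fold changes can be measured free of compositional bias
    library_factors: pd.Series | None = None

    def planted_probes(self) -> pd.Index:
        return self.probe_labels.index[self.probe_labels != "null"]

    def planted_genes(self) -> pd.Index:
        return self.gene_labels.index[self.gene_labels != "null"]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def simulate_sample_sheet(config: SimulationConfig) -> SampleSheet:
    """Tumor samples T01.. and normals N1.., all with both assays."""
    rng = _rng(config.seed, "sample_sheet")
    rows = []
    for i in range(config.n_tumor):
        rows.append(
            (
                f"T{i + 1:02d}",
                "tumor",
                rng.choice(["F", "M"]),
                int(rng.integers(45, 90)),
                int(rng.integers(0, 19)),
                True,
                True,
            )
        )
    for i in range(config.n_normal):
        rows.append(
            (f"N{i + 1}", "normal", rng.choice(["F", "M"]), int(rng.integers(35, 70)), np.nan, True, True)
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "group",
            "sex",
            "age",
            "survival_months",
            "has_expression",
            "has_methylation",
        ],
    ).set_index("case_id")
    return SampleSheet(df)


def simulate_manifest(config: SimulationConfig) -> ProbeAnnotation:
    """Generate a probe annotation manifest (see module docstring)."""
    rng = _rng(config.seed, "manifest")
    n = config.n_probes
    n_prom = int(round(config.genic_props["promoter"] * n))
    n_body = int(round(config.genic_props["body"] * n))
    n_inter = n - n_prom - n_body
    if n_inter < 0:
        n_body += n_inter
        n_inter = 0

    # genes with probes: ~2 promoter probes each (or 3 body probes if no
    # promoter budget), body probes spread round-robin
    if n_prom > 0:
        m = max(1, n_prom // 2)
    elif n_body > 0:
        m = max(1, n_body // 3)
    else:
        m = 0
    if m > config.n_genes:
        raise ValidationError(
            f"manifest needs {m} genes with probes but n_genes={config.n_genes}"
        )
    genes = _gene_ids(config.n_genes)[:m]
    prom_alloc = np.zeros(m, dtype=int)
    for i in range(n_prom):
        prom_alloc[i % m] += 1
    body_alloc = np.zeros(m, dtype=int)
    for i in range(n_body):
        body_alloc[i % m] += 1
    inter_alloc = np.zeros(max(m, 1), dtype=int)
    for i in range(n_inter):
        inter_alloc[i % len(inter_alloc)] += 1

    chroms = [f"chr{i}" for i in range(1, 23)]
    per_chrom = max(1, math.ceil(max(m, 1) / len(chroms)))
    rows: list[tuple] = []
    probe_no = 0

    def _emit(chrom: str, pos: int, genic: str, gene: str, enhancer: bool) -> None:
        nonlocal probe_no
        probe_no += 1
        rows.append((f"cg{probe_no:07d}", chrom, pos, genic, gene, enhancer))

    cursors = {c: 10_000 for c in chroms}
    for gi in range(max(m, 1)):
        chrom = chroms[min(gi // per_chrom, len(chroms) - 1)]
        tss = cursors[chrom]
        gene = genes[gi] if gi < m else ""
        pos = tss
        for _ in range(prom_alloc[gi] if gi < m else 0):
            _emit(chrom, pos, "promoter", gene, False)
            pos += 200
        pos = tss + 1_000
        for _ in range(body_alloc[gi] if gi < m else 0):
            _emit(chrom, pos, "body", gene, False)
            pos += 800
        pos += 2_000
        for _ in range(inter_alloc[gi]):
            enh = bool(rng.random() < config.enhancer_fraction)
            _emit(chrom, pos, "intergenic", "", enh)
            pos += 3_000
        cursors[chrom] = pos + 50_000

    df = pd.DataFrame(
        rows,
        columns=["probe_id", "chromosome", "position", "genic_relation", "gene_symbol", "enhancer_flag"],
    ).set_index("probe_id")
    cats = list(config.island_props)
    probs = np.array([config.island_props[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    df["island_relation"] = rng.choice(cats, size=len(df), p=probs)
    df["cross_reactive_flag"] = rng.random(len(df)) < config.frac_cross_reactive
    df["maf_over_5pct_flag"] = rng.random(len(df)) < config.frac_maf_over_5pct
    return ProbeAnnotation(
        df[
            [
                "chromosome",
                "position",
                "island_relation",
                "genic_relation",
                "gene_symbol",
                "enhancer_flag",
                "cross_reactive_flag",
                "maf_over_5pct_flag",
            ]
        ]
    )


def _draw_mode(rng: np.random.Generator, size: int, low_mode: bool) -> np.ndarray:
    # Beta-shaped modes with means ~0.15 / ~0.85
    if low_mode:
        return rng.beta(1.5, 8.5, size=size)
    return rng.beta(8.5, 1.5, size=size)


def simulate_methylation(
    config: SimulationConfig, manifest: ProbeAnnotation
) -> tuple[BetaMatrix, GroundTruth]:
    """Generate the beta matrix with planted hyper/hypo probe blocks."""
    rng = _rng(config.seed, "methylation")
    ann = manifest.table
    probes = list(ann.index)
    n = len(probes)
    labels = pd.Series("null", index=pd.Index(probes, name="probe_id"))

    if config.delta_effect > 0:
        # blocks: (gene, relation) for genic probes, singletons otherwise
        blocks: list[tuple[str, list[str]]] = []
        genic = ann[ann["gene_symbol"] != ""]
        for (gene, _rel), sub in genic.groupby(["gene_symbol", "genic_relation"], sort=True):
            blocks.append((gene, list(sub.index)))
        for probe in ann.index[ann["gene_symbol"] == ""]:
            blocks.append(("", [probe]))
        order = rng.permutation(len(blocks))
        n_hyper = int(round(config.frac_hyper * n))
        n_hypo = int(round(config.frac_hypo * n))
        used_genes: set[str] = set()
        assigned = {"hyper": 0, "hypo": 0}
        for bi in order:
            gene, members = blocks[bi]
            if gene and gene in used_genes:
                continue
            if assigned["hyper"] < n_hyper:
                label = "hyper"
            elif assigned["hypo"] < n_hypo:
                label = "hypo"
            else:
                break
            labels.loc[members] = label
            assigned[label] += len(members)
            if gene:
                used_genes.add(gene)

    delta = config.delta_effect
    baseline = np.empty(n)
    is_hyper = (labels == "hyper").to_numpy()
    is_hypo = (labels == "hypo").to_numpy()
    is_null = ~(is_hyper | is_hypo)
    low_mode = rng.random(n) < 0.5
    base_null = np.where(
        low_mode, _draw_mode(rng, n, True), _draw_mode(rng, n, False)
    ).clip(0.02, 0.98)
    baseline[is_null] = base_null[is_null]
    baseline[is_hyper] = _draw_mode(rng, int(is_hyper.sum()), True).clip(
        0.02, 0.98 - delta
    )
    baseline[is_hypo] = _draw_mode(rng, int(is_hypo.sum()), False).clip(
        0.02 + delta, 0.98
    )

    tumor_mean = baseline + delta * is_hyper - delta * is_hypo
    sample_ids = [f"T{i + 1:02d}" for i in range(config.n_tumor)] + [
        f"N{i + 1}" for i in range(config.n_normal)
    ]
    mu = np.column_stack(
        [np.tile(tumor_mean, (config.n_tumor, 1)).T, np.tile(baseline, (config.n_normal, 1)).T]
    )
    k = config.beta_precision
    if np.isinf(k):
        values = mu.copy()
    else:
        values = rng.beta(mu * k, (1 - mu) * k)
    values = np.clip(values, 0.0, 1.0)
    beta = BetaMatrix(pd.DataFrame(values, index=probes, columns=sample_ids))
    truth = GroundTruth(
        probe_labels=labels,
        gene_labels=pd.Series(
            "null", index=pd.Index(_gene_ids(config.n_genes), name="gene_id")
        ),
        pairs=pd.DataFrame(columns=["probe_id", "gene_id", "quadrant"]),
    )
    return beta, truth


_GENE_IMPLICATION = {
    ("promoter", "hypo"): ("up", "promoter_hypo_up"),
    ("promoter", "hyper"): ("down", "promoter_hyper_down"),
    ("body", "hyper"): ("up", "body_hyper_up"),
    ("body", "hypo"): ("down", "body_hypo_down"),
}


def simulate_counts(
    config: SimulationConfig, manifest: ProbeAnnotation, truth: GroundTruth
) -> tuple[CountMatrix, GroundTruth]:
    """Generate the count matrix, planting concordant expression changes for
    linked differentially methylated genes and topping up independent DE
    genes; returns the counts and the updated ground truth."""
    rng = _rng(config.seed, "counts")
    ann = manifest.table
    gene_labels = truth.gene_labels.copy()
    pair_rows: list[tuple[str, str, str]] = []

    # genes carrying a planted DM block (never used for independent DE)
    genic = ann[ann["gene_symbol"] != ""]
    dm_genes: set[str] = set()
    for (gene, rel), sub in genic.groupby(["gene_symbol", "genic_relation"], sort=True):
        block_labels = set(truth.probe_labels.loc[sub.index])
        block_labels.discard("null")
        if not block_labels:
            continue
        (label,) = block_labels
        dm_genes.add(gene)
        implication = _GENE_IMPLICATION.get((rel, label))
        if implication is None:
            continue
        gene_dir, quadrant = implication
        if rng.random() < config.linkage_table.get(quadrant, 0.0):
            gene_labels.loc[gene] = gene_dir
            for probe in sub.index:
                pair_rows.append((probe, gene, quadrant))

    # enhancer linkage: hypo enhancer probe -> nearest untouched gene goes up
    gene_pos = manifest.gene_positions()
    enh_probes = ann.index[
        ann["enhancer_flag"]
        & (truth.probe_labels.loc[ann.index] == "hypo").to_numpy()
    ]
    for probe in enh_probes:
        if rng.random() >= config.linkage_table.get("enhancer_hypo_up", 0.0):
            continue
        chrom = ann.at[probe, "chromosome"]
        pos = int(ann.at[probe, "position"])
        cand = gene_pos[gene_pos["chromosome"] == chrom].copy()
        cand["dist"] = (cand["position"] - pos).abs()
        cand = cand[cand["dist"] <= config.enhancer_link_window]
        cand = cand[
            [
                g not in dm_genes and gene_labels.loc[g] == "null"
                for g in cand.index
            ]
        ]
        if cand.empty:
            continue
        target = cand["dist"].idxmin()
        gene_labels.loc[target] = "up"
        pair_rows.append((probe, target, "enhancer_hypo_up"))

    # independent DE genes, drawn from genes without any DM block
    if config.lfc_effect > 0:
        free = [
            g
            for g in gene_labels.index
            if g not in dm_genes and gene_labels.loc[g] == "null"
        ]
        rng.shuffle(free)
        n_up = int(round(config.frac_de_up * config.n_genes))
        n_down = int(round(config.frac_de_down * config.n_genes))
        need_up = max(0, n_up - int((gene_labels == "up").sum()))
        need_down = max(0, n_down - int((gene_labels == "down").sum()))
        for g in free[:need_up]:
            gene_labels.loc[g] = "up"
        for g in free[need_up : need_up + need_down]:
            gene_labels.loc[g] = "down"
    else:
        gene_labels[:] = "null"
        pair_rows = []

    n_genes = config.n_genes
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, n_genes)
    n_samples = config.n_tumor + config.n_normal
    half = math.log(config.libsize_fold_range) / 2
    lib_factor = np.exp(rng.uniform(-half, half, n_samples))
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal)
    lfc = np.where(
        gene_labels == "up",
        config.lfc_effect,
        np.where(gene_labels == "down", -config.lfc_effect, 0.0),
    )
    mu = base[:, None] * lib_factor[None, :] * np.power(
        2.0, lfc[:, None] * is_tumor[None, :]
    )
    if config.nb_dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu * config.nb_dispersion)
        counts = rng.poisson(lam)
    sample_ids = [f"T{i + 1:02d}" for i in range(config.n_tumor)] + [
        f"N{i + 1}" for i in range(config.n_normal)
    ]
    cm = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=_gene_ids(n_genes), columns=sample_ids)
    )
    updated = GroundTruth(
        probe_labels=truth.probe_labels,
        gene_labels=gene_labels,
        pairs=pd.DataFrame(pair_rows, columns=["probe_id", "gene_id", "quadrant"]),
        library_factors=pd.Series(lib_factor, index=sample_ids, name="library_factor"),
    )
    return cm, updated


@dataclass
class SimulatedData:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    manifest: ProbeAnnotation
    beta: BetaMatrix
    counts: CountMatrix
    sample_sheet: SampleSheet
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run all generators off the single config seed."""
    manifest = simulate_manifest(config)
    beta, truth = simulate_methylation(config, manifest)
    counts, truth = simulate_counts(config, manifest, truth)
    sheet = simulate_sample_sheet(config)
    return SimulatedData(
        config=config,
        manifest=manifest,
        beta=beta,
        counts=counts,
        sample_sheet=sheet,
        truth=truth,
    )
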