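import numpy as np
import pandas as pd
import pytest

import methx as mx
from methx.io import ProbeAnnotation, SampleSheet


@pytest.fixture(scope="session")
def recovery_data():
    """The default parameter-recovery dataset: 2,000 probes / 2,000 genes,
    10 tumor vs 4 normal, delta 0.6, precision 300, lfc 2, full linkage."""
    return mx.simulate_all(mx.recovery_config(seed=1))


@pytest.fixture(scope="session")
def recovery_dm(recovery_data):
    return mx.DifferentialMethylation(
        recovery_data.beta, recovery_data.sample_sheet
    ).fit()


@pytest.fixture(scope="session")
def recovery_de(recovery_data):
    return mx.NegativeBinomialDE(
        recovery_data.counts, recovery_data.sample_sheet
    ).fit()


@pytest.fixture(scope="session")
def small_data():
    """A small, fast dataset for pipeline-level tests."""
    return mx.simulate_all(
        mx.recovery_config(seed=3, n_probes=300, n_genes=300, baseline_log_sigma=0.6)
    )


def make_sheet(tumors, normals):
    rows = [(t, "tumor") for t in tumors] + [(n, "normal") for n in normals]
    df = pd.DataFrame(rows, columns=["case_id", "group"]).set_index("case_id")
    df["has_expression"] = True
    df["has_methylation"] = True
    return SampleSheet(df)


def make_annotation(rows):
    """rows: list of dicts with probe_id plus any annotation fields."""
    defaults = dict(
        chromosome="chr1",
        position=1000,
        island_relation="open_sea",
        genic_relation="intergenic",
        gene_symbol="",
        enhancer_flag=False,
        cross_reactive_flag=False,
        maf_over_5pct_flag=False,
    )
    recs = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r["position"] = 1000 + 100 * i
        r.update(row)
        recs.append(r)
    df = pd.DataFrame(recs).set_index("probe_id")
    return ProbeAnnotation(df)


@pytest.fixture
def swapped_sheet():
    """Factory: relabel tumor<->normal on a SampleSheet."""

    def _swap(sheet):
        df = sheet.table.copy()
        df["group"] = np.where(df["group"] == "tumor", "normal", "tumor")
        return SampleSheet(df)

    return _swap
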