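import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methx as mx
from methx.io import BetaMatrix, ValidationError
from methx.diffmeth import summarize_context

from .conftest import make_annotation, make_sheet
from .oracles import bh_stepup_oracle, fisher_2x3_fraction_oracle, fisher_2x3_subset_oracle


class TestBinBeta:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.3, "low"), (0.7, "high"), (0.5, "moderate"), (0.0, "low"), (1.0, "high"),
         (0.30000001, "moderate"), (0.69999999, "moderate")],
    )
    def test_boundaries_closed_as_defined(self, value, expected):
        assert mx.bin_beta(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mx.bin_beta(1.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_every_beta_lands_in_exactly_one_bin(self, value):
        assert mx.bin_beta(value) in ("low", "moderate", "high")


class TestFisherExact:
    def test_single_consistent_table_gives_p_one(self):
        assert mx.fisher_exact_2x3([[4, 0, 0], [4, 0, 0]]) == 1.0

    def test_maximal_separation_example(self):
        # margins rows (4,4), cols (4,0,4): 2 of 70 equally-likely
        # assignments are as extreme as the observed split
        assert mx.fisher_exact_2x3([[4, 0, 0], [0, 0, 4]]) == pytest.approx(2 / 70, rel=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            mx.fisher_exact_2x3([[1, -1, 2], [1, 1, 1]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mx.fisher_exact_2x3([[0, 0, 0], [1, 2, 3]])

    def test_matches_fraction_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            table = rng.integers(0, 8, size=(2, 3))
            if table[0].sum() < 1 or table[1].sum() < 1:
                continue
            p = mx.fisher_exact_2x3(table)
            oracle = float(fisher_2x3_fraction_oracle(table.tolist()))
            assert p == pytest.approx(oracle, rel=1e-12)

    def test_matches_subset_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 25:
            table = rng.integers(0, 4, size=(2, 3))
            if table[0].sum() < 1 or table[1].sum() < 1 or table.sum() > 10:
                continue
            p = mx.fisher_exact_2x3(table)
            oracle = float(fisher_2x3_subset_oracle(table.tolist()))
            assert p == pytest.approx(oracle, rel=1e-12)
            checked += 1

    def test_matches_r_fisher_test(self, tmp_path):
        tables = [
            [[0, 0, 10], [4, 0, 0]],
            [[3, 4, 3], [1, 2, 1]],
            [[5, 0, 5], [2, 2, 0]],
            [[1, 1, 8], [3, 1, 0]],
        ]
        lines = ["options(digits=15)"]
        for t in tables:
            (a, b, c), (d, e, f) = t
            lines.append(
                f"cat(fisher.test(matrix(c({a},{d},{b},{e},{c},{f}),nrow=2))$p.value, '\\n')"
            )
        script = tmp_path / "fisher.R"
        script.write_text("\n".join(lines) + "\n")
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        r_ps = [float(x) for x in out.stdout.split()]
        for t, r_p in zip(tables, r_ps):
            assert mx.fisher_exact_2x3(t) == pytest.approx(r_p, rel=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6),
           st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
    def test_invariance_under_column_permutation_and_row_swap(self, a, b, c, d, e, f):
        if a + b + c < 1 or d + e + f < 1:
            return
        p = mx.fisher_exact_2x3([[a, b, c], [d, e, f]])
        assert 0 < p <= 1
        assert mx.fisher_exact_2x3([[c, a, b], [f, d, e]]) == pytest.approx(p, rel=1e-12)
        assert mx.fisher_exact_2x3([[d, e, f], [a, b, c]]) == pytest.approx(p, rel=1e-12)


class TestBHAdjust:
    def test_stepup_worked_example(self):
        assert mx.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert mx.bh_adjust([0.5]) == pytest.approx([0.5])

    def test_empty_input_empty_output(self):
        assert len(mx.bh_adjust([])) == 0

    def test_matches_stepup_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 50)).tolist()
            ours = mx.bh_adjust(p)
            assert ours == pytest.approx(bh_stepup_oracle(p), rel=1e-12)
            sm_adj = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(sm_adj, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = mx.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestFilterProbes:
    def test_flagged_and_sex_probes_removed(self):
        ann = make_annotation(
            [
                dict(probe_id="cg1", chromosome="chrX"),
                dict(probe_id="cg2", chromosome="chrY"),
                dict(probe_id="cg3", maf_over_5pct_flag=True),
                dict(probe_id="cg4", cross_reactive_flag=True),
                dict(probe_id="cg5"),
            ]
        )
        df = pd.DataFrame(
            0.5, index=["cg1", "cg2", "cg3", "cg4", "cg5"], columns=["s1", "s2"]
        )
        filtered, removed = mx.filter_probes(BetaMatrix(df), ann)
        assert filtered.probe_ids == ["cg5"]
        assert removed == {
            "cross_reactive": 1,
            "maf_over_5pct": 1,
            "sex_chromosome": 2,
            "retained": 1,
        }

    def test_unannotated_probe_is_an_error(self):
        ann = make_annotation([dict(probe_id="cg1")])
        df = pd.DataFrame(0.5, index=["cg1", "cgX"], columns=["s1"])
        with pytest.raises(ValidationError, match="cgX"):
            mx.filter_probes(BetaMatrix(df), ann)


def _beta_for(tumor_vals, normal_vals, probes=("cgA",)):
    n_t, n_n = len(tumor_vals[0]), len(normal_vals[0])
    tumors = [f"T{i}" for i in range(n_t)]
    normals = [f"N{i}" for i in range(n_n)]
    data = np.hstack([np.asarray(tumor_vals, float), np.asarray(normal_vals, float)])
    df = pd.DataFrame(data, index=list(probes), columns=tumors + normals)
    return BetaMatrix(df), make_sheet(tumors, normals)


class TestCallDM:
    def test_maximal_separation_called_hyper(self):
        beta, sheet = _beta_for([[0.9] * 10], [[0.1] * 4])
        rec = mx.call_dm(beta, sheet)
        row = rec.loc["cgA"]
        assert row["direction"] == "hyper"
        assert row["delta_beta"] == pytest.approx(0.8)
        assert row["significant"]

    def test_identical_groups_not_called(self):
        beta, sheet = _beta_for([[0.1, 0.5, 0.9, 0.1, 0.5, 0.9, 0.1, 0.5, 0.9, 0.5]],
                                [[0.1, 0.5, 0.9, 0.5]])
        rec = mx.call_dm(beta, sheet)
        assert rec.loc["cgA", "direction"] == "none"

    def test_zero_variance_probe_still_tested_with_p_one(self):
        beta, sheet = _beta_for([[0.5] * 10], [[0.5] * 4])
        rec = mx.call_dm(beta, sheet)
        assert rec.loc["cgA", "p_raw"] == 1.0

    def test_small_group_rejected(self):
        beta, sheet = _beta_for([[0.5] * 10], [[0.5]])
        with pytest.raises(ValidationError, match="normal"):
            mx.call_dm(beta, sheet)

    def test_probe_with_missing_value_dropped(self):
        beta, sheet = _beta_for(
            [[0.9] * 10, [0.8] * 10], [[0.1] * 4, [0.2] * 4], probes=["cgA", "cgB"]
        )
        vals = beta.values.copy()
        vals.loc["cgB", "T0"] = np.nan
        rec = mx.call_dm(BetaMatrix(vals), sheet)
        assert list(rec.index) == ["cgA"]

    def test_delta_beta_antisymmetric_under_group_swap(self, swapped_sheet):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(0, 1, size=(20, 14)),
            index=[f"cg{i}" for i in range(20)],
            columns=[f"T{i}" for i in range(10)] + [f"N{i}" for i in range(4)],
        )
        sheet = make_sheet([f"T{i}" for i in range(10)], [f"N{i}" for i in range(4)])
        rec = mx.call_dm(BetaMatrix(df), sheet)
        rec_swapped = mx.call_dm(BetaMatrix(df), swapped_sheet(sheet))
        assert rec["delta_beta"].to_numpy() == pytest.approx(
            -rec_swapped["delta_beta"].to_numpy()
        )
        assert rec["p_raw"].to_numpy() == pytest.approx(rec_swapped["p_raw"].to_numpy())

    def test_alpha_zero_yields_no_calls(self, recovery_data):
        rec = mx.call_dm(recovery_data.beta, recovery_data.sample_sheet, alpha=0.0)
        assert not rec["significant"].any()


class TestResultsInvariants:
    def test_hyper_plus_hypo_equals_significant(self, recovery_dm):
        assert recovery_dm.n_hyper + recovery_dm.n_hypo == recovery_dm.n_significant

    def test_record_invariants(self, recovery_dm):
        rec = recovery_dm.records
        sig = (rec["p_adj"] < 0.05) & (rec["delta_beta"].abs() >= 0.3)
        assert (rec["significant"] == sig).all()
        assert ((rec["direction"] == "hyper") == (sig & (rec["delta_beta"] > 0))).all()
        assert ((rec["direction"] == "hypo") == (sig & (rec["delta_beta"] < 0))).all()

    def test_bin_counts_sum_to_group_sizes(self, recovery_dm):
        rec = recovery_dm.records
        assert (rec[["tumor_low", "tumor_moderate", "tumor_high"]].sum(axis=1) == 10).all()
        assert (rec[["normal_low", "normal_moderate", "normal_high"]].sum(axis=1) == 4).all()

    def test_summary_mentions_counts(self, recovery_dm):
        s = recovery_dm.summary()
        assert str(recovery_dm.n_significant) in s


class TestContextSummary:
    def test_all_hyper_on_islands(self):
        ann = make_annotation(
            [dict(probe_id="cg1", island_relation="island"),
             dict(probe_id="cg2", island_relation="open_sea")]
        )
        dm = pd.DataFrame(
            {"direction": ["hyper", "none"], "significant": [True, False]},
            index=["cg1", "cg2"],
        )
        ctx = summarize_context(dm, ann)
        assert ctx.island.loc["island", "hyper"] == 1.0

    def test_background_uses_all_tested_probes(self, recovery_dm, recovery_data):
        ctx = recovery_dm.context_summary(recovery_data.manifest)
        ann = recovery_data.manifest.table.loc[recovery_dm.records.index]
        expected = (ann["island_relation"] == "island").mean()
        assert ctx.island.loc["island", "background"] == pytest.approx(expected)

    def test_proportions_sum_to_one(self, recovery_dm, recovery_data):
        ctx = recovery_dm.context_summary(recovery_data.manifest)
        for df in (ctx.island, ctx.genic):
            assert df.sum(axis=0).to_numpy() == pytest.approx([1.0, 1.0, 1.0], abs=1e-9)


class TestNullCalibration:
    def test_permuted_labels_control_raw_p(self, recovery_data):
        # mix tumors and normals: exchangeable null per probe
        rng = np.random.default_rng(99)
        samples = list(recovery_data.beta.sample_ids)
        perm = rng.permutation(samples)
        df = recovery_data.sample_sheet.table.loc[perm].copy()
        df.index = pd.Index(samples, name="case_id")
        from methx.io import SampleSheet

        rec = mx.call_dm(recovery_data.beta, SampleSheet(df))
        frac = (rec["p_raw"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(rec))
        assert frac <= 0.05 + 3 * se
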