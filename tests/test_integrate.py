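import numpy as np
import pandas as pd
import pytest

import methx as mx
from methx.io import ValidationError
from methx.diffexpr import log_cpm

from .conftest import make_annotation


def _dm(rows):
    """rows: (probe_id, delta_beta, significant)"""
    df = pd.DataFrame(rows, columns=["probe_id", "delta_beta", "significant"]).set_index(
        "probe_id"
    )
    df["direction"] = np.where(
        ~df["significant"], "none", np.where(df["delta_beta"] > 0, "hyper", "hypo")
    )
    df["p_adj"] = np.where(df["significant"], 0.01, 0.5)
    return df


def _de(rows):
    """rows: (gene_id, log2fc, significant)"""
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "significant"]).set_index(
        "gene_id"
    )
    df["direction"] = np.where(
        ~df["significant"], "none", np.where(df["log2fc"] > 0, "up", "down")
    )
    return df


class TestPromoterQuadrants:
    def setup_method(self):
        self.ann = make_annotation(
            [
                dict(probe_id="p1", genic_relation="promoter", gene_symbol="GA"),
                dict(probe_id="p2", genic_relation="body", gene_symbol="GB"),
                dict(probe_id="p3", genic_relation="promoter", gene_symbol="GC"),
                dict(probe_id="p4", genic_relation="promoter", gene_symbol="GD"),
                dict(probe_id="p5", genic_relation="intergenic"),
            ]
        )

    def test_quadrant_assignment(self):
        dm = _dm([("p1", -0.4, True), ("p2", 0.5, True), ("p3", 0.4, True),
                  ("p4", -0.4, True), ("p5", -0.5, True)])
        de = _de([("GA", 2.0, True), ("GB", 1.5, True), ("GC", -1.0, True),
                  ("GD", 1.0, True)])
        quad = mx.promoter_quadrants(dm, de, self.ann)
        got = dict(zip(quad.pairs["probe_id"], quad.pairs["quadrant"]))
        assert got["p1"] == "promoter_hypo_up"
        assert got["p2"] == "body_hyper_up"
        assert got["p3"] == "promoter_hyper_down"
        # p4: promoter hypo + gene up -> also hypo_up; p5 intergenic ignored
        assert got["p4"] == "promoter_hypo_up"
        assert "p5" not in got

    def test_non_significant_gene_leaves_probe_unpaired(self):
        dm = _dm([("p1", -0.4, True)])
        de = _de([("GA", 2.0, False)])
        quad = mx.promoter_quadrants(dm, de, self.ann)
        assert len(quad.pairs) == 0
        assert quad.n_unpaired == 1

    def test_direction_mismatch_counted_discordant(self):
        dm = _dm([("p1", 0.4, True)])  # promoter hyper
        de = _de([("GA", 2.0, True)])  # gene up -> discordant for promoter
        quad = mx.promoter_quadrants(dm, de, self.ann)
        assert len(quad.pairs) == 0
        assert quad.n_discordant == 1

    def test_gene_absent_from_de_table_is_unpaired_not_error(self):
        dm = _dm([("p1", -0.4, True)])
        de = _de([("OTHER", 2.0, True)])
        quad = mx.promoter_quadrants(dm, de, self.ann)
        assert quad.n_unpaired == 1

    def test_recovery_of_planted_quadrants(self, recovery_data, recovery_dm, recovery_de):
        quad = mx.promoter_quadrants(
            recovery_dm.records, recovery_de.records, recovery_data.manifest
        )
        truth = recovery_data.truth.pairs
        for q in (
            "promoter_hypo_up",
            "promoter_hyper_down",
            "body_hyper_up",
            "body_hypo_down",
        ):
            planted = set(
                map(tuple, truth.loc[truth["quadrant"] == q, ["probe_id", "gene_id"]].values)
            )
            recovered = set(
                map(
                    tuple,
                    quad.pairs.loc[quad.pairs["quadrant"] == q, ["probe_id", "gene_id"]].values,
                )
            )
            assert planted, q
            sens = len(planted & recovered) / len(planted)
            prec = len(planted & recovered) / len(recovered)
            assert sens >= 0.8, (q, sens)
            assert prec >= 0.8, (q, prec)

    def test_label_swap_maps_quadrants(self, small_data, swapped_sheet):
        dm = mx.call_dm(small_data.beta, small_data.sample_sheet)
        de = mx.test_de(small_data.counts, small_data.sample_sheet)
        dm_s = mx.call_dm(small_data.beta, swapped_sheet(small_data.sample_sheet))
        de_s = mx.test_de(small_data.counts, swapped_sheet(small_data.sample_sheet))
        quad = mx.promoter_quadrants(dm, de, small_data.manifest)
        quad_s = mx.promoter_quadrants(dm_s, de_s, small_data.manifest)
        mapping = {
            "promoter_hypo_up": "promoter_hyper_down",
            "promoter_hyper_down": "promoter_hypo_up",
            "body_hyper_up": "body_hypo_down",
            "body_hypo_down": "body_hyper_up",
        }
        orig = {
            (r.probe_id, r.gene_id): r.quadrant for r in quad.pairs.itertuples()
        }
        swapped = {
            (r.probe_id, r.gene_id): r.quadrant for r in quad_s.pairs.itertuples()
        }
        assert set(orig) == set(swapped)
        for key, q in orig.items():
            assert swapped[key] == mapping[q]


class TestPromoterMedianDeltaBeta:
    def setup_method(self):
        self.ann = make_annotation(
            [
                dict(probe_id=f"p{i}", genic_relation="promoter", gene_symbol=g)
                for i, g in enumerate(["GA", "GB", "GB", "GB", "GC", "GC"])
            ]
        )

    def test_median_rules(self):
        dm = _dm(
            [
                ("p0", 0.4, True),
                ("p1", -0.4, True),
                ("p2", -0.5, True),
                ("p3", -0.6, True),
                ("p4", 0.3, True),
                ("p5", 0.5, True),
            ]
        )
        med = mx.promoter_median_delta_beta(dm, self.ann)
        assert med["GA"] == pytest.approx(0.4)  # singleton
        assert med["GB"] == pytest.approx(-0.5)  # odd count
        assert med["GC"] == pytest.approx(0.4)  # even-count midpoint

    def test_only_significant_promoter_probes_used(self):
        dm = _dm([("p0", 0.4, False), ("p1", -0.4, True)])
        med = mx.promoter_median_delta_beta(dm, self.ann)
        assert "GA" not in med.index
        assert med["GB"] == pytest.approx(-0.4)


class TestCorrelatePromoterFc:
    def test_collinear_pairs_give_r_minus_one(self):
        db = pd.Series({"GA": -0.4, "GB": -0.3, "GC": -0.5})
        de = _de([("GA", 2.0, True), ("GB", 1.5, True), ("GC", 2.5, True)])
        r, n = mx.correlate_promoter_fc(db, de)
        assert r == pytest.approx(-1.0, abs=1e-9)
        assert n == 3

    def test_constant_delta_beta_is_an_error(self):
        db = pd.Series({"GA": -0.4, "GB": -0.4, "GC": -0.4})
        de = _de([("GA", 2.0, True), ("GB", 1.5, True), ("GC", 2.5, True)])
        with pytest.raises(ValidationError, match="variance"):
            mx.correlate_promoter_fc(db, de)

    def test_too_few_pairs_is_an_error(self):
        db = pd.Series({"GA": -0.4, "GB": -0.3})
        de = _de([("GA", 2.0, True), ("GB", 1.5, True)])
        with pytest.raises(ValidationError, match=">= 3"):
            mx.correlate_promoter_fc(db, de)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(10)]
        db = pd.Series(rng.uniform(-0.6, -0.3, 10), index=genes)
        de = _de([(g, v, True) for g, v in zip(genes, rng.normal(2, 0.5, 10))])
        r1, _ = mx.correlate_promoter_fc(db, de)
        r2, _ = mx.correlate_promoter_fc(db * 3 + 1, de)
        assert r1 == pytest.approx(r2)

    def test_negative_on_synthetic_linkage(self, recovery_data, recovery_dm, recovery_de):
        med = mx.promoter_median_delta_beta(recovery_dm.records, recovery_data.manifest)
        r, n = mx.correlate_promoter_fc(med, recovery_de.records)
        assert r < 0
        assert n >= 3


class TestEnhancerPairs:
    def test_planted_enhancer_pairs_recovered(self, recovery_data, recovery_dm):
        pairs = mx.enhancer_pairs(
            recovery_dm.records,
            log_cpm(recovery_data.counts),
            recovery_data.manifest,
            recovery_data.sample_sheet,
        )
        truth = recovery_data.truth.pairs
        planted = set(
            map(
                tuple,
                truth.loc[truth["quadrant"] == "enhancer_hypo_up", ["probe_id", "gene_id"]].values,
            )
        )
        recovered = set(map(tuple, pairs[["probe_id", "gene_id"]].values))
        assert planted
        assert len(planted & recovered) / len(planted) >= 0.8

    def test_direction_lock(self, recovery_data, recovery_dm):
        pairs = mx.enhancer_pairs(
            recovery_dm.records,
            log_cpm(recovery_data.counts),
            recovery_data.manifest,
            recovery_data.sample_sheet,
        )
        hypo = pairs[pairs["probe_direction"] == "hypo"]
        hyper = pairs[pairs["probe_direction"] == "hyper"]
        assert (hypo["gene_direction"] == "up").all()
        assert (hyper["gene_direction"] == "down").all()
        assert (pairs["distance"].abs() <= 500_000).all()

    def test_no_gene_in_window_no_pair(self, recovery_data, recovery_dm):
        pairs = mx.enhancer_pairs(
            recovery_dm.records,
            log_cpm(recovery_data.counts),
            recovery_data.manifest,
            recovery_data.sample_sheet,
            window=1,
        )
        assert len(pairs) == 0

    def test_missing_positions_is_an_error(self, recovery_data, recovery_dm):
        broken = recovery_data.manifest.table.copy()
        broken["position"] = np.nan
        from methx.io import ProbeAnnotation

        ann = ProbeAnnotation(broken)
        with pytest.raises(ValidationError, match="position"):
            mx.enhancer_pairs(
                recovery_dm.records,
                log_cpm(recovery_data.counts),
                ann,
                recovery_data.sample_sheet,
            )
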