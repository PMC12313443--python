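"""Randomization nulls and Cohen's-d SES: conservation, calibration, determinism."""

import numpy as np
import pytest

from conftest import make_record
from gutweb.design import DesignSpec, WebUnitKey
from gutweb.nullmodels import (
    NullConfig,
    cohens_d_ses,
    null_distribution,
    run_ses,
    ses_table,
    shuffle_detections,
)
from gutweb.synthetic import SyntheticParams, simulate_detections
from gutweb.webs import build_webs, remove_self_detections


def simulate_clean(design, **kw):
    params = SyntheticParams(design=design, **kw)
    return remove_self_detections(simulate_detections(params), design.self_detection_map)


def column_sums(records, design):
    return {
        t: sum(r.detections[t] for r in records) for t in design.prey_targets
    }


class TestShuffleDetections:
    def test_prey_label_shuffle_conserves_column_sums_and_structure(self, small_design):
        records = simulate_clean(small_design, seed=0)
        out = shuffle_detections(records, small_design, NullConfig(seed=1))
        assert column_sums(out, small_design) == column_sums(records, small_design)
        assert [(r.unit, r.predator_species) for r in out] == [
            (r.unit, r.predator_species) for r in records
        ]

    def test_cell_shuffle_conserves_grand_total(self, small_design):
        records = simulate_clean(small_design, seed=0)
        cfg = NullConfig(strategy="cell_shuffle", seed=1)
        out = shuffle_detections(records, small_design, cfg)
        total = sum(sum(r.detections.values()) for r in records)
        assert sum(sum(r.detections.values()) for r in out) == total

    def test_shuffled_data_stay_self_detection_free(self, small_design):
        records = simulate_clean(small_design, seed=2)
        for strategy in ("prey_label_shuffle", "cell_shuffle", "within_unit_shuffle"):
            out = shuffle_detections(records, small_design, NullConfig(strategy=strategy, seed=3))
            for r in out:
                tgt = small_design.self_detection_map.get(r.predator_species)
                assert r.detections[tgt] == 0

    def test_identical_vectors_make_shuffling_a_no_op_on_webs(self, tiny_design, unit):
        # when every individual carries the same detection vector, any
        # recombination returns an equivalent dataset and identical webs
        records = [
            make_record(unit, sp, ["Collembola"], tiny_design)
            for sp in ("Poecilus", "Araneae") for _ in range(3)
        ]
        for strategy in ("prey_label_shuffle", "within_unit_shuffle"):
            out = shuffle_detections(records, tiny_design, NullConfig(strategy=strategy, seed=4))
            (w0,) = build_webs(records, tiny_design)
            (w1,) = build_webs(out, tiny_design)
            np.testing.assert_array_equal(w0.matrix, w1.matrix)
        # cell_shuffle moves mass between prey columns, so the equivalence
        # there needs every eligible cell to hold the same value
        all_pos = [
            make_record(unit, sp, ["Collembola", "Oligochaeta", "Poecilus"], tiny_design)
            for sp in ("Poecilus", "Araneae") for _ in range(3)
        ]
        from gutweb.webs import remove_self_detections as _clean

        all_pos = _clean(all_pos, tiny_design.self_detection_map)
        out = shuffle_detections(all_pos, tiny_design, NullConfig(strategy="cell_shuffle", seed=4))
        (w0,) = build_webs(all_pos, tiny_design)
        (w1,) = build_webs(out, tiny_design)
        np.testing.assert_array_equal(w0.matrix, w1.matrix)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            NullConfig(strategy="bogus")


class TestNullDistribution:
    def test_reproducible_from_seed(self, small_design):
        records = simulate_clean(small_design, seed=1)
        unit = records[0].unit
        cfg = NullConfig(n_randomizations=11, seed=5)
        a, inv_a = null_distribution(records, small_design, unit, cfg)
        b, inv_b = null_distribution(records, small_design, unit, cfg)
        np.testing.assert_array_equal(a, b)
        assert inv_a == inv_b

    def test_fast_path_matches_explicit_shuffle_rebuild(self, tiny_design):
        # the per-unit hypergeometric sampler must define the same null as
        # literally shuffling the records and rebuilding the web
        units = [WebUnitKey("2020", "F1", "fertilized", "P1", s) for s in (1, 2)]
        rng = np.random.default_rng(0)
        records = []
        for u in units:
            for sp in ("Poecilus", "Araneae"):
                for _ in range(6):
                    pos = [t for t in tiny_design.prey_targets
                           if rng.random() < 0.4 and t != tiny_design.self_detection_map.get(sp)]
                    records.append(make_record(u, sp, pos, tiny_design))
        from gutweb.specialization import h2_prime

        cfg = NullConfig(n_randomizations=600, seed=7)
        fast, _ = null_distribution(records, tiny_design, units[0], cfg)
        slow = []
        rng2 = np.random.default_rng(8)
        for _ in range(600):
            shuffled = shuffle_detections(records, tiny_design, cfg, rng=rng2)
            web = [w for w in build_webs(shuffled, tiny_design) if w.unit == units[0]][0]
            res = h2_prime(web)
            if res.valid:
                slow.append(res.H2prime)
        slow = np.array(slow)
        se = np.sqrt(fast.var() / len(fast) + slow.var() / len(slow))
        assert abs(fast.mean() - slow.mean()) < 4 * se + 1e-6

    def test_single_species_unit_raises(self, tiny_design, unit):
        records = [make_record(unit, "Araneae", ["Collembola"], tiny_design)
                   for _ in range(3)]
        cfg = NullConfig(n_randomizations=5, seed=0)
        with pytest.raises(ValueError, match="invalid"):
            null_distribution(records, tiny_design, unit, cfg)


class TestCohensD:
    def test_zero_when_observed_equals_null_mean(self):
        draws = np.array([0.2, 0.4, 0.6])
        res = cohens_d_ses(0.4, draws)
        assert res.ses_d == pytest.approx(0.0)

    def test_two_sd_above_gives_two(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.5, 0.1, 500)
        obs = draws.mean() + 2 * draws.std(ddof=1)
        assert cohens_d_ses(obs, draws).ses_d == pytest.approx(2.0)

    def test_zero_sd_flagged(self):
        res = cohens_d_ses(0.9, np.array([0.5, 0.5, 0.5]))
        assert res.flag == "zero_sd" and np.isnan(res.ses_d)


class TestRunSES:
    def test_order_independent_and_byte_identical(self, small_design, tmp_path):
        from gutweb.io import write_table

        records = simulate_clean(small_design, seed=3)
        cfg = NullConfig(n_randomizations=49, seed=11)
        res_fwd = run_ses(records, small_design, cfg)
        res_rev = run_ses(records[::-1], small_design, cfg)
        write_table(ses_table(res_fwd), tmp_path / "a.csv")
        write_table(ses_table(res_rev), tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_empty_records_give_empty_result(self, small_design):
        assert run_ses([], small_design, NullConfig(seed=0)) == []

    def test_strongly_concentrated_preferences_give_positive_ses(self, small_design):
        records = simulate_clean(
            small_design, seed=4,
            preference_concentration_by_session={1: 0.05, 2: 0.05, 3: 0.05},
        )
        res = run_ses(records, small_design, NullConfig(n_randomizations=199, seed=12))
        d = [r.ses_d for r in res if r.flag == ""]
        assert len(d) >= 8
        assert np.mean(d) > 0

    def test_mean_ses_decreases_with_generative_kappa(self):
        # smaller kappa = more concentrated diets = stronger specialization signal
        design = DesignSpec(
            years=["2020"], fields_per_year=1, treatments=["fertilized", "unfertilized"],
            plots_per_treatment=2, sessions_per_year={"2020": 2},
        )
        means = []
        for kappa in (0.05, 0.5, 5.0):
            records = simulate_clean(
                design, seed=5,
                preference_concentration_by_session={1: kappa, 2: kappa},
            )
            res = run_ses(records, design, NullConfig(n_randomizations=99, seed=13))
            means.append(np.mean([r.ses_d for r in res if r.flag == ""]))
        assert means[0] > means[1] > means[2]
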