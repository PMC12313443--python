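"""Generator behaviour: concentration dial, determinism, sampling means."""

import math

import numpy as np
import pytest

from gutweb.design import DesignSpec, enumerate_units
from gutweb.synthetic import (
    SyntheticParams,
    simulate_community,
    simulate_detections,
    simulate_species_preferences,
)


def flat_kappa(design, value):
    return {s: value for s in range(1, max(design.sessions_per_year.values()) + 1)}


class TestPreferences:
    def test_large_kappa_approaches_availability(self, small_design):
        params = SyntheticParams(
            design=small_design,
            preference_concentration_by_session=flat_kappa(small_design, 1e6),
        )
        w = np.array([params.base_prey_availability[t] for t in small_design.prey_targets])
        w = w / w.sum()
        rng = np.random.default_rng(0)
        draws = [
            simulate_species_preferences(params, "Poecilus", 1, "unfertilized", rng=rng)
            for _ in range(100)
        ]
        assert np.abs(np.mean(draws, axis=0) - w).max() < 0.01

    def test_small_kappa_concentrates_on_one_target(self, small_design):
        params = SyntheticParams(
            design=small_design,
            preference_concentration_by_session=flat_kappa(small_design, 0.01),
        )
        rng = np.random.default_rng(0)
        hits = sum(
            simulate_species_preferences(params, "Poecilus", 1, "unfertilized", rng=rng).max()
            > 0.95
            for _ in range(200)
        )
        assert hits > 0.9 * 200

    def test_fixed_seed_identical_vectors(self, small_design):
        params = SyntheticParams(design=small_design, seed=7)
        a = simulate_species_preferences(params, "Harpalus", 2, "fertilized")
        b = simulate_species_preferences(params, "Harpalus", 2, "fertilized")
        np.testing.assert_array_equal(a, b)
        assert abs(a.sum() - 1.0) < 1e-12

    def test_nonpositive_kappa_rejected(self, small_design):
        with pytest.raises(ValueError, match="> 0"):
            SyntheticParams(
                design=small_design,
                preference_concentration_by_session={1: 0.0, 2: 1.0, 3: 1.0},
            )

    def test_treatment_multiplier_shifts_detritivore_mass(self, small_design):
        params = SyntheticParams(
            design=small_design,
            preference_concentration_by_session=flat_kappa(small_design, 1e6),
            treatment_availability_multiplier={"fertilized": 4.0, "unfertilized": 1.0},
        )
        rng = np.random.default_rng(0)
        fert = np.mean(
            [simulate_species_preferences(params, "Poecilus", 1, "fertilized", rng=rng)
             for _ in range(50)], axis=0)
        unfert = np.mean(
            [simulate_species_preferences(params, "Poecilus", 1, "unfertilized", rng=rng)
             for _ in range(50)], axis=0)
        j = small_design.prey_targets.index("Collembola")
        assert fert[j] > 2 * unfert[j]


class TestDetections:
    def test_zero_capture_rate_gives_empty_list(self, small_design):
        params = SyntheticParams(design=small_design, individuals_per_species_per_unit=0.0)
        assert simulate_detections(params) == []

    def test_mean_positives_matches_binarized_multinomial_oracle(self):
        # Independent oracle: an individual draws k ~ Poisson(lam) prey data
        # points over S equally likely targets; after collapsing to binary
        # presence the expected number of positives is S * (1 - exp(-lam/S)).
        design = DesignSpec(
            years=["y"], fields_per_year=1, treatments=["t"], plots_per_treatment=1,
            sessions_per_year={"y": 1}, self_detection_map={},
        )
        S = len(design.prey_targets)
        lam = 2.0
        expected = S * (1 - math.exp(-lam / S))
        params = SyntheticParams(
            design=design,
            individuals_per_species_per_unit=1500.0,  # ~10,500 individuals total
            detections_per_individual=lam,
            preference_concentration_by_session={1: 1e7},  # uniform preferences
            seed=0,
        )
        records = simulate_detections(params)
        positives = np.array([sum(r.detections.values()) for r in records])
        se = positives.std(ddof=1) / np.sqrt(len(positives))
        assert abs(positives.mean() - expected) < 3 * se + 1e-9

    def test_one_year_field_design_spans_all_168_units(self):
        design = DesignSpec(
            years=["2020"], fields_per_year=3, treatments=["fertilized", "unfertilized"],
            plots_per_treatment=4, sessions_per_year={"2020": 7},
        )
        params = SyntheticParams(design=design, seed=0)
        units = {r.unit for r in simulate_detections(params)}
        assert units == set(enumerate_units(design, "2020"))
        assert len(units) == 168

    def test_self_detections_absent_by_default_injectable_by_flag(self, small_design):
        params = SyntheticParams(design=small_design, seed=3,
                                 individuals_per_species_per_unit=5.0)
        for r in simulate_detections(params):
            tgt = small_design.self_detection_map.get(r.predator_species)
            assert r.detections[tgt] == 0
        params2 = SyntheticParams(design=small_design, seed=3,
                                  individuals_per_species_per_unit=5.0,
                                  inject_self_detections=True)
        assert any(
            r.detections[small_design.self_detection_map[r.predator_species]] == 1
            for r in simulate_detections(params2)
        )

    def test_dataset_is_pure_function_of_params(self, small_design):
        a = simulate_detections(SyntheticParams(design=small_design, seed=5))
        b = simulate_detections(SyntheticParams(design=small_design, seed=5))
        assert a == b
        c = simulate_detections(SyntheticParams(design=small_design, seed=6))
        assert a != c


class TestCommunity:
    def test_flat_huge_means_give_near_maximal_diversity(self):
        design = DesignSpec(
            years=["y"], fields_per_year=1, treatments=["t"], plots_per_treatment=1,
            sessions_per_year={"y": 1},
        )
        taxa = [f"x{i}" for i in range(6)]
        params = SyntheticParams(
            design=design, seed=0,
            community_abundance_profile={t: 10000.0 for t in taxa},
            tiller_aphid_profile={}, community_dispersion=1000.0,
            detritivore_targets=(),
        )
        sample = simulate_community(params)[0]
        counts = np.array([sample.pitfall_counts[t] for t in taxa], dtype=float)
        p = counts / counts.sum()
        H = -(p * np.log(p)).sum()
        assert abs(H - math.log(6)) < 0.05

    def test_zero_mean_taxon_never_appears(self, small_design):
        profile = {"Collembola": 5.0, "Gastropoda": 0.0}
        params = SyntheticParams(design=small_design, seed=2,
                                 community_abundance_profile=profile,
                                 detritivore_targets=())
        for s in simulate_community(params):
            assert s.pitfall_counts["Gastropoda"] == 0

    def test_fixed_seed_reproducible(self, small_design):
        a = simulate_community(SyntheticParams(design=small_design, seed=9))
        b = simulate_community(SyntheticParams(design=small_design, seed=9))
        assert a == b
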