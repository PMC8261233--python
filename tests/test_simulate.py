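"""Synthetic-cytometry generator: parameter validation, reproducibility,
population bookkeeping and the Hill dose-response."""

import collections
import dataclasses

import numpy as np
import pandas as pd
import pytest

from flowmod import (
    CohortConfig,
    SerumSample,
    SimParams,
    effective_concentration_pM,
    hill_internalized_fraction,
    simulate_cohort,
    simulate_dilution_series,
    simulate_well,
)
from flowmod.simulate import (
    DEFAULT_GROUP_SIZES,
    SimulationError,
    make_cohort_samples,
    serum_nuisance_effect,
)


class TestParamValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sum to 1"):
            SimParams(viable_fraction=0.5)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_events_per_well": 0}, "n_events_per_well"),
            ({"modulation_k": np.nan}, "modulation_k"),
            ({"hill": np.inf}, "hill"),
            ({"viable_fraction": -0.1, "dead_fraction": 0.18}, "viable_fraction"),
        ],
    )
    def test_bad_parameters_name_the_field(self, kwargs, field):
        with pytest.raises(SimulationError, match=field):
            SimParams(**kwargs)

    def test_unknown_role_rejected(self, small_params, healthy_sample):
        with pytest.raises(SimulationError, match="role"):
            simulate_well(healthy_sample, 20, "stained", small_params, 0)

    def test_negative_dilution_rejected(self, small_params, healthy_sample):
        with pytest.raises(SimulationError, match="dilution"):
            simulate_well(healthy_sample, -20, "unstained", small_params, 0)

    def test_serum_sample_invariants(self):
        with pytest.raises(SimulationError):
            SerumSample("x", "healthy", true_conc_pM=-1)
        with pytest.raises(SimulationError):
            SerumSample("x", "healthy", ria_pM=0.0)


class TestReproducibilityAndBookkeeping:
    def test_same_seed_bitwise_identical(self, small_params, healthy_sample):
        a = simulate_well(healthy_sample, 20, "test", small_params, 3)
        b = simulate_well(healthy_sample, 20, "test", small_params, 3)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert (a.labels == b.labels).all()

    def test_population_counts_follow_multinomial_draw(self, small_params, healthy_sample):
        """Subpopulation counts equal the seeded multinomial draw exactly."""
        table = simulate_well(healthy_sample, 20, "test", small_params, 3)
        counts = collections.Counter(table.labels)
        rng = np.random.default_rng(
            np.random.SeedSequence([small_params.seed, 101, 3])
        )
        expected = rng.multinomial(
            small_params.n_events_per_well,
            [0.70, 0.15, 0.07, 0.08],
        )
        assert [counts[k] for k in ("viable", "debris", "doublet", "dead")] == list(
            expected
        )

    def test_unstained_control_independent_of_serum(self, small_params):
        """The unstained well's PE distribution must not depend on which
        serum shares the plate."""
        s1 = SerumSample("A", "healthy")
        s2 = SerumSample("B", "seropositive_AAG", true_conc_pM=2000.0, ria_pM=2000.0)
        a = simulate_well(s1, 20, "unstained", small_params, 5)
        b = simulate_well(s2, 20, "unstained", small_params, 5)
        pd.testing.assert_frame_equal(a.events, b.events)


class TestDoseResponse:
    def test_unstained_pe_is_pure_autofluorescence(self, small_params, positive_sample):
        """Gain is forced to zero: PE matches the lognormal autofluorescence
        model regardless of the serum."""
        table = simulate_well(positive_sample, 20, "unstained", small_params, 7)
        pe = np.log(table.events["PE-A"])
        assert abs(pe.mean() - small_params.autofluor_mean_log) < 0.05
        assert abs(pe.std() - small_params.autofluor_sd_log) < 0.05

    def test_zero_concentration_matches_max_stained(self, small_params):
        """An antibody-free test serum with no nuisance effect reproduces the
        maximally stained control in distribution."""
        params = dataclasses.replace(
            small_params, negative_serum_effect_mean=0.0, negative_serum_effect_sd=0.0
        )
        neg = SerumSample("NEG", "healthy")
        test = simulate_well(neg, 20, "test", params, 9)
        maxs = simulate_well(neg, 20, "max_stained", params, 9)
        viable_t = test.events.loc[test.labels == "viable", "PE-A"]
        viable_m = maxs.events.loc[maxs.labels == "viable", "PE-A"]
        assert abs(np.log(viable_t).mean() - np.log(viable_m).mean()) < 0.05

    def test_half_maximal_internalization_at_k(self):
        """c = K with hill=1, M_max=0.95 gives an internalized fraction of
        exactly 0.475, and the Monte-Carlo mean receptor loss agrees."""
        params = SimParams(modulation_k=1000.0)
        assert hill_internalized_fraction(1000.0, params) == pytest.approx(0.475)

        # brute-force per-event check: mean PE excess of a serum at c=K vs
        # the max-stained well is (1 - 0.475) of the receptor signal
        params = dataclasses.replace(
            params,
            n_events_per_well=100_000,
            negative_serum_effect_mean=0.0,
            negative_serum_effect_sd=0.0,
            seed=2,
        )
        at_k = SerumSample("K", "seropositive_AAG", true_conc_pM=1000.0, ria_pM=1000.0)
        test = simulate_well(at_k, 20, "test", params, 1)
        maxs = simulate_well(at_k, 20, "max_stained", params, 2)
        unst = simulate_well(at_k, 20, "unstained", params, 3)

        def receptor_signal(t):
            return t.events.loc[t.labels == "viable", "PE-A"].mean()

        autofluor = receptor_signal(unst)
        ratio = (receptor_signal(test) - autofluor) / (
            receptor_signal(maxs) - autofluor
        )
        assert ratio == pytest.approx(1.0 - 0.475, abs=0.02)

    def test_saturating_concentration_leaves_5_percent(self):
        """c -> infinity: receptors_remaining averages M_max's complement
        (5%), strictly below the max-stained level."""
        params = SimParams(
            n_events_per_well=100_000,
            negative_serum_effect_mean=0.0,
            negative_serum_effect_sd=0.0,
            seed=2,
        )
        c = 1e6 * params.modulation_k
        assert hill_internalized_fraction(c, params) == pytest.approx(0.95, abs=1e-5)
        sat = SerumSample("SAT", "seropositive_AAG", true_conc_pM=c, ria_pM=1000.0)
        test = simulate_well(sat, 20, "test", params, 1)
        maxs = simulate_well(sat, 20, "max_stained", params, 2)
        unst = simulate_well(sat, 20, "unstained", params, 3)

        def receptor_signal(t):
            return t.events.loc[t.labels == "viable", "PE-A"].mean()

        autofluor = receptor_signal(unst)
        ratio = (receptor_signal(test) - autofluor) / (
            receptor_signal(maxs) - autofluor
        )
        assert ratio == pytest.approx(0.05, abs=0.01)

    def test_hill_fraction_monotone_in_concentration_and_dilution(self):
        params = SimParams()
        concs = [0.0, 10.0, 100.0, 1000.0, 10_000.0]
        fracs = [hill_internalized_fraction(c, params) for c in concs]
        assert fracs == sorted(fracs)
        dils = [20, 40, 80, 160]
        eff = [effective_concentration_pM(730.0, d) for d in dils]
        assert eff == sorted(eff, reverse=True)

    def test_dilution_arithmetic(self):
        assert round(effective_concentration_pM(730.0, 640)) == 23

    def test_nuisance_effect_is_per_sample_and_bounded(self, small_params):
        s = SerumSample("HC77", "healthy")
        m1 = serum_nuisance_effect(s, small_params)
        m2 = serum_nuisance_effect(s, small_params)
        assert m1 == m2
        draws = [
            serum_nuisance_effect(SerumSample(f"HC{i}", "healthy"), small_params)
            for i in range(500)
        ]
        bound = 2.0 * small_params.negative_serum_effect_sd
        assert all(
            abs(d - small_params.negative_serum_effect_mean) <= bound + 1e-12
            for d in draws
        )


class TestDilutionSeries:
    def test_requires_increasing_nonempty(self, small_params, positive_sample):
        with pytest.raises(SimulationError, match="empty"):
            simulate_dilution_series(positive_sample, [], small_params, 0)
        with pytest.raises(SimulationError, match="increasing"):
            simulate_dilution_series(positive_sample, [20, 20], small_params, 0)

    def test_series_structure(self, small_params, positive_sample):
        unst, maxs, series = simulate_dilution_series(
            positive_sample, [20, 40, 80], small_params, 0
        )
        assert unst.meta["role"] == "unstained"
        assert maxs.meta["role"] == "max_stained"
        assert [t.meta["reciprocal_dilution"] for t in series] == [20, 40, 80]
        assert all(t.meta["role"] == "test" for t in series)


class TestCohort:
    def test_default_cohort_composition(self):
        samples = make_cohort_samples(CohortConfig(seed=3))
        assert len(samples) == 190
        positives = [
            s
            for s in samples
            if s.category == "seropositive_AAG" or s.blinded_truth == "positive"
        ]
        assert len(positives) == 8
        assert all(s.true_conc_pM > 0 and s.ria_pM is not None for s in positives)
        negatives = [s for s in samples if s not in positives]
        assert all(s.true_conc_pM == 0 for s in negatives)

    def test_ria_values_in_published_range_and_monotone(self):
        from scipy.stats import spearmanr

        samples = [
            s for s in make_cohort_samples(CohortConfig(seed=5)) if s.ria_pM is not None
        ]
        rias = np.array([s.ria_pM for s in samples])
        concs = np.array([s.true_conc_pM for s in samples])
        assert ((rias >= 730.0) & (rias <= 3464.0)).all()
        assert spearmanr(concs, rias).statistic > 0.8

    def test_minimal_cohort_well_layout(self):
        config = CohortConfig(
            group_sizes={"healthy": 2},
            blinded_positive=0,
            seed=1,
        )
        params = SimParams(n_events_per_well=500, seed=1)
        layout, wells, metadata = simulate_cohort(config, params)
        assert (layout["role"] == "test").sum() == 2
        assert (layout["role"] == "unstained").sum() == 1
        assert (layout["role"] == "max_stained").sum() == 1
        assert set(layout["well"]) == set(wells)
        assert len(metadata) == 2

    def test_blinded_positive_bounded_by_blinded_count(self):
        with pytest.raises(SimulationError, match="blinded"):
            CohortConfig(group_sizes={"blinded": 2}, blinded_positive=3)

    def test_default_group_sizes_sum_to_190(self):
        assert sum(DEFAULT_GROUP_SIZES.values()) == 190
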