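import numpy as np
import pytest
from scipy import stats as sps

from arraybsa.errors import DomainError, InsufficientDataError
from arraybsa.qc import apply_qc_flags, build_fingerprint, spike_in_normalize
from arraybsa.simulate import (
    DosageModel,
    SignalModel,
    beta_for_ratio,
    exact_moment_sample,
    reference_moment_fixtures,
    simulate_bulk_hybridization,
    simulate_f1_population,
    simulate_study,
)


class TestExactMomentSample:
    @pytest.mark.parametrize("mean,sd", [(743.53, 252.08), (0.27, 0.35), (-4.0, 1.0)])
    def test_sample_moments_exact(self, mean, sd):
        v = exact_moment_sample(12, mean, sd, seed=0)
        assert v.mean() == pytest.approx(mean, abs=1e-9)
        assert v.std(ddof=1) == pytest.approx(sd, abs=1e-9)

    def test_zero_sd_gives_constant(self):
        assert (exact_moment_sample(5, 3.0, 0.0, seed=0) == 3.0).all()

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(
            exact_moment_sample(12, 0, 1, seed=9), exact_moment_sample(12, 0, 1, seed=9)
        )

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            exact_moment_sample(1, 0.0, 1.0, seed=0)


class TestDosagePopulation:
    def test_null_parents_give_all_short_day(self):
        pop = simulate_f1_population(50, 0, 0, seed=0)
        assert {p.flowering_class for p in pop} == {"SD"}

    def test_full_dosage_parents_give_all_strong_dn(self):
        pop = simulate_f1_population(50, 8, 8, seed=0)
        assert {p.flowering_class for p in pop} == {"DN1"}

    def test_class_frequencies_match_binomial_convolution(self):
        # independent oracle: offspring dosage = Bin(4, 6/8) + Bin(4, 0)
        model = DosageModel()
        pop = simulate_f1_population(600, 6, 0, model=model, seed=42)
        k = np.arange(5)
        pmf = np.convolve(sps.binom.pmf(k, 4, 0.75), sps.binom.pmf(k, 4, 0.0))
        expected = {}
        for dosage, prob in enumerate(pmf):
            cls = {1: "DN1", 2: "DN2", 3: "DN3", 4: "SD"}[
                model.score_from_dosage(dosage)
            ]
            expected[cls] = expected.get(cls, 0.0) + prob
        for cls, prob in expected.items():
            observed = sum(p.flowering_class == cls for p in pop) / 600
            sigma = np.sqrt(prob * (1 - prob) / 600)
            assert abs(observed - prob) < max(4 * sigma, 0.01)

    def test_invalid_parent_dosage(self):
        with pytest.raises(DomainError):
            simulate_f1_population(10, 9, 0, seed=0)


class TestBetaForRatio:
    def test_solves_target_ratio(self):
        beta = beta_for_ratio(3.0, 7.0, 0.5)
        assert (1 + beta * 7.0) / (1 + beta * 0.5) == pytest.approx(3.0)

    def test_infeasible_dosages_rejected(self):
        with pytest.raises(DomainError):
            beta_for_ratio(3.0, 1.0, 0.9)


DOSAGES = {"DN1": 7.0, "DN2": 4.5, "DN3": 2.5, "SD": 0.5}


class TestSignalSimulator:
    def test_same_seed_bitwise_identical(self):
        m1, _ = simulate_bulk_hybridization(DOSAGES, SignalModel(n_features=20), seed=5)
        m2, _ = simulate_bulk_hybridization(DOSAGES, SignalModel(n_features=20), seed=5)
        np.testing.assert_array_equal(m1.values.to_numpy(), m2.values.to_numpy())

    def test_noise_free_fingerprint_ratio_is_exact(self):
        beta = beta_for_ratio(3.0, DOSAGES["DN1"], DOSAGES["SD"])
        model = SignalModel(n_features=20, noise_sd=0.0, marker_effect=beta)
        matrix, truth = simulate_bulk_hybridization(DOSAGES, model, seed=1)
        norm = spike_in_normalize(apply_qc_flags(matrix))
        fp_dn1 = build_fingerprint(norm, "DN1").values[truth.planted_feature]
        fp_sd = build_fingerprint(norm, "SD").values[truth.planted_feature]
        assert fp_dn1 / fp_sd == pytest.approx(3.0, abs=1e-9)

    def test_normalization_removes_slide_distortions_when_noise_free(self):
        model = SignalModel(n_features=20, noise_sd=0.0, slide_scale_sd=0.5)
        matrix, _ = simulate_bulk_hybridization(DOSAGES, model, seed=2)
        norm = spike_in_normalize(apply_qc_flags(matrix))
        sub = norm.features_of_category("subtracted")
        dn1 = norm.columns_for("DN1")
        # noise-free: all DN1 columns must agree cell-by-cell after
        # normalization (the injected per-slide scales are removed)
        vals = norm.values.loc[sub, dn1].to_numpy()
        assert np.max(np.abs(vals - vals[:, [0]]) / vals[:, [0]]) < 1e-9

    def test_null_marker_effect_is_indistinguishable(self):
        model = SignalModel(n_features=40, marker_effect=0.0)
        matrix, truth = simulate_bulk_hybridization(DOSAGES, model, seed=3)
        from arraybsa.stats import two_bulk_stats

        norm = spike_in_normalize(apply_qc_flags(matrix))
        tbl = two_bulk_stats(norm, "DN1", "SD").set_index("feature_id")
        planted_rank = (
            tbl["fisher_ratio"].rank(ascending=False)[truth.planted_feature]
        )
        assert planted_rank > 1  # not systematically the top feature

    def test_negative_sigma_rejected(self):
        with pytest.raises(DomainError):
            SignalModel(noise_sd=-0.1)


class TestStudySimulation:
    def test_bulk_sizes_and_expected_ratio(self):
        study = simulate_study(11, model=SignalModel(n_features=15))
        sizes = {b: len(m) for b, m in study.bulks.items()}
        assert sizes == {"DN1": 2, "DN2": 19, "DN3": 18, "SD": 10}
        assert study.truth.expected_ratio_dn1_sd == pytest.approx(3.0)
        assert study.bulk_dosages["DN1"] > study.bulk_dosages["SD"]


class TestReferenceFixtures:
    def test_reproduces_printed_t_and_df(self):
        fx = reference_moment_fixtures(seed=0)
        from arraybsa.stats import independent_t_test

        for _, row in fx.iterrows():
            res = independent_t_test(
                row.values_dn, row.values_sd, variant=row.variant
            )
            assert abs(res.t) == pytest.approx(abs(row.t), abs=0.01)
            if row.variant == "pooled":
                assert res.df == 22
            else:
                assert res.df_rounded == pytest.approx(row.df, abs=0.1)
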