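import numpy as np
import pytest
from scipy import stats

import cogtrace as ct
from cogtrace import ValidationError


class TestIdealResponse:
    def test_exact_requirement_met(self):
        q = ct.QMatrix(entries=[[1, 1, 0]])
        assert ct.ideal_response([1, 1, 0], q).tolist() == [1]

    def test_master_of_everything(self, q3):
        assert ct.ideal_response([1, 1, 1], q3).tolist() == [1] * 20

    def test_collision_pair_identical_on_k3(self, q3):
        # brute force over Table rows: no item requires attribute 3 alone
        a = ct.ideal_response([0, 0, 0], q3)
        b = ct.ideal_response([0, 0, 1], q3)
        assert a.tolist() == [0] * 20
        assert np.array_equal(a, b)

    def test_dimension_mismatch(self, q3):
        with pytest.raises(ValidationError):
            ct.ideal_response([1, 0], q3)


class TestSimulateResponses:
    def test_noise_free_equals_ideal(self, q_emp, rng):
        profiles = rng.integers(0, 2, size=(40, 3))
        profiles[:, 0] = 1  # keep every row valid (any row works for DINA)
        params = ct.ItemParams(slip=np.zeros(8), guess=np.zeros(8))
        resp = ct.simulate_responses(profiles, q_emp, params, rng)
        assert np.array_equal(resp.scores, ct.ideal_response(profiles, q_emp))

    def test_success_rates_match_closed_form(self, q3, rng):
        # item 1 (high regime): s=0.16, g=0.04
        params = ct.builtin_fixture("params_high_20")
        n = 100_000
        masters = np.tile([1, 1, 0], (n, 1))
        non = np.zeros((n, 3), dtype=int)
        r1 = ct.simulate_responses(masters, q3, params, rng).scores[:, 0].mean()
        r0 = ct.simulate_responses(non, q3, params, rng).scores[:, 0].mean()
        se = 3 / np.sqrt(n)
        assert r1 == pytest.approx(1 - 0.16, abs=se)
        assert r0 == pytest.approx(0.04, abs=se)

    def test_half_noise_destroys_information(self, q_emp, rng):
        params = ct.ItemParams(slip=np.full(8, 0.5), guess=np.full(8, 0.5))
        profiles = np.tile([1, 0, 1], (50_000, 1))
        rate = ct.simulate_responses(profiles, q_emp, params, rng).scores.mean()
        assert rate == pytest.approx(0.5, abs=0.01)


class TestInitialProfiles:
    def test_degenerate_marginals(self, rng):
        prof = ct.sample_initial_profiles(100, [1, 1, 1], 0.0, rng)
        assert prof.all()

    def test_marginals_exact_under_correlation(self, rng):
        p = (0.4, 0.4, 0.2)
        prof = ct.sample_initial_profiles(100_000, p, 0.5, rng)
        assert np.allclose(prof.mean(axis=0), p, atol=0.006)

    def test_pairwise_agreement_matches_orthant_probability(self, rng):
        # quadrature oracle for P(Z1>0, Z2>0) under corr 0.5
        oracle = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, 0.5], [0.5, 1]]).cdf([0, 0])
        prof = ct.sample_initial_profiles(200_000, [0.5, 0.5], 0.5, rng)
        both = (prof[:, 0] & prof[:, 1]).mean()
        assert both == pytest.approx(oracle, abs=3 * np.sqrt(oracle / 200_000))

    def test_pattern_distribution_matches_monte_carlo(self, rng):
        p = (0.4, 0.4, 0.2)
        exact = ct.pattern_distribution(p, 0.5)
        prof = ct.sample_initial_profiles(200_000, p, 0.5, rng)
        emp = np.bincount(ct.encode_patterns(prof), minlength=8) / 200_000
        assert np.allclose(exact, emp, atol=0.005)
        assert exact.sum() == pytest.approx(1.0)


class TestAdvanceProfiles:
    def test_identity_is_absorbing(self, rng):
        prof = rng.integers(0, 2, size=(200, 3))
        eye = [np.eye(2)] * 3
        assert np.array_equal(ct.advance_profiles(prof, eye, rng), prof)

    def test_gain_and_loss_rates_match_generator(self, trans3, rng):
        n = 100_000
        se = 3 / np.sqrt(n)
        zeros = np.zeros((n, 3), dtype=int)
        ones = np.ones((n, 3), dtype=int)
        nxt0 = ct.advance_profiles(zeros, trans3[0], rng)
        nxt1 = ct.advance_profiles(ones, trans3[0], rng)
        assert nxt0[:, 0].mean() == pytest.approx(0.45, abs=se)  # A1 gain
        assert nxt1[:, 2].mean() == pytest.approx(0.13, abs=se)  # A3 retention

    def test_bad_rows_rejected(self, rng):
        with pytest.raises(ValidationError):
            ct.advance_profiles(np.zeros((5, 1), dtype=int),
                                [np.array([[0.5, 0.6], [0, 1]])], rng)


class TestSimulateLongitudinal:
    def test_single_wave_is_cross_sectional(self, q3):
        params = ct.builtin_fixture("params_high_20")
        cond = ct.make_condition(3, 20, 50, "high", n_waves=1)
        samp = ct.simulate_longitudinal(cond.design, q3, params, seed=0)
        assert samp.n_waves == 1

    def test_seed_determinism_bitwise(self, q3):
        params = ct.builtin_fixture("params_high_20")
        cond = ct.make_condition(3, 20, 100, "high")
        a = ct.simulate_longitudinal(cond.design, q3, params, seed=9)
        b = ct.simulate_longitudinal(cond.design, q3, params, seed=9)
        for t in range(3):
            assert np.array_equal(a.profiles[t], b.profiles[t])
            assert np.array_equal(a.responses[t].scores, b.responses[t].scores)

    def test_wave2_mastery_matches_forward_product(self, q3):
        # Chapman-Kolmogorov for A1: 0.6*0.45 + 0.4*0.97 = 0.658
        params = ct.builtin_fixture("params_high_20")
        cond = ct.make_condition(3, 20, 100_000, "high")
        samp = ct.simulate_longitudinal(cond.design, q3, params, seed=4)
        a1 = samp.profiles[1][:, 0].mean()
        assert a1 == pytest.approx(0.658, abs=3 / np.sqrt(100_000))

    def test_mastery_monotone_without_loss(self, q3, rng):
        gain_only = tuple(
            tuple(np.array([[0.5, 0.5], [0.0, 1.0]]) for _ in range(3))
            for _ in range(2))
        design = ct.StudyDesign(n_attributes=3, n_items=20, n_examinees=2000,
                                regime="high", initial_mastery=[0.4, 0.4, 0.2],
                                transitions=gain_only)
        params = ct.builtin_fixture("params_high_20")
        samp = ct.simulate_longitudinal(design, q3, params, seed=2)
        rates = np.array([p.mean(axis=0) for p in samp.profiles])
        assert (np.diff(rates, axis=0) >= 0).all()

    def test_save_writes_manifest(self, tmp_path, q3):
        params = ct.builtin_fixture("params_high_20")
        cond = ct.make_condition(3, 20, 20, "high")
        samp = ct.simulate_longitudinal(cond.design, q3, params, seed=1)
        samp.save(tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "responses_T3.csv").exists()


class TestTrainingSet:
    def test_uniform_exact_stratification(self, q_emp):
        X, y = ct.build_training_set(q_emp, size=8 * 5)
        assert np.bincount(y, minlength=8).tolist() == [5] * 8

    def test_empirical_ideal_vectors_distinct(self, q_emp):
        X, _ = ct.build_training_set(q_emp, size=8)
        assert len({row.tobytes() for row in X}) == 8

    def test_k3_has_exactly_one_colliding_pair(self, q3):
        X, _ = ct.build_training_set(q3, size=8)
        seen = {}
        for i, row in enumerate(X):
            seen.setdefault(row.tobytes(), []).append(i)
        dup = [v for v in seen.values() if len(v) > 1]
        assert dup == [[0, 1]]

    def test_zero_weights_rejected(self, q_emp, rng):
        with pytest.raises(ValidationError):
            ct.build_training_set(q_emp, pattern_weights=np.zeros(8), size=10,
                                  rng=rng)
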