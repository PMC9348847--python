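"""GLM, cluster-permutation and model-selection statistics."""

import itertools

import numpy as np
import pytest
from scipy import special, stats as sstats

from moodrisk import (
    BAND_FAMILY_NAMES,
    band_model_family,
    baseline_extreme_selector,
    cluster_permutation,
    conditional_glm,
    dual_site_glm,
    extreme_selector,
    feedback_decomposition_glm,
    group_random_effects,
    median_split_selector,
    rfx_bms,
    timepoint_glm,
)
from moodrisk.envelopes import EnvelopeEpochs
from moodrisk.stats import _clusters_from_t, _max_cluster_masses


def _epochs(data, fs=100.0):
    data = np.asarray(data, dtype=float)
    T = data.shape[2]
    return EnvelopeEpochs(
        data=data,
        times=np.arange(T) / fs,
        site_labels=[f"s{i}" for i in range(data.shape[1])],
        sampling_rate=fs,
    )


class TestTimepointGlm:
    def test_injected_beta_recovered(self):
        rng = np.random.default_rng(0)
        n, T = 200, 40
        x = rng.standard_normal(n)
        profile = np.zeros(T)
        profile[10:20] = 0.8
        data = x[:, None, None] * profile[None, None, :] + 0.1 * rng.standard_normal((n, 1, T))
        res = timepoint_glm(_epochs(data), x)
        np.testing.assert_allclose(res.betas[0, 10:20], 0.8, atol=0.05)
        np.testing.assert_allclose(res.betas[0, :10], 0.0, atol=0.05)
        assert np.all(np.abs(res.tvalues[0, 10:20]) > 10)

    def test_normalized_regressor_scale_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((50, 2, 10))
        x = rng.standard_normal(50)
        a = timepoint_glm(_epochs(data), x)
        b = timepoint_glm(_epochs(data), 10.0 * x + 3.0)
        np.testing.assert_allclose(a.betas, b.betas, rtol=1e-10)

    def test_null_regressor_betas_small(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((400, 1, 5))
        res = timepoint_glm(_epochs(data), rng.standard_normal(400))
        assert np.all(np.abs(res.tvalues) < 4)

    def test_errors(self):
        data = np.zeros((20, 1, 5))
        with pytest.raises(ValueError, match="length"):
            timepoint_glm(_epochs(data), np.ones(7))
        with pytest.raises(ValueError, match="constant"):
            timepoint_glm(_epochs(data), np.ones(20))


class TestClusterScan:
    def test_toy_mass(self):
        t = np.array([[3.0, 3.0, -1.0, 0.0, 2.5]])
        assert _max_cluster_masses(t, 2.0)[0] == pytest.approx(6.0)

    def test_negative_cluster_mass_absolute(self):
        t = np.array([[-3.0, -4.0, 0.0, 2.5]])
        assert _max_cluster_masses(t, 2.0)[0] == pytest.approx(7.0)

    def test_no_suprathreshold_gives_zero(self):
        assert _max_cluster_masses(np.array([[1.0, -1.5, 0.2]]), 2.0)[0] == 0.0

    def test_cluster_extraction(self):
        t = np.array([3.0, 3.0, -1.0, -2.5, -2.5, 0.0])
        clusters = _clusters_from_t(t, 2.0, np.arange(6) * 0.01)
        assert len(clusters) == 2
        pos, neg = clusters
        assert (pos["start_idx"], pos["end_idx"], pos["mass"]) == (0, 1, 6.0)
        assert (neg["start_idx"], neg["end_idx"], neg["mass"]) == (3, 4, -5.0)
        assert neg["start_s"] == pytest.approx(0.03)


class TestClusterPermutation:
    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(3)
        n_trials, n_sites, T, n_shuffles, seed, alpha = 8, 3, 5, 4, 12, 0.3
        data = rng.standard_normal((n_trials, n_sites, T))
        x = rng.standard_normal(n_trials)
        res = cluster_permutation(
            _epochs(data), x, alpha=alpha, n_shuffles=n_shuffles, seed=seed, exhaustive=True
        )
        assert res.n_combinations == n_shuffles**n_sites

        # independent naive reimplementation
        xz = (x - x.mean()) / x.std()
        rng2 = np.random.default_rng(seed)
        perms = [rng2.permutation(n_trials) for _ in range(n_shuffles)]

        def slope(y, xv):
            return np.polyfit(xv, y, 1)[0]

        def across_t(b):
            return np.mean(b) / (np.std(b, ddof=1) / np.sqrt(len(b)))

        tcrit = sstats.t.ppf(1 - alpha / 2, df=n_sites - 1)

        def max_mass(tser):
            best = 0.0
            for sign in (1, -1):
                run = 0.0
                for v in sign * tser:
                    run = run + v if v > tcrit else 0.0
                    best = max(best, run)
            return best

        null = []
        for combo in itertools.product(range(n_shuffles), repeat=n_sites):
            tser = np.array(
                [
                    across_t([slope(data[:, s, j], xz[perms[combo[s]]]) for s in range(n_sites)])
                    for j in range(T)
                ]
            )
            null.append(max_mass(tser))
        np.testing.assert_allclose(np.sort(res.null_max_masses), np.sort(null), atol=1e-9)
        for c in res.clusters:
            expected_p = (1 + np.sum(np.array(null) >= abs(c["mass"]))) / (1 + len(null))
            assert c["p_corr"] == pytest.approx(expected_p, abs=1e-12)

    def test_strong_effect_is_significant(self):
        rng = np.random.default_rng(4)
        n, S, T = 120, 4, 60
        x = rng.standard_normal(n)
        data = 0.3 * rng.standard_normal((n, S, T))
        data[:, :, 20:35] += 0.9 * x[:, None, None]
        res = cluster_permutation(
            _epochs(data), x, n_shuffles=100, n_combinations=2000, seed=0
        )
        sig = res.significant
        assert len(sig) >= 1
        main = max(sig, key=lambda c: abs(c["mass"]))
        assert main["start_idx"] >= 15 and main["end_idx"] <= 40
        assert main["p_corr"] < 0.01

    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((80, 4, 30))
        res = cluster_permutation(
            _epochs(data), rng.standard_normal(80), n_shuffles=100, n_combinations=2000, seed=1
        )
        assert all(c["p_corr"] > 0.05 for c in res.clusters)

    def test_per_site_regressors_accepted(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((40, 3, 10))
        reg = rng.standard_normal((3, 40))
        res = cluster_permutation(
            _epochs(data), reg, n_shuffles=20, n_combinations=200, seed=0
        )
        assert res.t_obs.shape == (10,)

    def test_single_site_rejected(self):
        data = np.zeros((20, 1, 5))
        with pytest.raises(ValueError, match="2 sites"):
            cluster_permutation(_epochs(data), np.arange(20.0))


class TestDualSiteGlm:
    def test_joint_coefficients_recovered(self):
        rng = np.random.default_rng(7)
        n = 300
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        y = 0.7 * a - 0.4 * b + 0.2 * rng.standard_normal(n)
        b1, b2, t1, t2 = dual_site_glm(y, a, b)
        assert b1 == pytest.approx(0.7, abs=0.06)
        assert b2 == pytest.approx(-0.4, abs=0.06)
        assert t1 > 4 and t2 < -4

    def test_collinear_pair_rejected(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(100)
        with pytest.raises(ValueError, match="collinear"):
            dual_site_glm(rng.standard_normal(100), a, a * 1.0000001)


class TestSelectors:
    def test_extreme_counts_and_content(self):
        v = np.arange(10.0)
        hi = extreme_selector(v, 0.4, "high")
        lo = extreme_selector(v, 0.4, "low")
        assert hi.sum() == lo.sum() == 4
        assert v[hi].min() == 6.0 and v[lo].max() == 3.0

    def test_median_split_partitions(self):
        v = np.arange(11.0)
        hi = median_split_selector(v, "high")
        lo = median_split_selector(v, "low")
        assert not np.any(hi & lo)
        assert np.all(hi | lo)

    def test_baseline_selector_excludes_fast_responses(self):
        b = np.arange(20.0)
        rt = np.full(20, 2.0)
        rt[18] = 1.0  # fast response among the highest-baseline trials
        mask = baseline_extreme_selector(b, 0.4, "high", response_times=rt)
        assert not mask[18]
        assert mask.sum() == int(round(0.4 * 19))

    def test_conditional_glm_identity_matches_full(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((60, 2, 8))
        x = rng.standard_normal(60)
        full = timepoint_glm(_epochs(data), x)
        cond = conditional_glm(_epochs(data), x, np.ones(60, dtype=bool))
        np.testing.assert_allclose(cond.betas, full.betas)

    def test_conditional_glm_too_few(self):
        data = np.zeros((30, 1, 4))
        mask = np.zeros(30, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="fewer than 10"):
            conditional_glm(_epochs(data), np.arange(30.0), mask)


class TestBandFamily:
    def test_sixteen_models_with_bga_first(self):
        assert len(BAND_FAMILY_NAMES) == 16
        assert BAND_FAMILY_NAMES[0] == "bga"
        assert len(set(BAND_FAMILY_NAMES)) == 16
        assert all(m.split("+")[0] == "bga" for m in BAND_FAMILY_NAMES)
        assert "bga+gamma+beta+alpha+theta" in BAND_FAMILY_NAMES

    def _powers(self, rng, n=150):
        return {b: rng.standard_normal(n) for b in ("bga", "gamma", "beta", "alpha", "theta")}

    def test_bga_only_truth_selects_bga(self):
        rng = np.random.default_rng(10)
        p = self._powers(rng)
        y = 0.8 * p["bga"] + 0.2 * rng.standard_normal(150)
        lmes = band_model_family(p, y)
        assert BAND_FAMILY_NAMES[int(np.argmax(lmes))] == "bga"

    def test_theta_contribution_selects_theta_model(self):
        rng = np.random.default_rng(11)
        p = self._powers(rng)
        y = 0.8 * p["bga"] + 0.8 * p["theta"] + 0.2 * rng.standard_normal(150)
        winner = BAND_FAMILY_NAMES[int(np.argmax(band_model_family(p, y)))]
        assert winner == "bga+theta"

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError, match="missing band"):
            band_model_family({"bga": np.zeros(10)}, np.zeros(10))


class TestRfxBms:
    def test_two_model_beta_integral_oracle(self):
        # with a Dirichlet(a1, a2) posterior the exceedance probability of
        # model 1 is the exact Beta integral P(r1 > 1/2)
        rng = np.random.default_rng(12)
        lme = np.zeros((14, 2))
        lme[:9, 0] = 2.0 + rng.random(9)
        lme[9:, 1] = 1.0 + rng.random(5)
        res = rfx_bms(lme, seed=0)
        a1, a2 = res.dirichlet_alpha
        exact = 1.0 - special.betainc(a1, a2, 0.5)
        assert res.exceedance_probabilities[0] == pytest.approx(exact, abs=0.01)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        lme = rng.standard_normal((10, 4))
        perm = [2, 0, 3, 1]
        a = rfx_bms(lme, seed=0)
        b = rfx_bms(lme[:, perm], seed=0)
        np.testing.assert_allclose(
            a.expected_frequencies[perm], b.expected_frequencies, atol=1e-9
        )
        np.testing.assert_allclose(
            a.exceedance_probabilities[perm], b.exceedance_probabilities, atol=0.01
        )

    def test_expected_frequencies_sum_to_one(self):
        rng = np.random.default_rng(14)
        res = rfx_bms(rng.standard_normal((8, 3)), seed=0)
        assert res.expected_frequencies.sum() == pytest.approx(1.0)
        assert res.exceedance_probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shape_and_finiteness_validation(self):
        with pytest.raises(ValueError):
            rfx_bms(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="non-finite"):
            rfx_bms(np.array([[0.0, -np.inf], [1.0, 0.0]]))


class TestFeedbackDecomposition:
    def test_dissociated_contributions(self):
        rng = np.random.default_rng(15)
        n = 300
        fb = rng.choice([-1.0, 1.0], n)
        prior = rng.standard_normal(n)
        y = 1.0 * fb + 0.5 * prior + 0.1 * rng.standard_normal(n)
        res = feedback_decomposition_glm(y, fb, prior)
        assert res.betas[0, 0] == pytest.approx(1.0, abs=0.05)
        assert res.betas[1, 0] == pytest.approx(0.5, abs=0.05)
        assert res.design == ["last_feedback", "prior_tml"]

    def test_timecourse_input(self):
        rng = np.random.default_rng(16)
        n, T = 100, 6
        fb = rng.choice([-1.0, 1.0], n)
        prior = rng.standard_normal(n)
        y = fb[:, None] * np.ones(T) + 0.2 * rng.standard_normal((n, T))
        res = feedback_decomposition_glm(y, fb, prior)
        assert res.betas.shape == (2, T)
        np.testing.assert_allclose(res.betas[0], 1.0, atol=0.1)

    def test_collinear_warns(self):
        fb = np.tile([-1.0, 1.0], 20)
        with pytest.warns(UserWarning, match="collinear"):
            feedback_decomposition_glm(np.random.default_rng(0).standard_normal(40), fb, fb)


class TestGroupRandomEffects:
    def test_within_subject_averaging(self):
        vals = [1.0, 3.0, 2.0, 2.0, 5.0]  # subjects a:{1,3}, b:{2,2}, c:{5}
        t, p, n, means = group_random_effects(vals, ["a", "a", "b", "b", "c"])
        assert n == 3
        np.testing.assert_allclose(np.sort(means), [2.0, 2.0, 5.0])
        assert t > 0

    def test_zero_variance_cap(self):
        t, p, n, _ = group_random_effects([1.0, 1.0, 1.0], ["a", "b", "c"])
        assert t == pytest.approx(1e6)
        assert p == 0.0

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            group_random_effects([1.0, 2.0], ["a", "b"])
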