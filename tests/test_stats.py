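from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from reachdecomp.demographics import demographic_summary, load_demographics
from reachdecomp.stats import (contrast_parameters, mann_whitney,
                               pearson_and_regression, predict_long_term,
                               shapiro_wilk, two_sample_t)
from reachdecomp.synthetic import control_config, generate_cohort, stroke_config

# frozen 20-point standard-normal draw; W and p from R's shapiro.test
SW_SAMPLE = [0.304717, -1.039984, 0.750451, 0.940565, -1.951035, -1.30218,
             0.12784, -0.316243, -0.016801, -0.853044, 0.879398, 0.777792,
             0.066031, 1.127241, 0.467509, -0.859292, 0.368751, -0.958883,
             0.87845, -0.049926]
SW_R_W, SW_R_P = 0.934304, 0.186789


def exact_mw_p(x, y):
    """Exhaustive-enumeration two-sided Mann-Whitney p (oracle).

    Enumerates every assignment of the pooled ranks to the first sample and
    counts arrangements with a U at least as extreme as observed.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    u_min = min(u_obs, nx * len(y) - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        if min(u, nx * len(y) - u) <= u_min + 1e-9:
            count += 1
        total += 1
    return count / total


class TestShapiroWilk:
    def test_matches_r_reference_to_four_decimals(self):
        w, p = shapiro_wilk(SW_SAMPLE)
        assert w == pytest.approx(SW_R_W, abs=1e-4)
        assert p == pytest.approx(SW_R_P, abs=1e-4)

    def test_detects_lognormal_sample(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 1.0, 50))
        assert shapiro_wilk(x)[1] < 0.05

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestMannWhitney:
    def test_tiny_exact_case(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res["U"] == 0
        assert res["p"] == pytest.approx(1 / 3, abs=1e-12)
        assert res["method"] == "exact"

    def test_identical_samples_are_not_distinguished(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert mann_whitney(x, x)["p"] == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("nx, ny", [(3, 4), (5, 4), (6, 6)])
    def test_reported_p_matches_enumeration_oracle(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(5):
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.5, 1, ny)
            assert mann_whitney(x, y)["p"] == pytest.approx(
                exact_mw_p(x, y), abs=0.01)

    def test_separates_fatigue_parameter_at_published_medians(self):
        rng = np.random.default_rng(5)
        c_stroke = rng.normal(1.11, 0.756, 16)
        c_control = rng.normal(0.12, 0.067, 10)
        assert mann_whitney(c_stroke, c_control)["p"] < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson_and_regression(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_hand_computed_triplet(self):
        res = pearson_and_regression([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.r2 == pytest.approx(0.25, abs=1e-12)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert pearson_and_regression(x, y).r == pytest.approx(
            pearson_and_regression(x[perm], y[perm]).r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_and_regression([1, 1, 1], [1, 2, 3])


class TestTTest:
    def test_published_age_comparison(self):
        demo = load_demographics()
        t, df, p = two_sample_t(
            demo.loc[demo.group == "stroke", "age_years"],
            demo.loc[demo.group == "control", "age_years"])
        assert p == pytest.approx(0.117, abs=0.002)
        assert df == 24

    def test_identical_samples(self):
        t, _, p = two_sample_t([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_case(self):
        t, df, p = two_sample_t([1, 2, 3, 4.0], [2, 3, 4, 5.0])
        assert t == pytest.approx(-1.095, abs=1e-3)
        assert df == 6
        assert p == pytest.approx(0.3153, abs=1e-3)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2.0], [2.0, 2.0])


def test_demographic_summary_reproduces_participant_table():
    s = demographic_summary()
    assert s["stroke"]["n"] == 16 and s["control"]["n"] == 10
    assert s["stroke"]["age_mean"] == pytest.approx(63.2, abs=0.05)
    assert s["stroke"]["fm_mean"] == pytest.approx(48.7, abs=0.05)
    # the duration column itself averages to 69.7 (summary texts round to 72)
    assert s["stroke"]["duration_mean"] == pytest.approx(69.7, abs=0.05)
    assert s["age_ttest"]["p"] == pytest.approx(0.117, abs=0.002)


class TestContrastBattery:
    def _params_frame(self, seed):
        s = generate_cohort(stroke_config(16, seed=seed))
        c = generate_cohort(control_config(10, seed=seed + 1000))
        return pd.concat([s.params_frame(), c.params_frame()],
                         ignore_index=True)

    def test_stroke_medians_exceed_control_for_all_parameters(self):
        contrasts = contrast_parameters(self._params_frame(4))
        assert len(contrasts) == 8
        for c in contrasts:
            assert c.median_a > c.median_b, c.parameter

    def test_type_one_error_is_near_nominal(self):
        """Null calibration: identical populations, ~5% rejections."""
        rng = np.random.default_rng(10)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(0, 1, 16)
            y = rng.normal(0, 1, 10)
            hits += mann_whitney(x, y)["p"] < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_single_subject_group_rejected(self):
        frame = self._params_frame(4).iloc[:17]   # 16 stroke + 1 control
        with pytest.raises(ValueError):
            contrast_parameters(frame)


class TestLongTermPrediction:
    def test_learning_outpredicts_net_performance_change(self, stroke_cohort):
        from reachdecomp.metrics import metrics_frame
        m = metrics_frame(stroke_cohort.subjects)
        r2_nl = predict_long_term(m, stroke_cohort.test_phases,
                                  "normalized_learning").r2
        r2_npc = predict_long_term(m, stroke_cohort.test_phases,
                                   "normalized_performance_change").r2
        assert r2_nl > r2_npc

    def test_homogeneous_learning_dynamics_give_near_perfect_prediction(self):
        """With a common tau and C and no retention noise, normalized
        learning determines the long-term change through A alone, so the
        regression tightens toward R^2 = 1.  (Under the full tau
        heterogeneity the relationship is intrinsically loose — tau
        modulates how much of A is expressed in-session but not
        retention — which is why R^2 stays moderate in realistic cohorts.)
        """
        from reachdecomp.metrics import metrics_frame
        cfg = stroke_config(16, seed=8, tau_log_sd=0.0, c_sd=0.0,
                            retention_noise_sd=0.0)
        co = generate_cohort(cfg)
        m = metrics_frame(co.subjects)
        r2 = predict_long_term(m, co.test_phases, "normalized_learning").r2
        assert r2 > 0.95

    def test_retention_noise_loosens_the_relationship_on_average(self):
        from reachdecomp.metrics import metrics_frame
        diffs = []
        for seed in range(5):
            clean = generate_cohort(stroke_config(16, seed=seed,
                                                  retention_noise_sd=0.0))
            noisy = generate_cohort(stroke_config(16, seed=seed,
                                                  retention_noise_sd=150.0))
            m_clean = metrics_frame(clean.subjects)
            m_noisy = metrics_frame(noisy.subjects)
            diffs.append(
                predict_long_term(m_clean, clean.test_phases,
                                  "normalized_learning").r2 -
                predict_long_term(m_noisy, noisy.test_phases,
                                  "normalized_learning").r2)
        assert np.mean(diffs) > 0

    def test_exclusion_bookkeeping(self, stroke_cohort):
        from reachdecomp.metrics import metrics_frame
        m = metrics_frame(stroke_cohort.subjects)
        full = predict_long_term(m, stroke_cohort.test_phases)
        drop = predict_long_term(m, stroke_cohort.test_phases,
                                 exclude=("S9",))
        assert drop.n == full.n - 1

    def test_unknown_predictor_rejected(self, stroke_cohort):
        from reachdecomp.metrics import metrics_frame
        m = metrics_frame(stroke_cohort.subjects)
        with pytest.raises(ValueError):
            predict_long_term(m, stroke_cohort.test_phases, "half_life_trials")
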