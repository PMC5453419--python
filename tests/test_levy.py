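import numpy as np
import pytest

from freewalk import (LevyConfig, Trajectory, classify_individual,
                      compare_waic, fit_exponential, fit_truncated_pareto,
                      sample_truncated_pareto, segment_moves, signed_moves,
                      truncate_steps)
from freewalk.levy import StepSeries, exp_loglik, gof_pvalue, tp_loglik

from conftest import make_walker


def series(lengths, iid="s", axis="x"):
    lengths = np.asarray(lengths, dtype=float)
    return StepSeries(iid, axis, lengths, a=float(lengths.min()),
                      b=float(lengths.max()))


class TestSegmentation:
    def test_sign_runs(self):
        tr = Trajectory("a", "c", np.arange(5.0),
                        [0.0, 1.0, 3.0, 2.0, 5.0], np.zeros(5))
        st = segment_moves(tr, "x", min_step=0.0)
        np.testing.assert_allclose(st.lengths, [3.0, 1.0, 3.0])

    def test_monotone_single_move(self):
        tr = Trajectory("a", "c", np.arange(5.0),
                        [0.0, 1.0, 2.0, 4.0, 7.0], np.zeros(5))
        st = segment_moves(tr, "x", min_step=0.0)
        np.testing.assert_allclose(st.lengths, [7.0])

    def test_zero_increment_extends_move(self):
        np.testing.assert_allclose(
            signed_moves([0.0, 1.0, 1.0, 2.0, 1.0]), [2.0, -1.0])

    def test_small_moves_merge_forward(self):
        # +3, -0.5, +2 with min_step 1: the -0.5 run folds into the +2 run
        m = signed_moves([0.0, 3.0, 2.5, 4.5], min_step=1.0)
        np.testing.assert_allclose(m, [3.0, 1.5])

    @pytest.mark.parametrize("min_step", [0.0, 1.0, 20.0])
    @pytest.mark.parametrize("kind,seed", [("brownian", 3), ("truncated_levy", 5),
                                           ("crw", 8)])
    def test_telescoping_to_net_displacement(self, kind, seed, min_step):
        tr = make_walker(kind, seed, n_frames=800, dt=1.0)
        for z in (tr.xs, tr.ys):
            assert signed_moves(z, min_step).sum() == pytest.approx(
                z[-1] - z[0], abs=1e-9)

    def test_oom(self):
        st = series([1.0, 5.0, 100.0])
        assert st.oom == pytest.approx(2.0)

    def test_truncate_steps_resets_support(self):
        st = truncate_steps(series([1.0, 5.0, 50.0, 100.0]), 5.0)
        assert st.a == 5.0 and st.n == 3


class TestExponentialFit:
    def test_lower_truncated_closed_form_limit(self):
        # with b >> typical draws the MLE approaches 1/(mean - a)
        rng = np.random.default_rng(2)
        x = 1.0 + rng.exponential(2.0, 20000)
        st = series(x)
        fit = fit_exponential(st)
        assert fit.parameter == pytest.approx(1.0 / (x.mean() - 1.0), rel=0.02)

    def test_self_consistency_and_grid_oracle(self):
        lam, a, b = 0.5, 1.0, 50.0
        rng = np.random.default_rng(4)
        # inverse-CDF sampler for the doubly truncated exponential
        u = rng.random(10000)
        x = a - np.log1p(u * np.expm1(-lam * (b - a))) / lam
        st = series(x)
        fit = fit_exponential(st)
        assert 0.48 <= fit.parameter <= 0.52
        grid = np.linspace(0.3, 0.7, 40001)
        ll = [exp_loglik(g, st) for g in grid]
        assert abs(grid[int(np.argmax(ll))] - fit.parameter) < 1e-4

    def test_optimality(self, rng):
        st = series(1.0 + rng.exponential(3.0, 500))
        fit = fit_exponential(st)
        ll = fit.log_likelihood
        assert ll >= exp_loglik(fit.parameter * 1.1, st)
        assert ll >= exp_loglik(fit.parameter * 0.9, st)
        assert fit.aic == pytest.approx(2.0 - 2.0 * ll)


class TestTruncatedParetoFit:
    @pytest.mark.parametrize("mu", [1.5, 2.0, 2.5])
    def test_recovery_and_grid_oracle(self, mu):
        x = sample_truncated_pareto(10000, mu, 1.0, 100.0, seed=17)
        st = series(x)
        fit = fit_truncated_pareto(st)
        assert abs(fit.parameter - mu) < 0.05
        grid = np.linspace(1.0001, 4.0, 60001)
        ll = [tp_loglik(g, st) for g in grid]
        assert abs(grid[int(np.argmax(ll))] - fit.parameter) < 1e-4

    def test_near_degenerate_hits_boundary_flag(self):
        x = np.array([1.0, 1.0001, 1.00005, 1.00002] * 5)
        fit = fit_truncated_pareto(series(x))
        assert fit.boundary

    def test_optimality(self):
        x = sample_truncated_pareto(400, 2.0, 1.0, 100.0, seed=3)
        st = series(x)
        fit = fit_truncated_pareto(st)
        assert fit.log_likelihood >= tp_loglik(fit.parameter + 0.1, st)
        assert fit.log_likelihood >= tp_loglik(fit.parameter - 0.1, st)

    def test_degenerate_support_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_truncated_pareto(series([2.0, 2.0, 2.0]))


class TestAkaikeWeights:
    def _fits(self, aics):
        out = []
        for aic in aics:
            f = fit_exponential(series([1.0, 2.0, 3.0, 8.0]))
            f.aic = aic
            out.append(f)
        return out

    def test_equal_aic_splits_evenly(self):
        fits = compare_waic(self._fits([10.0, 10.0]))
        assert [f.waic for f in fits] == pytest.approx([0.5, 0.5])

    def test_delta_twenty(self):
        fits = compare_waic(self._fits([0.0, 20.0]))
        assert fits[0].waic == pytest.approx(0.9999546, abs=1e-6)
        assert fits[1].waic == pytest.approx(4.54e-5, rel=0.01)

    def test_weights_sum_to_one(self, rng):
        fits = compare_waic(self._fits(list(rng.uniform(0, 50, 5))))
        assert sum(f.waic for f in fits) == pytest.approx(1.0)

    def test_mismatched_n_rejected(self):
        f1 = fit_exponential(series([1.0, 2.0, 3.0]))
        f2 = fit_exponential(series([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="same step series"):
            compare_waic([f1, f2])


class TestGoodnessOfFit:
    def test_true_model_passes(self):
        x = sample_truncated_pareto(300, 2.0, 1.0, 100.0, seed=9)
        st = series(x)
        fit = fit_truncated_pareto(st)
        assert gof_pvalue(st, fit, 500, seed=1) >= 0.05

    def test_wrong_model_rejected(self):
        x = sample_truncated_pareto(1000, 1.5, 1.0, 1000.0, seed=9)
        st = series(x)
        fit = fit_exponential(st)
        assert gof_pvalue(st, fit, 500, seed=1) < 0.05


class TestClassification:
    CFG = LevyConfig(fit_floor=50.0, gof_resamples=500, seed=42)

    def test_levy_walker_detected_on_both_axes(self):
        tr = make_walker("truncated_levy", 1, n_frames=6000, dt=1.0)
        cls = classify_individual(tr, self.CFG)
        assert cls.overall == "TP_both"
        for mu in (cls.mu_x, cls.mu_y):
            assert abs(mu - 2.0) < 0.3
            assert 1.0 < mu <= 3.0   # admissible Levy range

    def test_mean_exponent_recovery_across_walkers(self):
        # averaging over walkers removes most of the per-individual noise;
        # residual bias of the segmentation pipeline stays small
        mus = []
        for seed in range(1, 9):
            tr = make_walker("truncated_levy", seed, n_frames=6000, dt=1.0)
            for axis in "xy":
                st = truncate_steps(segment_moves(tr, axis, 1.0), 50.0)
                mus.append(fit_truncated_pareto(st).parameter)
        assert abs(np.mean(mus) - 2.0) < 0.15

    def test_brownian_walker_prefers_exponential(self):
        tr = make_walker("brownian", 1, n_frames=6000, dt=1.0, sigma_step=25.0)
        cls = classify_individual(tr, self.CFG)
        for ax in (cls.x, cls.y):
            tp_w = next(f.waic for f in ax.fits if f.model == "truncated_pareto")
            assert tp_w < 0.5

    def test_too_few_moves_flagged(self):
        t = np.arange(8.0)
        x = np.array([0.0, 5, 1, 7, 2, 9, 3, 10])
        tr = Trajectory("tiny", "c", t, x, x[::-1].copy(), fps_nominal=1.0)
        cls = classify_individual(tr, LevyConfig(min_step=0.0))
        assert cls.overall == "neither"
        assert "insufficient" in cls.x.reason
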