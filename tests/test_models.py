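import math

import numpy as np
import pytest

from smaddyn.models import (DepletionModelParams, FeedbackModelParams,
                            GeneParams, NoResponseError, ReceptorModelParams,
                            WindowTooShortError, adaptation_metrics,
                            classify_dynamics, normalize_ct, simulate_feedback,
                            simulate_ligand_depletion,
                            simulate_receptor_depletion, simulate_target_gene)
from smaddyn.schedules import make_pulse_train, make_ramp, make_step


class TestFeedbackModel:
    def test_no_ligand_stays_at_steady_state(self, smad4_params, t12):
        traj = simulate_feedback(smad4_params, make_step(0.0, 0.0, 12.0), t12)
        assert np.allclose(traj.S, smad4_params.S0, atol=1e-7)

    def test_saturating_step_baseline_fraction(self, smad4_params, t12):
        traj = simulate_feedback(smad4_params, make_step(50.0, 0.0, 12.0), t12)
        m = adaptation_metrics(traj)
        assert m.baseline_fraction == pytest.approx(0.20, abs=0.02)
        assert classify_dynamics(m) == "adaptive"

    def test_plateau_above_baseline_under_sustained_ligand(self, smad4_params, t12):
        # the adapted plateau is maintained by continued ligand exposure
        traj = simulate_feedback(smad4_params, make_step(50.0, 0.0, 12.0), t12)
        assert traj.S[-1] > smad4_params.S0 + 0.05

    def test_ramp_peak_strongly_reduced_vs_step(self, smad4_params, t24):
        step = simulate_feedback(smad4_params, make_step(50.0, 0.0, 24.0), t24)
        ramp = simulate_feedback(
            smad4_params, make_ramp(50.0, 10.0, 10, hold_until=24.0), t24)
        s0 = smad4_params.S0
        assert (ramp.S.max() - s0) < 0.5 * (step.S.max() - s0)

    def test_ramp_peak_monotone_in_step_count(self, smad4_params, t24):
        s0 = smad4_params.S0
        peaks = []
        for n in (1, 2, 5, 10, 20):
            traj = simulate_feedback(
                smad4_params, make_ramp(50.0, 10.0, n, hold_until=24.0), t24)
            peaks.append(traj.S.max() - s0)
        assert np.all(np.diff(peaks) <= 1e-9)

    def test_peak_monotone_in_ramp_rate(self, smad4_params):
        # faster ramps (same dose, shorter duration) give larger peaks
        s0 = smad4_params.S0
        peaks = []
        for dur in (16.0, 8.0, 4.0, 2.0):
            t = np.arange(0.0, 24.0 + 1e-9, 0.005)
            traj = simulate_feedback(
                smad4_params,
                make_ramp(50.0, dur, max(int(dur), 1), hold_until=24.0), t)
            peaks.append(traj.S.max() - s0)
        assert np.all(np.diff(peaks) > 0)

    def test_peak_monotone_in_dose(self, smad4_params, t12):
        peaks = [adaptation_metrics(
            simulate_feedback(smad4_params, make_step(d, 0.0, 12.0), t12)).peak
            for d in (5.0, 12.5, 25.0, 50.0)]
        assert np.all(np.diff(peaks) > 0)

    def test_timescale_nearly_dose_independent(self, smad4_params, t12):
        doses = (5.0, 8.0, 12.5, 20.0, 32.0, 50.0)
        ts = [adaptation_metrics(
            simulate_feedback(smad4_params, make_step(d, 0.0, 12.0), t12)
        ).adaptation_timescale for d in doses]
        assert np.std(ts) / np.mean(ts) < 0.10

    def test_pulses_retrigger_after_relaxation_gap(self, smad4_params):
        t = np.arange(0.0, 21.0 + 1e-9, 0.005)
        sched = make_pulse_train(50.0, (6.0, 10.0), gap=5.0)
        traj = simulate_feedback(smad4_params, sched, t)
        x = traj.S - smad4_params.S0
        first = x[(t >= 0) & (t < 6)].max()
        second = x[t >= 11].max()
        assert second >= 0.80 * first

    def test_short_gap_damps_second_pulse(self, smad4_params):
        t = np.arange(0.0, 13.0 + 1e-9, 0.002)
        sched = make_pulse_train(50.0, (6.0, 6.0), gap=0.05)
        traj = simulate_feedback(smad4_params, sched, t)
        x = traj.S - smad4_params.S0
        first = x[(t >= 0) & (t < 6)].max()
        second = x[t >= 6.05].max()
        assert second < 0.5 * first

    def test_smad23_weaker_adaptation(self, smad23_params, t12):
        traj = simulate_feedback(smad23_params, make_step(50.0, 0.0, 12.0), t12)
        m = adaptation_metrics(traj)
        assert m.baseline_fraction == pytest.approx(0.60, abs=0.05)
        assert classify_dynamics(m) == "intermediate"


class TestReceptorModel:
    def test_no_ligand_steady_state(self, receptor_params, t12):
        traj = simulate_receptor_depletion(
            receptor_params, make_step(0.0, 0.0, 12.0), t12)
        assert np.allclose(traj.S, 0.0, atol=1e-8)
        R0 = receptor_params.s / receptor_params.d_i
        assert np.allclose(traj.params["R"], R0, rtol=1e-7)

    @pytest.mark.parametrize("ratio", [0.1, 0.2, 0.3, 0.4, 0.5])
    def test_adapted_fraction_equals_degradation_ratio(self, ratio):
        # at saturating ligand the plateau/peak ratio is d_i/d_a
        p = ReceptorModelParams(s=1.0, d_i=ratio, d_a=1.0, k_b=10.0)
        t = np.arange(0.0, 24.0 + 1e-9, 0.005)
        sched = make_step(50.0, 0.0, 24.0)  # k_b*L = 500 >> d_a
        m = adaptation_metrics(simulate_receptor_depletion(p, sched, t), S0=0.0)
        assert m.baseline_fraction == pytest.approx(ratio, rel=0.05)

    def test_recovery_time_is_ln10_over_di(self, receptor_params):
        # stimulate to deplete receptors, remove ligand, watch R recover
        p = receptor_params
        t = np.arange(0.0, 60.0 + 1e-9, 0.005)
        sched = make_step(50.0, 0.0, 12.0)
        traj = simulate_receptor_depletion(p, sched, t)
        R = traj.params["R"]
        post = t >= 12.0
        R0 = p.s / p.d_i
        span = R0 - R[post][0]
        target = R0 - 0.1 * span  # 90% of the way back
        t_rec = t[post][np.nonzero(R[post] >= target)[0][0]] - 12.0
        assert t_rec == pytest.approx(math.log(10) / p.d_i, rel=0.05)

    def test_strong_adaptation_forces_slow_recovery(self):
        """Recovery/adaptation timescale ratio tracks d_a/d_i (the disproof)."""
        t = np.arange(0.0, 80.0 + 1e-9, 0.005)
        ratios = []
        truth = []
        for d_i in (0.1, 0.2, 0.4):
            p = ReceptorModelParams(s=1.0, d_i=d_i, d_a=1.0, k_b=50.0)
            traj = simulate_receptor_depletion(p, make_step(50.0, 0.0, 80.0), t)
            tau_adapt = adaptation_metrics(traj, S0=0.0).adaptation_timescale
            # recovery timescale: 1 - 1/e relaxation of R from empty
            traj2 = simulate_receptor_depletion(p, make_step(50.0, 0.0, 20.0),
                                                np.arange(0.0, 80.0 + 1e-9, 0.005))
            R = traj2.params["R"]
            tt = traj2.t
            post = tt >= 20.0
            R0 = p.s / p.d_i
            span = R0 - R[post][0]
            target = R[post][0] + (1 - 1 / math.e) * span
            tau_rec = tt[post][np.nonzero(R[post] >= target)[0][0]] - 20.0
            ratios.append(tau_rec / tau_adapt)
            truth.append(p.d_a / p.d_i)
        # monotone: stronger adaptation (smaller d_i/d_a) -> slower recovery
        assert np.all(np.diff(ratios) < 0)
        np.testing.assert_allclose(ratios, truth, rtol=0.10)


class TestLigandDepletionModel:
    def test_no_uptake_sustained(self):
        p = DepletionModelParams(u=1e-9, L_thresh=1.0, alpha=2.0, gamma=2.0)
        t = np.arange(0.0, 48.0 + 1e-9, 0.01)
        traj = simulate_ligand_depletion(p, L0=10.0, t_grid=t)
        m = adaptation_metrics(traj)
        assert m.baseline_fraction > 0.95

    def test_duration_increases_with_dose(self, depletion_params):
        t = np.arange(0.0, 48.0 + 1e-9, 0.01)

        def half_duration(L0):
            traj = simulate_ligand_depletion(depletion_params, L0=L0, t_grid=t)
            x = traj.S - depletion_params.S0
            above = np.nonzero(x >= 0.5 * x.max())[0]
            return t[above[-1]] - t[above[0]]

        assert half_duration(10.0) < half_duration(50.0)

    def test_ligand_crossing_matches_closed_form(self, depletion_params):
        p = depletion_params
        t = np.arange(0.0, 48.0 + 1e-9, 0.001)
        traj = simulate_ligand_depletion(p, L0=10.0, t_grid=t)
        L = traj.params["L"]
        t_cross = t[np.nonzero(L <= p.L_thresh)[0][0]]
        assert t_cross == pytest.approx(math.log(10.0 / p.L_thresh) / p.u,
                                        rel=1e-3)


class TestAdaptationMetrics:
    def test_flat_trace_flagged_no_response(self, smad4_params, t12):
        traj = simulate_feedback(smad4_params, make_step(0.0, 0.0, 12.0), t12)
        with pytest.raises(NoResponseError):
            adaptation_metrics(traj)

    def test_sustained_trace_sentinels(self):
        from smaddyn.models import SignalTrajectory
        t = np.linspace(0, 12, 600)
        S = 1.0 + (1 - np.exp(-t))  # monotone rise to plateau
        m = adaptation_metrics(SignalTrajectory(t, S, params={"S0": 1.0}))
        assert m.baseline_fraction == 1.0
        assert math.isinf(m.adaptation_timescale)
        assert classify_dynamics(m) == "sustained"

    def test_window_too_short_raises(self, smad4_params):
        t = np.arange(0.0, 0.25 + 1e-9, 0.001)  # < 4 adaptation timescales
        traj = simulate_feedback(smad4_params, make_step(50.0, 0.0, 0.25), t)
        with pytest.raises(WindowTooShortError):
            adaptation_metrics(traj)


class TestTargetGene:
    def _step_traj(self, params, t):
        return simulate_feedback(params, make_step(50.0, 0.0, t[-1]), t)

    def test_no_signal_no_transcript(self, smad4_params, t12):
        traj = simulate_feedback(smad4_params, make_step(0.0, 0.0, 12.0), t12)
        gene = GeneParams(mode="adaptive", a=1.0, theta=0.35, delta_m=0.2)
        assert np.allclose(simulate_target_gene(gene, traj), 0.0)

    def test_sustained_gene_plateaus(self, smad4_params, t24):
        traj = self._step_traj(smad4_params, t24)
        # threshold below the adapted baseline excess (~0.2)
        gene = GeneParams(mode="sustained", a=1.0, theta=0.05, delta_m=0.5)
        m = simulate_target_gene(gene, traj)
        tail = m[t24 >= 20.0]
        assert tail.min() > 0.5 * m.max()
        assert np.ptp(tail) < 0.05 * m.max()

    def test_adaptive_gene_peaks_and_decays(self, smad4_params, t24):
        traj = self._step_traj(smad4_params, t24)
        gene = GeneParams(mode="adaptive", a=1.0, theta=0.35, delta_m=0.2)
        m = simulate_target_gene(gene, traj)
        assert m[-1] < 0.2 * m.max()

    def test_inhibition_halves_mrna_at_half_life(self, smad4_params, t24):
        traj = self._step_traj(smad4_params, t24)
        gene = GeneParams(mode="sustained", a=1.0, theta=0.05, delta_m=0.3)
        t_inh = 12.0
        m = simulate_target_gene(gene, traj, t_inhibit=t_inh)
        half_life = math.log(2) / gene.delta_m
        i0 = np.searchsorted(t24, t_inh)
        i1 = np.searchsorted(t24, t_inh + half_life)
        # pure exponential decay after inhibition (exact on the grid) ...
        expected = m[i0] * math.exp(-gene.delta_m * (t24[i1] - t24[i0]))
        assert m[i1] == pytest.approx(expected, rel=1e-9)
        # ... which is one half after one half-life
        assert m[i1] == pytest.approx(m[i0] / 2, rel=0.01)


class TestQpcrNormalization:
    @pytest.mark.parametrize("ct_t, ct_r, expected", [
        (20.0, 20.0, 0.0),
        (18.0, 20.0, 2.0),     # 4-fold higher expression
        (23.32, 20.0, -3.32),
    ])
    def test_reference_gene_delta_ct(self, ct_t, ct_r, expected):
        assert normalize_ct(ct_t, ct_r) == pytest.approx(expected)


def _rk4(rhs, y0, t_grid, h):
    """Fixed-step classical Runge-Kutta reference integrator."""
    y = np.asarray(y0, dtype=float)
    t = t_grid[0]
    out = [y.copy()]
    for t_next in t_grid[1:]:
        n = max(1, int(round((t_next - t) / h)))
        dt = (t_next - t) / n
        for _ in range(n):
            k1 = np.asarray(rhs(t, y))
            k2 = np.asarray(rhs(t + dt / 2, y + dt / 2 * k1))
            k3 = np.asarray(rhs(t + dt / 2, y + dt / 2 * k2))
            k4 = np.asarray(rhs(t + dt, y + dt * k3))
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        out.append(y.copy())
    return np.array(out)


class TestIntegratorAgreement:
    """Adaptive-solver output matches a fixed-step RK4 oracle at 1e-4."""

    COARSE = np.array([1.0, 2.0, 3.0])
    H = 0.1  # 10x finer than the coarse spacing

    def test_feedback(self):
        p = FeedbackModelParams(alpha=2.0, K_L=10.0, gamma=1.0, beta=2.0,
                                delta=0.5, K_I=1.0, S0=1.0)
        sched = make_step(50.0, 0.0, 4.0)

        def rhs(t, y):
            S, I = y
            O = 50.0 / 60.0
            return (p.alpha * O / (1 + I / p.K_I) - p.gamma * (S - p.S0),
                    p.beta * (S - p.S0) - p.delta * I)

        grid = np.concatenate([[0.0], self.COARSE])
        traj = simulate_feedback(p, sched, grid)
        ref = _rk4(rhs, (p.S0, 0.0), grid, self.H)
        np.testing.assert_allclose(traj.S[1:], ref[1:, 0], rtol=1e-4)

    def test_receptor(self):
        p = ReceptorModelParams(s=1.0, d_i=0.2, d_a=1.0, k_b=0.1)
        sched = make_step(10.0, 0.0, 4.0)

        def rhs(t, y):
            R, Ra = y
            bind = p.k_b * 10.0 * R
            return (p.s - p.d_i * R - bind, bind - p.d_a * Ra)

        grid = np.concatenate([[0.0], self.COARSE])
        traj = simulate_receptor_depletion(p, sched, grid)
        ref = _rk4(rhs, (p.s / p.d_i, 0.0), grid, self.H)
        np.testing.assert_allclose(traj.S[1:], ref[1:, 1], rtol=1e-4)

    def test_ligand_depletion(self):
        p = DepletionModelParams(u=0.15, L_thresh=1.0, alpha=2.0, gamma=2.0)

        def rhs(t, y):
            S, L = y
            O = max(L, 0.0) ** 4 / (max(L, 0.0) ** 4 + 1.0)
            return (p.alpha * O - p.gamma * (S - p.S0), -p.u * max(L, 0.0))

        grid = np.concatenate([[0.0], self.COARSE])
        traj = simulate_ligand_depletion(p, L0=10.0, t_grid=grid)
        ref = _rk4(rhs, (p.S0, 10.0), grid, self.H)
        np.testing.assert_allclose(traj.S[1:], ref[1:, 0], rtol=1e-4)
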