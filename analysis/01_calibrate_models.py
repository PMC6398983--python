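"""Calibrate the shipped model defaults and freeze them into the package config.

The negative-feedback (Activin/Nodal-like) model is fit once so that a
saturating 50 ng/ml step produces a late plateau at 20% of the peak excess
(the quantified degree of adaptation of the SMAD4 response) and a peak excess
of ~1 ratio unit (nuc:cyt ratio rising from ~1 to ~2), while a second
saturating pulse after a 5 hr gap re-triggers >= ~87% of the first peak (the
refractory period matches the adaptation timescale rather than exceeding it).

The two-variable divisive-feedback form cannot make all of the above
absolutely slow at the same time: committing to the 20% plateau and to full
recovery within a 5 hr gap compresses the peak time and 1/e adaptation
timescale relative to the measured response (minutes rather than ~1 hr /
~2 hr).  The calibration deliberately privileges the quantified plateau and
the pulse-relaxation behavior; the shape (overshoot, plateau, dose relations,
rate sensitivity) is preserved.  See docs/methods.md.

The SMAD2/3 variant shares all rates but has weaker feedback (larger K_I),
calibrated so the plateau sits at 60% of peak.  Receptor-depletion and
ligand-depletion defaults are stated, not fitted: their behavior is governed
by rate ratios that are set directly.

Writes src/smaddyn/config/model_defaults.json (the file the package ships)
and a diagnostics report under results/.
"""

from __future__ import annotations

import json
import pathlib
import sys

import numpy as np
from scipy.optimize import least_squares, brentq

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from smaddyn.models import (FeedbackModelParams, adaptation_metrics,  # noqa: E402
                            simulate_feedback)
from smaddyn.schedules import make_step, make_ramp, make_pulse_train  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]
CONFIG = ROOT / "src" / "smaddyn" / "config" / "model_defaults.json"
RESULTS = ROOT / "results"

K_L = 20.0   # ng/ml; increments of a staircase ramp must be sub-saturating
K_I = 1.0
S0 = 1.0
T_GRID = np.arange(0.0, 48.0 + 1e-9, 0.01)


def step_metrics(params: FeedbackModelParams, dose: float = 50.0):
    traj = simulate_feedback(params, make_step(dose, 0.0, T_GRID[-1]), T_GRID)
    return adaptation_metrics(traj)


def retrigger_ratio(params: FeedbackModelParams, gap: float = 5.0) -> float:
    """Second-pulse peak excess relative to the first (saturating pulses)."""
    sch = make_pulse_train(50.0, (6.0, 10.0), gap)
    tr = simulate_feedback(params, sch, np.arange(0.0, 21.0 + 1e-9, 0.005))
    x = tr.S - params.S0
    first = x[(tr.t >= 0) & (tr.t < 6)].max()
    second = x[(tr.t >= 6 + gap)].max()
    return float(second / first)


def _make(x) -> FeedbackModelParams:
    a, g, b, d = np.exp(x)
    return FeedbackModelParams(alpha=a, K_L=K_L, gamma=g, beta=b, delta=d,
                               K_I=K_I, S0=S0)


def residuals(x):
    p = _make(x)
    try:
        m = step_metrics(p)
        r = retrigger_ratio(p)
    except Exception:
        return [1e3] * 5
    ts = min(m.adaptation_timescale, 50.0)
    return [
        (m.baseline_fraction - 0.20) * 100.0,  # the quoted number: dominate
        (r - 0.87) * 30.0,                     # 5 hr gap must re-trigger
        (m.peak - 1.0) * 2.0,                  # ratio roughly doubles at peak
        (ts - 2.0) * 0.3,                      # mild pull toward slow dynamics
        (m.peak_time - 1.0) * 0.3,
    ]


def main() -> None:
    x0 = np.log([30.0, 20.0, 12.0, 0.6])  # alpha, gamma, beta, delta
    fit = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12,
                        bounds=(np.log([0.5, 0.5, 0.5, 0.2]),
                                np.log([500.0, 200.0, 500.0, 3.0])))
    alpha, gamma, beta, delta = np.exp(fit.x)
    smad4 = _make(fit.x)
    m4 = step_metrics(smad4)
    r4 = retrigger_ratio(smad4)
    print(f"SMAD4 calibration: alpha={alpha:.4f} gamma={gamma:.4f} "
          f"beta={beta:.4f} delta={delta:.4f}")
    print(f"  baseline_fraction={m4.baseline_fraction:.4f} peak_excess={m4.peak:.3f} "
          f"peak_time={m4.peak_time:.3f} hr timescale={m4.adaptation_timescale:.3f} hr "
          f"retrigger={r4:.3f}")

    def bf_for_KI(k_i: float) -> float:
        p = FeedbackModelParams(alpha=alpha, K_L=K_L, gamma=gamma,
                                beta=beta, delta=delta, K_I=k_i, S0=S0)
        return step_metrics(p).baseline_fraction - 0.60

    k_i_23 = brentq(bf_for_KI, K_I, 1000.0 * K_I, xtol=1e-10)
    smad23 = FeedbackModelParams(alpha=alpha, K_L=K_L, gamma=gamma,
                                 beta=beta, delta=delta, K_I=k_i_23, S0=S0)
    m23 = step_metrics(smad23)
    print(f"SMAD2/3 variant: K_I={k_i_23:.4f} -> baseline_fraction={m23.baseline_fraction:.4f}")

    # -- diagnostics the calibration must not break -------------------------
    doses = [5.0, 12.5, 25.0, 50.0]
    per_dose = [step_metrics(smad4, d) for d in doses]
    peaks = [m.peak for m in per_dose]
    tss = [m.adaptation_timescale for m in per_dose]
    cv_ts = float(np.std(tss) / np.mean(tss))
    print(f"  dose series {doses}: peaks={np.round(peaks,3).tolist()} "
          f"timescale CV={cv_ts:.3f}")

    step = make_step(50.0, 0.0, 24.0)
    ramp = make_ramp(50.0, 10.0, 10, hold_until=24.0)
    tgrid = np.arange(0.0, 24.0 + 1e-9, 0.005)
    pk = lambda sch: float(simulate_feedback(smad4, sch, tgrid).S.max() - S0)
    ratio = pk(ramp) / pk(step)
    print(f"  ramp(10 steps)/step peak-excess ratio = {ratio:.3f}")

    cfg = {
        "feedback_smad4": {"alpha": alpha, "K_L": K_L, "gamma": gamma,
                           "beta": beta, "delta": delta, "K_I": K_I, "S0": S0},
        "feedback_smad23": {"alpha": alpha, "K_L": K_L, "gamma": gamma,
                            "beta": beta, "delta": delta, "K_I": k_i_23, "S0": S0},
        # adapted fraction d_i/d_a = 0.2; recovery (1/d_i) 5x slower than
        # adaptation (1/d_a) -- the ratio the model is disproved by
        "receptor": {"s": 1.0, "d_i": 0.2, "d_a": 1.0, "k_b": 10.0},
        # low BMP doses (~10 ng/ml) lose half-maximal occupancy by ~15 hr
        "ligand_depletion": {"u": 0.15, "L_thresh": 1.0, "alpha": 2.0,
                             "gamma": 2.0, "S0": 1.0, "n_hill": 4.0},
    }
    CONFIG.parent.mkdir(parents=True, exist_ok=True)
    CONFIG.write_text(json.dumps(cfg, indent=2) + "\n")
    print(f"wrote {CONFIG.relative_to(ROOT)}")

    RESULTS.mkdir(exist_ok=True)
    report = {
        "smad4": {"baseline_fraction": m4.baseline_fraction, "peak_excess": m4.peak,
                  "peak_time_hr": m4.peak_time,
                  "adaptation_timescale_hr": m4.adaptation_timescale,
                  "retrigger_ratio_5hr_gap": r4,
                  "timescale_cv_across_doses": cv_ts,
                  "ramp_over_step_peak_ratio": ratio},
        "smad23": {"baseline_fraction": m23.baseline_fraction, "K_I": k_i_23},
    }
    (RESULTS / "calibration_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {(RESULTS / 'calibration_report.json').relative_to(ROOT)}")


if __name__ == "__main__":
    main()
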