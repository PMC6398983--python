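"""ODE models of pathway response to ligand schedules.

Three minimal mechanisms are implemented, each behind its own parameter type
so alternates can be swapped in:

* **Negative feedback** (Activin/Nodal-like, adaptive): receptor occupancy
  drives a signal ``S`` (the nuclear:cytoplasmic SMAD4 ratio proxy) whose own
  excess over the pre-stimulus level ``S0`` produces an inhibitor ``I`` that
  divisively dampens activation::

      dS/dt = alpha * O(L) / (1 + I/K_I) - gamma * (S - S0)
      dI/dt = beta * (S - S0) - delta * I,      O(L) = L / (L + K_L)

  A step input overshoots and relaxes to a plateau above ``S0`` that is
  maintained by continued ligand exposure; the adaptation timescale
  (~1/delta) is independent of dose.

* **Receptor depletion** (the rejected alternative): inactive receptors ``R``
  are made at rate ``s``, degrade at ``d_i``, bind ligand at ``k_b·L`` and the
  active complex ``R*`` degrades at ``d_a``; signal is proportional to ``R*``.
  The adapted fraction of the peak equals ``d_i/d_a`` at saturating ligand, so
  strong adaptation forces recovery (rate ``d_i``) to be much slower than
  adaptation (rate ``d_a``) — the quantitative argument against upstream
  depletion as the adaptation mechanism.

* **Ligand depletion** (BMP-like, sustained): the response itself is
  non-adaptive, but the ligand in the medium is consumed,
  ``dL/dt = -u·L`` between media changes, so low doses give a sustained
  response of dose-dependent duration (the duration of half-maximal
  signaling grows like ``ln(L0/L_thresh)/u``).

Target-gene transcription downstream of a signal trajectory distinguishes
adaptive targets (threshold above the adapted baseline, so transcription
peaks and decays) from sustained targets (threshold below the baseline, so
transcription is maintained by baseline signaling).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .schedules import LigandSchedule, make_step

__all__ = [
    "FeedbackModelParams",
    "ReceptorModelParams",
    "DepletionModelParams",
    "GeneParams",
    "SignalTrajectory",
    "AdaptationMetrics",
    "NoResponseError",
    "WindowTooShortError",
    "IntegrationError",
    "default_feedback_params",
    "default_receptor_params",
    "default_depletion_params",
    "simulate_feedback",
    "simulate_receptor_depletion",
    "simulate_ligand_depletion",
    "adaptation_metrics",
    "classify_dynamics",
    "simulate_target_gene",
    "normalize_ct",
]


class IntegrationError(RuntimeError):
    """ODE solver failure, with the offending parameters echoed."""


class NoResponseError(ValueError):
    """Trajectory shows no excursion above baseline; metrics are undefined."""


class WindowTooShortError(ValueError):
    """Trajectory does not cover enough of the post-peak relaxation."""


# --------------------------------------------------------------------------
# parameter types
# --------------------------------------------------------------------------


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be a positive finite number, got {v}")


@dataclass(frozen=True)
class FeedbackModelParams:
    """Negative-feedback (adaptive) model parameters.

    alpha   max activation rate (ratio units / hr)
    K_L     half-saturating ligand dose (ng/ml)
    gamma   signal relaxation rate (1/hr)
    beta    inhibitor production rate (1/hr)
    delta   inhibitor decay rate (1/hr); adaptation timescale ~ 1/delta
    K_I     inhibitor scale at which activation is halved (dimensionless)
    S0      pre-stimulus signal level (nuc:cyt ratio units)
    """

    alpha: float
    K_L: float
    gamma: float
    beta: float
    delta: float
    K_I: float = 1.0
    S0: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(alpha=self.alpha, K_L=self.K_L, gamma=self.gamma,
                          beta=self.beta, delta=self.delta, K_I=self.K_I, S0=self.S0)

    def occupancy(self, L):
        return np.asarray(L, dtype=float) / (np.asarray(L, dtype=float) + self.K_L)


@dataclass(frozen=True)
class ReceptorModelParams:
    """Receptor-depletion (rejected alternative) model parameters.

    s     receptor synthesis rate (molecules/hr)
    d_i   inactive-receptor degradation rate (1/hr)
    d_a   active-receptor degradation rate (1/hr)
    k_b   ligand-binding rate constant (1/(ng/ml)/hr)

    Pre-stimulus receptor steady state is ``s/d_i``; the adapted baseline
    fraction at saturating ligand is ``d_i/d_a``.
    """

    s: float
    d_i: float
    d_a: float
    k_b: float

    def __post_init__(self) -> None:
        _require_positive(s=self.s, d_i=self.d_i, d_a=self.d_a, k_b=self.k_b)


@dataclass(frozen=True)
class DepletionModelParams:
    """Ligand-depletion (BMP-like, sustained) model parameters.

    u         ligand uptake/depletion rate (1/hr)
    L_thresh  dose at which occupancy is half-maximal (ng/ml); the sharp
              (switch-like) dose response uses Hill coefficient ``n_hill``
    alpha     max activation rate (ratio units / hr)
    gamma     signal relaxation rate (1/hr)
    S0        pre-stimulus signal level
    """

    u: float
    L_thresh: float
    alpha: float
    gamma: float
    S0: float = 1.0
    n_hill: float = 4.0

    def __post_init__(self) -> None:
        _require_positive(u=self.u, L_thresh=self.L_thresh, alpha=self.alpha,
                          gamma=self.gamma, S0=self.S0, n_hill=self.n_hill)

    def occupancy(self, L):
        L = np.asarray(L, dtype=float)
        Ln = np.where(L > 0, L, 0.0) ** self.n_hill
        return Ln / (Ln + self.L_thresh ** self.n_hill)


@dataclass(frozen=True)
class GeneParams:
    """Target-gene transcription parameters.

    mode      'adaptive' (threshold above adapted baseline) or 'sustained'
    a         max transcription rate (1/hr)
    theta     signal threshold (ratio units, excess over S0)
    delta_m   mRNA decay rate (1/hr)
    K_m       half-saturation of the transcriptional response (ratio units)
    """

    mode: Literal["adaptive", "sustained"]
    a: float
    theta: float
    delta_m: float
    K_m: float = 0.1

    def __post_init__(self) -> None:
        _require_positive(a=self.a, delta_m=self.delta_m, K_m=self.K_m)
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.mode not in ("adaptive", "sustained"):
            raise ValueError(f"unknown gene mode {self.mode!r}")


@dataclass
class SignalTrajectory:
    """Time series of a signaling readout on a strictly increasing grid."""

    t: np.ndarray
    S: np.ndarray
    channel: str = "SMAD4"
    schedule_name: str = ""
    model_name: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.t.shape != self.S.shape:
            raise ValueError("t and S must have the same length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.S < -1e-9):
            raise ValueError("signal values must be non-negative")

    @property
    def S0(self) -> float:
        return float(self.params.get("S0", self.S[0]))


@dataclass(frozen=True)
class AdaptationMetrics:
    """Summary of a step response.

    ``baseline_fraction`` is the late-time plateau excess over ``S0`` as a
    fraction of the peak excess; adaptive responses sit well below 1, a
    monotone sustained response reports exactly 1 with an infinite timescale.
    """

    peak: float
    peak_time: float
    baseline: float
    baseline_fraction: float
    adaptation_timescale: float
    S0: float


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

_RTOL = 1e-8
_ATOL = 1e-10


def _integrate_piecewise(rhs, y0, t_grid, breakpoints, params_repr: str):
    """Integrate ``rhs`` over ``t_grid``, restarting at each breakpoint.

    Restarting the adaptive-step solver at schedule discontinuities avoids
    smoothing steps over; dense output is evaluated on the requested grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) < 2 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    cuts = [t for t in np.asarray(breakpoints, dtype=float) if t0 < t < t1]
    edges = [t0, *sorted(set(cuts)), t1]

    out = np.empty((len(np.atleast_1d(y0)), len(t_grid)))
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    for lo, hi in zip(edges, edges[1:]):
        sol = solve_ivp(rhs, (lo, hi), y, method="LSODA",
                        rtol=_RTOL, atol=_ATOL, dense_output=True)
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed on [{lo}, {hi}]: {sol.message}; params={params_repr}"
            )
        mask = (t_grid >= lo) & (t_grid < hi)
        if mask.any():
            out[:, mask] = sol.sol(t_grid[mask])
        y = sol.y[:, -1]
    out[:, -1] = y
    return out


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------


def simulate_feedback(
    params: FeedbackModelParams,
    schedule: LigandSchedule,
    t_grid,
    channel: str = "SMAD4",
) -> SignalTrajectory:
    """Simulate the negative-feedback model under an arbitrary schedule.

    Initial condition is the pre-stimulus steady state (S = S0, I = 0)."""
    p = params

    def rhs(t, y):
        S, I = y
        O = p.occupancy(float(schedule(t)))
        dS = p.alpha * O / (1.0 + I / p.K_I) - p.gamma * (S - p.S0)
        dI = p.beta * (S - p.S0) - p.delta * I
        return (dS, dI)

    y = _integrate_piecewise(rhs, (p.S0, 0.0), t_grid, schedule.breakpoints(), repr(p))
    S = np.clip(y[0], 0.0, None)
    meta = asdict(p)
    return SignalTrajectory(np.asarray(t_grid, float), S, channel=channel,
                            schedule_name=schedule.name, model_name="feedback",
                            params=meta)


def simulate_receptor_depletion(
    params: ReceptorModelParams,
    schedule: LigandSchedule,
    t_grid,
    channel: str = "SMAD4",
) -> SignalTrajectory:
    """Simulate the receptor-depletion model; signal is the active receptor level.

    Returns S proportional to R* with S0 = 0 (no signaling without ligand).
    The full state (R, R*) is stored in ``params['final_state']`` and the R
    trajectory under ``params['R']`` for recovery-timescale analysis.
    """
    p = params

    def rhs(t, y):
        R, Ra = y
        L = float(schedule(t))
        bind = p.k_b * L * R
        return (p.s - p.d_i * R - bind, bind - p.d_a * Ra)

    y0 = (p.s / p.d_i, 0.0)
    y = _integrate_piecewise(rhs, y0, t_grid, schedule.breakpoints(), repr(p))
    meta = asdict(p)
    meta["S0"] = 0.0
    traj = SignalTrajectory(np.asarray(t_grid, float), np.clip(y[1], 0.0, None),
                            channel=channel, schedule_name=schedule.name,
                            model_name="receptor_depletion", params=meta)
    traj.params["R"] = y[0].copy()
    return traj


def simulate_ligand_depletion(
    params: DepletionModelParams,
    L0: float | None = None,
    t_grid=None,
    schedule: LigandSchedule | None = None,
    channel: str = "SMAD4",
) -> SignalTrajectory:
    """Simulate the sustained (BMP-like) response with ligand consumption.

    Either a single bolus ``L0`` at t = t_grid[0] or a full ``schedule`` may
    be given.  With a schedule, the medium is replenished to the nominal
    concentration at every segment boundary (a media change) and decays as
    ``dL/dt = -u L`` in between — a single-segment schedule therefore decays
    over its whole span, reproducing dose-dependent signaling duration at
    low doses.
    """
    if (L0 is None) == (schedule is None):
        raise ValueError("give exactly one of L0 or schedule")
    t_grid = np.asarray(t_grid, dtype=float)
    if schedule is None:
        schedule = make_step(float(L0), t_on=float(t_grid[0]), t_off=float(t_grid[-1]),
                             name=f"bolus_{L0:g}")
    p = params

    def rhs(t, y):
        S, L = y
        dS = p.alpha * float(p.occupancy(max(L, 0.0))) - p.gamma * (S - p.S0)
        return (dS, -p.u * max(L, 0.0))

    # integrate segment by segment, resetting L to nominal at each boundary
    edges = schedule.breakpoints()
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    cuts = [t for t in edges if t0 < t < t1]
    bounds = [t0, *cuts, t1]
    S_out = np.empty_like(t_grid)
    L_out = np.empty_like(t_grid)
    y = np.array([p.S0, float(schedule(t0))])
    for lo, hi in zip(bounds, bounds[1:]):
        y[1] = float(schedule(lo))  # media change replenishes ligand
        sol = solve_ivp(rhs, (lo, hi), y, method="LSODA", rtol=_RTOL, atol=_ATOL,
                        dense_output=True)
        if not sol.success:
            raise IntegrationError(f"ligand-depletion integration failed: {sol.message}; "
                                   f"params={p!r}")
        mask = (t_grid >= lo) & (t_grid < hi)
        if mask.any():
            S_out[mask], L_out[mask] = sol.sol(t_grid[mask])
        y = sol.y[:, -1]
    S_out[t_grid == t1], L_out[t_grid == t1] = y
    meta = asdict(p)
    traj = SignalTrajectory(t_grid, np.clip(S_out, 0.0, None), channel=channel,
                            schedule_name=schedule.name, model_name="ligand_depletion",
                            params=meta)
    traj.params["L"] = L_out  # remaining ligand, for depletion diagnostics
    return traj


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def adaptation_metrics(
    traj: SignalTrajectory,
    S0: float | None = None,
    baseline_window: float = 0.10,
    min_excess: float = 1e-3,
) -> AdaptationMetrics:
    """Peak / baseline / timescale summary of a (putative) step response.

    peak                maximum excess of S over S0
    baseline            mean of the final ``baseline_window`` fraction of the trace
    baseline_fraction   (baseline - S0) / (peak - S0); exactly 1 for monotone
                        sustained responses
    adaptation_timescale  time from the peak until the excess above baseline
                        has decayed to 1/e of (peak - baseline); +inf when
                        the trajectory never relaxes

    Raises :class:`NoResponseError` when the peak excess is negligible and
    :class:`WindowTooShortError` when the window after the peak covers less
    than 4 adaptation timescales.
    """
    s0 = traj.S0 if S0 is None else float(S0)
    t, S = traj.t, traj.S
    excess = S - s0
    i_peak = int(np.argmax(excess))
    peak = float(excess[i_peak])
    if peak <= min_excess:
        raise NoResponseError(
            f"no response: peak excess {peak:.3g} <= {min_excess:.3g} over S0={s0:.3g}"
        )
    span = t[-1] - t[0]
    n_tail = max(2, int(np.ceil(baseline_window * len(t))))
    baseline = float(np.mean(S[-n_tail:]))
    peak_time = float(t[i_peak])

    # monotone sustained: the peak sits in (or at the edge of) the tail window
    if i_peak >= len(t) - n_tail or peak - (baseline - s0) <= 0.02 * peak:
        return AdaptationMetrics(peak=peak, peak_time=peak_time, baseline=baseline,
                                 baseline_fraction=1.0,
                                 adaptation_timescale=math.inf, S0=s0)

    target = (baseline - s0) + (peak - (baseline - s0)) / math.e
    post = excess[i_peak:]
    t_post = t[i_peak:]
    below = np.nonzero(post <= target)[0]
    if len(below) == 0:
        timescale = math.inf
        bf = 1.0
    else:
        j = below[0]
        # linear interpolation between the bracketing samples
        if j == 0:
            t_cross = t_post[0]
        else:
            y0e, y1e = post[j - 1], post[j]
            frac = (y0e - target) / (y0e - y1e) if y1e != y0e else 0.0
            t_cross = t_post[j - 1] + frac * (t_post[j] - t_post[j - 1])
        timescale = float(t_cross - peak_time)
        bf = float((baseline - s0) / peak)
        if (t[-1] - peak_time) < 4.0 * timescale:
            raise WindowTooShortError(
                f"window after peak ({t[-1] - peak_time:.3g} hr) is shorter than "
                f"4x the adaptation timescale ({timescale:.3g} hr)"
            )
    return AdaptationMetrics(peak=peak, peak_time=peak_time, baseline=baseline,
                             baseline_fraction=bf, adaptation_timescale=timescale,
                             S0=s0)


def classify_dynamics(metrics: AdaptationMetrics) -> str:
    """'sustained' (bf >= 0.8), 'adaptive' (bf <= 0.5) or 'intermediate'."""
    if metrics.baseline_fraction >= 0.8:
        return "sustained"
    if metrics.baseline_fraction <= 0.5:
        return "adaptive"
    return "intermediate"


# --------------------------------------------------------------------------
# target genes and qPCR normalization
# --------------------------------------------------------------------------


def simulate_target_gene(
    gene: GeneParams,
    traj: SignalTrajectory,
    t_inhibit: float | None = None,
    m0: float = 0.0,
) -> np.ndarray:
    """mRNA time series on ``traj.t`` driven by the signal trajectory.

    dm/dt = a * h(max(S - S0 - theta, 0)) - delta_m * m  with the saturating
    response h(x) = x / (x + K_m).  ``t_inhibit`` models acute pathway
    inhibition: the signal is clamped to S0 from that time on, so mRNA decays
    exponentially at rate ``delta_m`` thereafter (rapid decline of stably
    expressed targets on inhibitor treatment).
    """
    t, S = traj.t, traj.S.copy()
    s0 = traj.S0
    if t_inhibit is not None:
        S[t >= t_inhibit] = s0
    drive = np.maximum(S - s0 - gene.theta, 0.0)
    h = drive / (drive + gene.K_m)
    # exact exponential integrator on the (piecewise-interpolated) drive
    m = np.empty_like(t)
    m[0] = m0
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        hbar = 0.5 * (h[i] + h[i - 1])
        decay = math.exp(-gene.delta_m * dt)
        m[i] = m[i - 1] * decay + gene.a * hbar / gene.delta_m * (1.0 - decay)
    return m


def normalize_ct(ct_target, ct_reference):
    """log2 expression of a qPCR target relative to the reference gene.

    Each PCR cycle doubles the product, so relative log2 expression is
    ``-(ct_target - ct_reference)``.
    """
    return -(np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float))


# --------------------------------------------------------------------------
# shipped calibrations
# --------------------------------------------------------------------------


def _load_config() -> dict:
    with resources.files("smaddyn").joinpath("config/model_defaults.json").open() as fh:
        return json.load(fh)


def default_feedback_params(channel: str = "SMAD4") -> FeedbackModelParams:
    """Shipped feedback-model calibration for the given channel.

    'SMAD4' is calibrated so that a saturating 50 ng/ml Activin-like step
    yields a late plateau at 20% of the peak excess, a peak near 1 hr and an
    adaptation timescale near 2 hr.  'SMAD2/3' shares all rates but has a
    weaker feedback (larger K_I), calibrated to a 60% plateau.
    """
    cfg = _load_config()
    key = {"SMAD4": "feedback_smad4", "SMAD2/3": "feedback_smad23"}.get(channel)
    if key is None:
        raise ValueError(f"no default calibration for channel {channel!r}")
    return FeedbackModelParams(**cfg[key])


def default_receptor_params() -> ReceptorModelParams:
    return ReceptorModelParams(**_load_config()["receptor"])


def default_depletion_params() -> DepletionModelParams:
    return DepletionModelParams(**_load_config()["ligand_depletion"])
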