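"""Fluorescence recovery after photobleaching for a shuttling protein.

The model: SMAD4 exists in four pools — free nuclear and free cytoplasmic
molecules that exchange with import rate ``k_in`` and export rate ``k_out``
(first-order, per minute), and *sequestered* nuclear and cytoplasmic
populations that may move within but not between compartments on the
recovery timescale.  Production and degradation are slow compared to
shuttling, so recovery after a nuclear bleach comes purely from
redistribution of unbleached molecules.

Consequences used throughout:

* nuclear fluorescence recovers as a single exponential with rate
  ``k = k_in + k_out`` (the non-zero eigenvalue of the 2x2 exchange system);
* with no sequestration, the post-recovery nuclear:cytoplasmic ratio R'
  equals the pre-bleach ratio R (the ratio is purely kinetic);
* with cytoplasmic sequestration, part of the cytoplasmic pool cannot enter
  the nucleus to replace bleached molecules there, so R' < R — the
  diagnostic for sequestered populations.

Intensities are bookkept per unit area with the effective nuclear/cytoplasmic
volume ratio folded into R; no explicit geometry.  Pre-bleach steady state
requires ``k_in * C_free = k_out * N_free``, which fixes
``R = (k_in/k_out) * (1 - f_cs) / (1 - f_ns)``; R is therefore derived, not
free.

The inversion implemented by :func:`infer_sequestration` maps measured
ensemble means of (A/I_nuc_pre, k, R, R') back to (f_ns, f_cs, k_out) — and
the bleach depth, which drops out — with first-order (delta-method) error
propagation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit

__all__ = [
    "ShuttlingParams",
    "FrapTrace",
    "FrapFit",
    "FitFailure",
    "SequestrationEstimate",
    "simulate_frap",
    "fit_recovery",
    "infer_sequestration",
    "K_IN_DEFAULT",
]

# Nuclear import rate convention (1/min). The model fixes the import rate so
# that measured recovery rates map one-to-one onto export rates; all k_out
# values in this package are relative to this convention.
K_IN_DEFAULT = 0.04


@dataclass(frozen=True)
class ShuttlingParams:
    """Shuttling/sequestration model parameters for one cell.

    k_in, k_out   free-pool import/export rates (1/min)
    f_ns, f_cs    fraction of nuclear / cytoplasmic molecules sequestered
    bleach_eff    fraction of nuclear fluorescence destroyed at the bleach
    """

    k_in: float = K_IN_DEFAULT
    k_out: float = 0.08
    f_ns: float = 0.0
    f_cs: float = 0.0
    bleach_eff: float = 0.7

    def __post_init__(self) -> None:
        if self.k_in <= 0 or self.k_out <= 0:
            raise ValueError("rates must be positive")
        for name in ("f_ns", "f_cs", "bleach_eff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.f_ns >= 1.0 or self.f_cs >= 1.0:
            raise ValueError("sequestered fractions must be < 1 (free pool required)")

    @property
    def R(self) -> float:
        """Pre-bleach nuclear:cytoplasmic intensity ratio (steady state)."""
        return (self.k_in / self.k_out) * (1.0 - self.f_cs) / (1.0 - self.f_ns)

    @property
    def recovery_rate(self) -> float:
        """Exchange relaxation rate k_in + k_out (1/min)."""
        return self.k_in + self.k_out


@dataclass
class FrapTrace:
    """One cell's bleach-recovery record (times in seconds)."""

    t: np.ndarray
    I_nuc: np.ndarray
    I_cyt: np.ndarray
    t_bleach: float
    cell_id: int = 0
    condition: str = "untreated"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I_nuc = np.asarray(self.I_nuc, dtype=float)
        self.I_cyt = np.asarray(self.I_cyt, dtype=float)
        if not (len(self.t) == len(self.I_nuc) == len(self.I_cyt)):
            raise ValueError("t, I_nuc, I_cyt must have equal length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class FrapFit:
    """Exponential recovery fit I_nuc(t) = I_inf - A exp(-k (t - t_bleach)).

    ``k`` is reported in 1/min. ``R`` is the pre-bleach ratio, ``R_prime``
    the ratio over the final 10% of the trace. ``I_pre_nuc`` (pre-bleach
    nuclear intensity) normalizes A for the sequestration inversion.
    """

    A: float
    k: float
    I_inf: float
    R: float
    R_prime: float
    I_pre_nuc: float
    se_A: float
    se_k: float
    cell_id: int = 0
    condition: str = "untreated"
    flag: Literal["ok", "no_bleach", "fit_failure"] = "ok"
    plateau_vs_tail: float = 0.0  # diagnostic: fitted plateau minus tail mean


class FitFailure(RuntimeError):
    """Unrecoverable failure of the exponential recovery fit."""


@dataclass(frozen=True)
class SequestrationEstimate:
    """Inferred sequestration fractions and export rate with propagated SEs."""

    f_ns_hat: float
    f_cs_hat: float
    k_out_hat: float
    se_f_ns: float
    se_f_cs: float
    se_k_out: float
    n_cells: int
    condition: str = ""
    boundary_clipped: bool = False


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------


def simulate_frap(
    params: ShuttlingParams,
    duration: float | None = None,
    dt: float = 10.0,
    t_bleach: float = 120.0,
    I_cyt_pre: float = 100.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    cell_id: int = 0,
    condition: str = "untreated",
) -> FrapTrace:
    """Simulate a nuclear-bleach FRAP trace (times in seconds).

    The trace holds the pre-bleach steady state until ``t_bleach``; the bleach
    instantaneously multiplies all nuclear fluorescent amounts by
    ``1 - bleach_eff``; afterwards only the free pools exchange (integrated
    numerically), sequestered fluorescence stays put, and nothing is produced
    or degraded.  ``duration`` defaults to 8 relaxation times after the
    bleach so the tail readout of R' sits on the plateau.
    """
    p = params
    k_in_s = p.k_in / 60.0
    k_out_s = p.k_out / 60.0
    if duration is None:
        duration = t_bleach + 8.0 / (k_in_s + k_out_s)
    if duration < t_bleach + 5.0 / (k_in_s + k_out_s):
        raise ValueError("duration must cover >= 5 exchange relaxation times")

    C = I_cyt_pre
    N = p.R * C
    N_f0, N_s0 = (1 - p.f_ns) * N, p.f_ns * N
    C_f0, C_s0 = (1 - p.f_cs) * C, p.f_cs * C

    t = np.arange(0.0, duration + 1e-9, dt)
    I_nuc = np.empty_like(t)
    I_cyt = np.empty_like(t)
    pre = t < t_bleach
    I_nuc[pre] = N
    I_cyt[pre] = C

    w = 1.0 - p.bleach_eff
    y0 = (w * N_f0, C_f0)

    def rhs(_t, y):
        nf, cf = y
        flux = k_in_s * cf - k_out_s * nf
        return (flux, -flux)

    t_post = t[~pre] - t_bleach
    if len(t_post):
        sol = solve_ivp(rhs, (0.0, float(t_post[-1]) if t_post[-1] > 0 else 1e-9),
                        y0, t_eval=t_post, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"FRAP integration failed: {sol.message}")
        I_nuc[~pre] = sol.y[0] + w * N_s0
        I_cyt[~pre] = sol.y[1] + C_s0

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        I_nuc = I_nuc + rng.normal(0.0, noise_sd, size=I_nuc.shape)
        I_cyt = I_cyt + rng.normal(0.0, noise_sd, size=I_cyt.shape)

    truth = {"k_in": p.k_in, "k_out": p.k_out, "f_ns": p.f_ns, "f_cs": p.f_cs,
             "bleach_eff": p.bleach_eff, "R": p.R,
             "recovery_rate": p.recovery_rate}
    return FrapTrace(t, I_nuc, I_cyt, t_bleach=t_bleach, cell_id=cell_id,
                     condition=condition, ground_truth=truth)


# --------------------------------------------------------------------------
# recovery fitting
# --------------------------------------------------------------------------


def fit_recovery(trace: FrapTrace, min_rel_amplitude: float = 0.02) -> FrapFit:
    """Least-squares exponential fit to the post-bleach nuclear recovery.

    R is the mean pre-bleach I_nuc/I_cyt; R' is taken from the final 10% of
    the trace (robust empirical readout; the difference to the fitted plateau
    ratio is kept as a diagnostic).  Fits with k <= 0, relative SE(k) > 100%
    or non-convergence are flagged ``fit_failure``; traces with negligible
    intensity drop are flagged ``no_bleach``.
    """
    t, In, Ic = trace.t, trace.I_nuc, trace.I_cyt
    pre = t < trace.t_bleach
    post = ~pre
    if pre.sum() < 1 or post.sum() < 10:
        raise FitFailure("need >= 1 pre-bleach and >= 10 post-bleach samples")
    I_pre = float(np.mean(In[pre]))
    R = float(np.mean(In[pre] / Ic[pre]))

    n_tail = max(2, int(np.ceil(0.10 * len(t))))
    R_prime = float(np.mean(In[-n_tail:] / Ic[-n_tail:]))

    tp = t[post] - trace.t_bleach
    yp = In[post]

    drop = I_pre - yp[0]
    if abs(drop) < min_rel_amplitude * abs(I_pre):
        return FrapFit(A=0.0, k=math.nan, I_inf=I_pre, R=R, R_prime=R_prime,
                       I_pre_nuc=I_pre, se_A=math.nan, se_k=math.nan,
                       cell_id=trace.cell_id, condition=trace.condition,
                       flag="no_bleach")

    def model(tt, I_inf, A, k):
        return I_inf - A * np.exp(-k * tt)

    # initial guesses from the data: plateau ~ tail, amplitude ~ span,
    # rate from the 1 - 1/e crossing
    I_inf0 = float(np.mean(yp[-n_tail:]))
    A0 = max(I_inf0 - yp[0], 1e-6)
    span = I_inf0 - yp[0]
    target = yp[0] + (1 - 1 / math.e) * span
    above = np.nonzero(yp >= target)[0]
    k0 = 1.0 / max(tp[above[0]], tp[1]) if len(above) else 1.0 / max(tp[-1] / 3, 1e-6)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, tp, yp, p0=(I_inf0, A0, k0), maxfev=20000)
    except RuntimeError as err:
        raise FitFailure(f"recovery fit did not converge: {err}") from err
    I_inf, A, k_s = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    se_A, se_k_s = float(se[1]), float(se[2])
    flag = "ok"
    if k_s <= 0 or not np.isfinite(k_s) or (np.isfinite(se_k_s) and se_k_s > abs(k_s)):
        flag = "fit_failure"
    ratio_inf = I_inf / float(np.mean(Ic[-n_tail:]))
    return FrapFit(A=float(A), k=float(k_s * 60.0), I_inf=float(I_inf), R=R,
                   R_prime=R_prime, I_pre_nuc=I_pre, se_A=se_A,
                   se_k=float(se_k_s * 60.0), cell_id=trace.cell_id,
                   condition=trace.condition, flag=flag,
                   plateau_vs_tail=float(ratio_inf - R_prime))


# --------------------------------------------------------------------------
# sequestration inference
# --------------------------------------------------------------------------


def _rprime_model(u: float, w: float, R: float, k_in: float, k_out: float) -> float:
    """Post-recovery ratio predicted by the sequestration model.

    u = 1 - f_ns (free nuclear fraction), w = 1 - bleach_eff; the cytoplasmic
    free fraction follows from the steady-state constraint: 1 - f_cs = rho*u
    with rho = k_out R / k_in.  Intensities in units of the pre-bleach
    cytoplasmic intensity.
    """
    k = k_in + k_out
    rho = k_out * R / k_in
    phi = k_in / k
    Tf = u * (w * R + rho)
    num = phi * Tf + (1.0 - u) * w * R
    den = (1.0 - phi) * Tf + (1.0 - rho * u)
    return num / den


def _invert(a: float, k: float, R: float, R_prime: float,
            k_in: float) -> tuple[float, float, float, bool]:
    """Closed-form-constrained inversion -> (f_ns, f_cs, k_out, clipped).

    a is the relative recovery amplitude A / I_nuc_pre.  Derived from the
    forward model: a = (1 - f_ns) * bleach_eff * k_out / k, the steady-state
    ratio constraint, and the R' expression; solved for u = 1 - f_ns by
    bracketed root finding.
    """
    clipped = False
    k_out = k - k_in
    if k_out <= 0:
        k_out = 1e-6
        clipped = True
    rho = k_out * R / k_in
    alpha = a * k / k_out          # = u * (1 - w) = u * bleach_eff
    u_max = min(1.0, 1.0 / rho) if rho > 0 else 1.0
    u_min = min(alpha, u_max)      # need w >= 0  ->  u >= alpha

    def g(u: float) -> float:
        w = 1.0 - alpha / u
        return _rprime_model(u, w, R, k_in, k_out) - R_prime

    lo = max(u_min, 1e-9) * (1 + 1e-12)
    hi = u_max * (1 - 1e-12)
    if lo >= hi:
        return 0.0, float(np.clip(1.0 - rho * u_max, 0, 1)), k_out, True
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        # measured R' outside the feasible band (noise): clip to nearer end
        u = lo if abs(glo) < abs(ghi) else hi
        clipped = True
    else:
        u = brentq(g, lo, hi, xtol=1e-12)
    f_ns = 1.0 - u
    f_cs = 1.0 - rho * u
    if not 0.0 <= f_cs <= 1.0:
        f_cs = float(np.clip(f_cs, 0.0, 1.0))
        clipped = True
    if not 0.0 <= f_ns <= 1.0:
        f_ns = float(np.clip(f_ns, 0.0, 1.0))
        clipped = True
    return f_ns, f_cs, k_out, clipped


def infer_sequestration(
    fits: Sequence[FrapFit],
    k_in: float = K_IN_DEFAULT,
    condition: str | None = None,
) -> SequestrationEstimate:
    """Infer (f_ns, f_cs, k_out) from an ensemble of recovery fits.

    Condition means of (A/I_nuc_pre, k, R, R') are pushed through the model
    inversion; standard errors of those means are propagated to first order
    (delta method, numerical Jacobian).  Fits flagged as failures are
    excluded with a logged count; at least 3 usable fits are required.
    """
    if k_in <= 0:
        raise ValueError("k_in must be positive")
    usable = [f for f in fits if f.flag == "ok"]
    n_dropped = len(fits) - len(usable)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} flagged fit(s) from inference")
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable fits, got {len(usable)}")
    if condition is None:
        condition = usable[0].condition

    obs = np.array([[f.A / f.I_pre_nuc, f.k, f.R, f.R_prime] for f in usable])
    mean = obs.mean(axis=0)
    sem = obs.std(axis=0, ddof=1) / math.sqrt(len(usable))

    f_ns, f_cs, k_out, clipped = _invert(*mean, k_in=k_in)
    if clipped:
        warnings.warn("sequestration inversion hit the feasible-region boundary; "
                      "estimate clipped")

    # delta method with a numerical Jacobian of (f_ns, f_cs, k_out) wrt the
    # four observable means
    jac = np.zeros((3, 4))
    for j in range(4):
        h = max(1e-6, 1e-4 * abs(mean[j]))
        up, dn = mean.copy(), mean.copy()
        up[j] += h
        dn[j] -= h
        pu = _invert(*up, k_in=k_in)[:3]
        pd = _invert(*dn, k_in=k_in)[:3]
        jac[:, j] = (np.array(pu) - np.array(pd)) / (2 * h)
    var = jac @ np.diag(sem ** 2) @ jac.T
    se = np.sqrt(np.clip(np.diag(var), 0.0, None))
    if not np.all(np.isfinite(se)):
        raise RuntimeError("propagated standard errors are not finite")

    return SequestrationEstimate(
        f_ns_hat=f_ns, f_cs_hat=f_cs, k_out_hat=k_out,
        se_f_ns=float(se[0]), se_f_cs=float(se[1]), se_k_out=float(se[2]),
        n_cells=len(usable), condition=condition, boundary_clipped=clipped,
    )
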