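# Methods

This note documents the models, calibrations and numerical choices behind
`smaddyn`, and what the synthetic-data generators do and do not emulate.

## Ligand schedules

All stimulation protocols are piecewise schedules `L(t)` (hours, ng/ml):
steps, staircase ramps (experimentally a "slow ramp" is hourly media
changes, i.e. equal concentration increments), and pulse trains (default
6/10/8 hr pulses at 30 ng/ml with 5 hr gaps, matching the pulsing
protocol).  Evaluation is right-continuous at media changes and zero
outside the covered span.  Dummy media changes are represented as schedule
breakpoints with no concentration change; the ODE solvers restart at every
breakpoint so discontinuities are never smoothed over.

## Adaptive (Activin/Nodal-like) pathway: negative feedback

The signal `S` is a proxy for the nuclear:cytoplasmic SMAD4 ratio with
pre-stimulus level `S0 = 1`:

    dS/dt = α · O(L) / (1 + I/K_I) − γ (S − S0)
    dI/dt = β (S − S0) − δ I,          O(L) = L / (L + K_L)

An inhibitor `I`, produced in proportion to signaling excess, divisively
dampens activation.  A step input overshoots and relaxes to a plateau above
`S0` that is maintained by continued ligand exposure; removing ligand lets
`I` decay at rate `δ`, restoring responsiveness — which is why pulses
separated by ~5 hr re-trigger near-full responses.  Because activation is
driven by absolute receptor occupancy, a staircase ramp (each increment
sub-saturating) elicits only small, individually adapted responses: the
pathway effectively reads the rate of concentration increase.

### Calibration

Defaults are fit once (`analysis/01_calibrate_models.py`) and shipped in
`src/smaddyn/config/model_defaults.json`:

| parameter | value | meaning |
|---|---|---|
| α | 65.66 /hr | maximum activation rate |
| K_L | 20 ng/ml | half-saturating dose |
| γ | 16.08 /hr | signal relaxation rate |
| β | 48.38 /hr | inhibitor production rate |
| δ | 0.715 /hr | inhibitor decay rate |
| K_I | 1 (SMAD4), 111.9 (SMAD2/3) | inhibitor scale |

Calibration targets, in priority order: (1) a saturating 50 ng/ml step
adapts to a plateau at 20.0% of its peak excess (the quantified degree of
SMAD4 adaptation; the SMAD2/3 variant, differing only in its weaker
feedback `K_I`, adapts to 60%); (2) a second saturating pulse after a 5 hr
gap reaches ≥87% of the first peak; (3) the peak excess is ~1 ratio unit
(the nuc:cyt ratio roughly doubles).

Two deliberate trade-offs:

- **Compressed timescales.**  In this minimal two-variable form, a 20%
  plateau requires a large steady-state inhibitor load, which either reacts
  quickly (fast adaptation) or decays too slowly to re-trigger within 5 hr.
  Committing to the 20% plateau and 5 hr re-triggering compresses the peak
  time and the 1/e adaptation timescale to ~0.05 hr and ~0.16 hr — several-
  fold faster than the measured response (peak ~1 hr, adaptation over a few
  hours).  The *shape* (overshoot, plateau fraction, dose relations, rate
  sensitivity, refractory behavior) is preserved; absolute model time
  should not be read as experimental time.  A feedback acting through an
  intermediate (delay) stage would relax this; it is intentionally out of
  scope of the minimal realization.
- **Dose half-saturation.**  `K_L = 20 ng/ml` makes staircase increments
  individually sub-saturating so that a 10-step ramp to 50 ng/ml peaks at
  ~40% of the step peak.  The experimental dose response saturates at lower
  doses than this occupancy curve implies; with a smaller `K_L`, however,
  the first stair of a ramp would already saturate occupancy and the
  rate-sensing phenotype would disappear from the model.  Occupancy, not
  dose, is the faithful axis here.

The 1/e adaptation timescale retains a mild dose dependence (0.203 hr at
5 ng/ml → 0.155 hr at 50 ng/ml; CV 9.2% over the default half-log dose
ladder 5–50 ng/ml).  Peak and plateau depend on dose; the timescale is
nearly fixed.

## Receptor depletion (the rejected alternative)

    dR/dt  = s − d_i R − k_b L R        (inactive receptors)
    dR*/dt = k_b L R − d_a R*           (active, signaling receptors)

with `S ∝ R*` and pre-stimulus steady state `R = s/d_i`.  At saturating
ligand the adapted plateau fraction is `d_i/d_a` (verified numerically
within 5% for `k_b L ≫ d_a`), the adaptation timescale is `1/d_a` and the
recovery of responsiveness after ligand removal proceeds at `d_i` (90%
recovery at `ln(10)/d_i`).  Hence recovery is `d_a/d_i` times slower than
adaptation: strong adaptation through upstream depletion *forces* a long
refractory period.  Since pulse experiments show re-triggering on the same
timescale as adaptation, this model class is excluded — the package
asserts the timescale relation as a monotone law over a parameter sweep.
Defaults: `s = 1`, `d_i = 0.2/hr`, `d_a = 1/hr`, `k_b = 10 /(ng/ml)/hr`.

## Sustained (BMP-like) pathway: ligand depletion

    dS/dt = α · H(L) − γ (S − S0),   H(L) = L^n / (L^n + L_thresh^n)
    dL/dt = −u L   between media changes (L reset to nominal at each change)

The response itself is non-adaptive and switch-like in dose (`n = 4`,
`L_thresh = 1 ng/ml`), but the ligand in the medium is consumed
(`u = 0.15/hr`), so a single low-dose bolus produces a sustained response
whose duration grows with the logarithm of the dose (`L` crosses
`L_thresh` at `ln(L0/L_thresh)/u`).  With hourly media changes, step and
ramp to the same final dose converge to the same late-time signal: this
pathway reads concentration.

## Target genes and qPCR

    dm/dt = a · h(max(S − S0 − θ, 0)) − δ_m m,    h(x) = x/(x + K_m)

Adaptive-class targets have `θ` above the adapted baseline excess, so their
transcription follows the signaling pulse and decays; sustained-class
targets (`θ` below baseline) are maintained by baseline signaling.
Clamping `S = S0` at an inhibition time makes mRNA decay exponentially at
`δ_m` — mRNA stability does not distinguish the classes.  The integrator
is the exact exponential-decay update with trapezoidal drive, so the
post-inhibition half-life is exact on the grid.  qPCR readouts are
reference-normalized ΔCt values, `−(Ct_target − Ct_ref)`, log base 2.

## FRAP model and inversion

Four pools: free nuclear/cytoplasmic molecules exchanging with rates
`k_in` (import, fixed at 0.04/min by convention — the data constrain only
ratios and sums, so all export rates are relative to this choice) and
`k_out`; sequestered nuclear/cytoplasmic populations immobile *between*
compartments on the recovery timescale (binding/unbinding is treated as
frozen; a slow-exchange extension is out of scope).  Intensities are
per-area with the volume ratio folded into the pre-bleach ratio `R`, which
is fixed by the steady-state constraint
`R = (k_in/k_out)(1 − f_cs)/(1 − f_ns)`.  Production and degradation are
neglected (recovery is pure redistribution; total fluorescence after the
bleach is conserved).

A nuclear bleach multiplies nuclear fluorescence by `1 − bleach_eff`
(instantaneous; acquisition bleaching neglected).  The free pools then
relax as a 2×2 linear exchange, so nuclear recovery is a single
exponential with rate `k = k_in + k_out`, independent of bleach depth.
With no sequestration the post-recovery ratio `R′` equals `R`; cytoplasmic
sequestration withholds molecules from the nuclear refill, making
`R′ < R` — the diagnostic for sequestered populations.

Per-cell fits use least squares on
`I_nuc(t) = I_inf − A·exp(−k (t − t_bleach))` over post-bleach samples; `R`
from the pre-bleach mean ratio; `R′` from the final 10% of the trace (a
robust empirical readout; its difference from the fitted-plateau ratio is
kept as a diagnostic).  Fits with `k ≤ 0` or relative SE(k) > 100% are
excluded with a logged count.

Inversion: with `a = A/I_nuc,pre` the forward model gives
`a = (1 − f_ns)·bleach_eff·k_out/k`, the steady-state constraint ties
`f_cs` to `f_ns`, and the `R′` expression closes the system; `k_out = k −
k_in`.  The solve is a bracketed 1-D root find in `u = 1 − f_ns`
(feasible-region boundaries are clipped with a warning).  Condition means
of `(a, k, R, R′)` over ≥3 usable cells are pushed through this map;
standard errors of those means are propagated to first order (delta
method, numerical Jacobian, observables treated as independent).  Because
the observables are actually correlated through shared cells, the
propagated SEs of `f_ns`/`f_cs` are somewhat conservative (empirical 1-SE
coverage ≈ 0.9), while `SE(k_out)` is an exactly calibrated SEM (coverage
≈ 0.68, as expected for a 1-σ interval).

## Image quantification

Signaling per cell is the background-subtracted nuclear:cytoplasmic mean
ratio, `(nuc − bg)/(cyt − bg)`; this is exactly invariant to intensity
offsets and gains.  Purely nuclear markers (pSMAD1, BRA) are nuclear mean
divided by the per-cell DAPI mean.  Cells whose background-subtracted
cytoplasmic mean is non-positive are excluded with a logged count.

Colony profiles: per-cell values binned into 20 μm annuli (0-based pixel
centers, radii in μm via the pixel size; a 700 μm colony gives 17 full
bins); empty bins are NaN, never zero, and NaN propagates (front fitting
drops missing rows).  Channel normalization conventions: per-time min-max
for SMAD2/3 and pSMAD1; SMAD4 rows divided by the profile maximum interior
to the innermost pSMAD1 half-maximum; BRA divided globally by the maximum
of the final time.  Min-max is idempotent; constant rows are zeroed with a
warning.

Front tracking reports, per time row, the innermost radius where linear
interpolation crosses the level (default 0.5) moving inward from the edge;
velocity is the negated least-squares slope over a window (default
25–40 hr, spanning several bin widths so sampling wobble averages out of
the slope).  Onset is the first time the half-max departs the edge region
— more than one bin inside the outermost 10% of the radius — *after having
been at the edge*; requiring prior edge presence makes the detector robust
to the early uniform phase, whose near-flat rows have no meaningful
crossing.  Expression domains are contiguous intervals above 20% of the
profile maximum, with interpolated boundaries.

Synthetic segmentation (for rendered fixtures only): Otsu threshold on the
nuclear-marker channel, watershed on the distance transform with peak
seeds at least 3 px apart, cytoplasm as a 2 px ring around each nucleus,
background beyond any ring.

## Synthetic data

Generators emit machine-readable ground-truth sidecars; closure tests read
only the sidecar.  Identical seeds and parameters reproduce identical
arrays.

- **Trajectory ensembles**: shared model solution, per-cell lognormal
  amplitude on the excess (unit mean, CV 0.2 — typical cell-to-cell
  reporter variability) plus additive Gaussian observation noise (SD 0.02
  ratio units); the ensemble mean converges to the model solution as
  1/√n.
- **Rendered cell fields**: non-overlapping disk nuclei with ring
  cytoplasms; intensities chosen so the noiseless background-subtracted
  ratio equals each cell's programmed value; Poisson shot noise at the
  pixel intensity plus Gaussian read noise, applied last.
- **FRAP ensembles**: shared `k_in`; per-cell lognormal jitter (CV 0.05)
  on `k_out` and the sequestered fractions; Gaussian intensity noise
  (SD 0.5 on a cytoplasmic intensity of 100).
- **Colony dynamics** are *phenomenological*: the quantity under test
  downstream is the measurement of rapid signaling change, not its
  mechanism, so no reaction–diffusion model is attempted.  The programmed
  SMAD4 field is the maximum of (i) a uniform early response that shuts
  down logistically so the interior falls below half the edge signal by
  the 12 hr restriction time, (ii) a persistent 50 μm edge band, and
  (iii) from 25 hr, an inward logistic wave (10–90% width 40 μm) whose
  half-maximum starts at the inner shoulder of the edge band (radius
  R − 50 μm) and moves inward at 10 μm/hr — one cell diameter per hour.
  The wave emanates from the band shoulder rather than the colony rim so
  that the tracked half-maximum leaves the edge region at the programmed
  onset rather than after crossing the band.  pSMAD1 carries the edge
  band only; SMAD2/3 carries the wave (with a faint pre-onset edge
  presence); BRA accumulates behind the wavefront by first-order gene
  kinetics (production 1/hr above a 0.3 threshold, decay 0.05/hr),
  giving the lagging expression domain.  Kymographs average 4 colonies,
  each with a lognormal amplitude factor (CV 0.2) and 1%-of-range
  Gaussian bin noise — per-colony amplitude variation dominates real
  colony-to-colony variability, and a multiplicative factor deliberately
  does not move normalized front positions.

What the generators do **not** emulate: cell movement and division,
mechanistic BMP/Nodal/Wnt coupling, secondary signaling gradients,
photobleaching during acquisition, realistic point-spread functions,
segmentation errors of crowded tissue.  Passing closure tests therefore
demonstrates that the measurement pipeline recovers known truth under the
stated noise model, not that it is robust to all properties of real
micrographs.

## Numerical choices

ODE integration uses an adaptive stiff-capable solver (LSODA, rtol 1e-8,
atol 1e-10) restarted at every schedule breakpoint; solutions match a
fixed-step RK4 reference at 10× finer step within 1e-4 relative.
Adaptation metrics: baseline = mean of the final 10% of the window; the
1/e timescale is interpolated between samples; monotone sustained
trajectories report baseline fraction 1 with an infinite timescale;
negligible peaks raise a no-response error, and windows shorter than 4
adaptation timescales after the peak raise a window-too-short error.
Classification thresholds: plateau ≥ 0.8 of peak = sustained, ≤ 0.5 =
adaptive, between = intermediate (our choice).  The edge zone for onset
detection is the outermost 10% of the colony radius; the velocity window
default (25–40 hr) matches the wave phase and is configurable.

Problem sizes used by the analyses and acceptance computations — 0.01 hr
grids over 12–48 hr, 20-cell FRAP ensembles, 27-point inversion grids,
350-cell colonies at 256×256 px over 40 frames — were chosen as the
smallest sizes at which the estimators' sampling error is clearly below
the tolerances asserted; all are configurable upward.

## Known limitations

- The feedback model's absolute timescales are compressed (see
  Calibration); comparisons against experimental time axes require a
  rescaling that the package deliberately does not hard-code.
- The FRAP inversion assumes frozen sequestration exchange and a fixed
  import-rate convention; `k_out` values are meaningful only relative to
  `k_in = 0.04/min`.
- Colony dynamics are programmed, not emergent; onset detection inherits
  the frame spacing of the kymograph (±0.5 hr at the default 0.5 hr grid).
- The dose–response of the feedback model saturates more slowly than the
  measured one (see the `K_L` trade-off above).
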