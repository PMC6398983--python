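# smaddyn

Quantitative machinery for studying how the two SMAD branches of TGF-β
superfamily signaling read ligand *dynamics* in human embryonic stem cells:
the BMP4→SMAD1/5/8 branch responds to ligand **concentration** (sustained
signaling, dose-dependent duration via ligand depletion), while the
Activin/Nodal→SMAD2/3 branch responds to the **rate of concentration
increase** (strongly adaptive signaling driven by negative feedback).  The
package is aimed at quantitative/systems biologists who want to simulate
these behaviors under arbitrary ligand schedules, analyze live-cell
nuclear:cytoplasmic reporter data and FRAP recordings, and quantify
self-organized signaling waves in micropatterned colonies — with synthetic
generators standing in for microscopy data so every analysis has known
ground truth.

## What is inside

- **`smaddyn.schedules`** — piecewise ligand schedules: steps, staircase
  ramps (hourly media changes), pulse trains (the 6/10/8 hr, 5 hr-gap
  protocol).
- **`smaddyn.models`** — ODE models of the pathway response `S(t)` (a
  nuclear:cytoplasmic ratio proxy):
  - negative feedback (adaptive, Activin/Nodal-like):
    `dS/dt = α·O(L)/(1 + I/K_I) − γ(S − S0)`,
    `dI/dt = β(S − S0) − δI`, with receptor occupancy `O(L) = L/(L+K_L)`;
  - receptor depletion (the rejected alternative):
    `dR/dt = s − d_i R − k_b L R`, `dR*/dt = k_b L R − d_a R*`, `S ∝ R*`,
    whose adapted plateau is the degradation-rate ratio `d_i/d_a` and whose
    recovery is `d_a/d_i` times slower than adaptation;
  - ligand depletion (sustained, BMP-like): switch-like occupancy with
    `dL/dt = −uL` between media changes;
  - target-gene kinetics (adaptive vs sustained transcription classes) and
    qPCR ΔCt normalization (log₂, reference gene).
- **`smaddyn.frap`** — bleach-recovery simulation and analysis for a
  shuttling protein with sequestered nuclear/cytoplasmic sub-populations:
  exponential fits (amplitude `A`, rate `k = k_in + k_out`), the `R′ < R`
  sequestration diagnostic, and closed-form inversion to
  `(f_ns, f_cs, k_out)` with delta-method error propagation.
- **`smaddyn.imagequant`** — background-subtracted per-cell nuc:cyt ratios
  from labeled images, radial profiles, kymographs, the field's channel
  normalization conventions, half-maximum front tracking and expression
  domains.
- **`smaddyn.synth`** — generators with ground-truth sidecars: trajectory
  ensembles, rendered cell fields (disk nuclei + ring cytoplasm, shot/read
  noise), FRAP ensembles, and programmed colony dynamics (edge restriction
  by ~12 hr, inward wave from 25 hr at 10 μm/hr).
- **`smaddyn.pipeline`** — end-to-end experiment drivers (step-vs-ramp,
  dose response, pulse train, FRAP conditions, colony wave) with
  deterministic CSV/JSON reports.

The `analysis/` directory holds numbered narrative drivers
(`01_calibrate_models.py` … `06_colony_wave.py`) that run these experiments
and write their tables under `results/`.

## Worked example

Simulate a saturating Activin-like step and quantify adaptation:

```python
import numpy as np
from smaddyn import (default_feedback_params, simulate_feedback,
                     adaptation_metrics, make_step)

params = default_feedback_params("SMAD4")
t = np.arange(0.0, 12.0, 0.01)
traj = simulate_feedback(params, make_step(50.0, 0.0, 12.0), t)
m = adaptation_metrics(traj)
print(f"peak excess {m.peak:.3f} at {m.peak_time:.2f} hr, "
      f"plateau at {100 * m.baseline_fraction:.1f}% of peak")
```

prints

```
peak excess 1.002 at 0.05 hr, plateau at 20.0% of peak
```

— the nuc:cyt ratio roughly doubles, then relaxes to a plateau retaining
20% of the peak excess, maintained by continued ligand exposure.  Running
`python analysis/03_step_vs_ramp.py` contrasts the two pathways:

```
50 ng/ml delivered as a step vs a 10-step ramp over 10 hr:
  adaptive (Activin-like): ramp peak is 40% of the step peak -> the pathway reads rate of increase
  sustained (BMP-like):   late-time ramp/step signal ratio 1.000 -> the pathway reads concentration
```

and `python analysis/06_colony_wave.py` runs the colony closure, recovering
the programmed edge restriction (~12 hr), wave onset (25 hr) and wavefront
velocity (10 μm/hr — about one cell diameter per hour) from the kymograph,
both directly and through full image rendering + segmentation.

## Documentation

`docs/methods.md` describes the models, their assumptions, the calibration
choices, what the synthetic generators do and do not emulate, and known
limitations.
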