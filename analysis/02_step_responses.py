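"""Step responses across doses: adaptive SMAD4 vs the sustained BMP-like model.

Simulates saturating and sub-saturating ligand steps with the shipped
calibrations, summarizes peak / plateau / timescale per dose, and shows the
two signatures the pathways differ by: a dose-independent adaptation
timescale with dose-dependent peak and plateau (Activin-like), and a
dose-dependent signaling *duration* under ligand depletion (BMP-like).
"""

import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from smaddyn.models import (adaptation_metrics, default_depletion_params,  # noqa: E402
                            default_feedback_params, simulate_feedback,
                            simulate_ligand_depletion)
from smaddyn.pipeline import ExperimentSpec, run_dose_response  # noqa: E402
from smaddyn.schedules import make_step  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "step_responses"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    report = run_dose_response(ExperimentSpec("dose_response", seed=0), OUT)
    print("Activin-like (negative feedback) dose series:")
    for row in report["per_dose"]:
        print(f"  {row['dose_ng_ml']:>5.1f} ng/ml: peak excess "
              f"{row['peak_excess']:.3f}, plateau {row['baseline_fraction']:.2f} "
              f"of peak, 1/e timescale {row['adaptation_timescale_hr']:.3f} hr "
              f"({row['dynamics_class']})")
    print(f"  timescale CV across doses: {report['timescale_cv']:.3f} "
          "(dose sets how high, not how long)")

    # BMP-like: duration of half-maximal signaling grows with dose
    dp = default_depletion_params()
    t = np.arange(0.0, 48.0 + 1e-9, 0.01)
    rows = []
    for L0 in (5.0, 10.0, 25.0, 50.0):
        traj = simulate_ligand_depletion(dp, L0=L0, t_grid=t)
        x = traj.S - dp.S0
        above = np.nonzero(x >= 0.5 * x.max())[0]
        rows.append({"dose_ng_ml": L0,
                     "half_max_duration_hr": float(t[above[-1]] - t[above[0]])})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "bmp_duration_vs_dose.csv", index=False)
    print("\nBMP-like (ligand depletion): signaling duration vs dose")
    for _, r in df.iterrows():
        print(f"  {r['dose_ng_ml']:>5.1f} ng/ml: half-maximal signaling for "
              f"{r['half_max_duration_hr']:.1f} hr")

    # a reference saturating-step trajectory for the worked example
    params = default_feedback_params("SMAD4")
    t12 = np.arange(0.0, 12.0 + 1e-9, 0.01)
    traj = simulate_feedback(params, make_step(50.0, 0.0, 12.0), t12)
    m = adaptation_metrics(traj)
    pd.DataFrame({"t_hr": traj.t, "nc_ratio": traj.S}).to_csv(
        OUT / "smad4_step50_trajectory.csv", index=False)
    print(f"\nSaturating 50 ng/ml step: peak excess {m.peak:.3f} at "
          f"{m.peak_time:.2f} hr, plateau at {100 * m.baseline_fraction:.1f}% "
          "of peak.")


if __name__ == "__main__":
    main()
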