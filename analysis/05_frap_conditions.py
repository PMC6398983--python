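"""FRAP before treatment, at the response peak, and after adaptation.

Ensembles of bleach-recovery traces are generated from the shuttling model
with programmed condition shifts, fit cell by cell, and inverted for
sequestration fractions and export rates.  The signatures: the recovery
rate drops at the peak and is *not* restored after adaptation (the adapted
state is kinetically distinct from the pre-stimulus state), while
adaptation shows up as reduced nuclear and increased cytoplasmic
sequestration.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from smaddyn.pipeline import ExperimentSpec, run_frap_conditions  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "frap_conditions"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    r = run_frap_conditions(ExperimentSpec("frap_conditions", seed=1), OUT)
    print(f"{'condition':<10} {'k (1/min)':>10} {'f_ns':>14} {'f_cs':>14} "
          f"{'k_out (1/min)':>16}")
    for row in r["per_condition"]:
        print(f"{row['condition']:<10} "
              f"{row['mean_recovery_rate_per_min']:>10.4f} "
              f"{row['f_ns_hat']:>7.3f}±{row['se_f_ns']:.3f} "
              f"{row['f_cs_hat']:>7.3f}±{row['se_f_cs']:.3f} "
              f"{row['k_out_hat']:>9.4f}±{row['se_k_out']:.4f}")
    print(f"recovery rate lower at peak than untreated: "
          f"{r['rate_lower_at_peak']}")
    print(f"rate NOT restored during adaptation:        "
          f"{r['rate_not_restored']}")
    print(f"adaptation = lower nuclear sequestration:   "
          f"{r['adapted_lower_nuclear_seq']}")
    print(f"adaptation = higher cytoplasmic sequestration: "
          f"{r['adapted_higher_cyto_seq']}")


if __name__ == "__main__":
    main()
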