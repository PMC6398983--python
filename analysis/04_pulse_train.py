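"""Pulsed vs sustained ligand: re-triggering and target-gene output.

Three 30 ng/ml pulses (6/10/8 hr) separated by 5 hr relaxation gaps are
compared with sustained ligand and with no ligand (dummy media changes).
Each pulse re-triggers a near-full response, and the adaptive target gene
accumulates more output under pulses despite lower integrated exposure.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from smaddyn.pipeline import ExperimentSpec, run_pulse_train  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "pulse_train"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    r = run_pulse_train(ExperimentSpec("pulse_train", seed=0), OUT)
    print("Pulse protocol (6/10/8 hr pulses, 5 hr gaps, 30 ng/ml):")
    for i, (pk, ratio) in enumerate(zip(r["pulse_peaks"],
                                        r["retrigger_ratios"]), 1):
        print(f"  pulse {i}: peak excess {pk:.3f} "
              f"({100 * ratio:.0f}% of first pulse)")
    lig = r["integrated_ligand"]
    gene = r["integrated_gene_output"]
    print(f"  integrated ligand exposure: pulses {lig['pulses']:.0f} vs "
          f"sustained {lig['sustained']:.0f} ng/ml*hr")
    print(f"  integrated adaptive-gene output: pulses {gene['pulses']:.2f} vs "
          f"sustained {gene['sustained']:.2f} vs none {gene['none']:.2f}")
    print("  -> repeated rapid increases, not total exposure, drive the "
          "adaptive targets")


if __name__ == "__main__":
    main()
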