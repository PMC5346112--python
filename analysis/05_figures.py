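"""Box-plot overlays: collective distributions against the all-participant box.

Renders, for the last simulated survey, the concentrated and the diluted
birch-pollen sample — the constellation where the simulated manufacturer
bias is most visible.  Figures are written to scratch/figures/ (PNG + SVG).
"""

from pathlib import Path

from ringtrial.io import read_device_profiles, read_results
from ringtrial.pipeline import run_evaluation
from ringtrial.plotting import render_collective_boxes

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
FIG = ROOT / "scratch" / "figures"


def main() -> None:
    results, _ = read_results(SIM / "results.csv")
    profiles = read_device_profiles(SIM / "devices.csv")
    run = run_evaluation(results, profiles)

    last_survey = sorted(results["survey_id"].unique())[-1]
    sel = run.included[run.included["survey_id"] == last_survey]
    FIG.mkdir(parents=True, exist_ok=True)
    for sample_id, label in [("S1", "concentrated"), ("S4", "diluted")]:
        for ext in ("png", "svg"):
            render_collective_boxes(
                sel,
                analyte="birch_pollen",
                sample_id=sample_id,
                out=FIG / f"birch_pollen_{label}.{ext}",
                title=f"{last_survey}: birch pollen, {label} sample",
            )
        print(f"wrote birch_pollen_{label}.png/.svg for survey {last_survey}")
    print(f"figures in {FIG}")


if __name__ == "__main__":
    main()
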