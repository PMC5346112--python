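"""Score the simulated study: outlier exclusion, collectives, pass/fail.

Reads the raw tables from step 01, runs the full consensus-median scoring
pipeline on both scales and writes per-survey pass rates, the certificate
summary and the exclusion log under results/.
"""

from pathlib import Path

import pandas as pd

from ringtrial.evaluation import pass_rate
from ringtrial.io import read_device_profiles, read_results
from ringtrial.pipeline import run_evaluation

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results"


def main() -> None:
    results, errors = read_results(SIM / "results.csv")
    assert errors.empty, "simulated data must satisfy the IO contract"
    profiles = read_device_profiles(SIM / "devices.csv")
    run = run_evaluation(results, profiles)

    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for (survey_id, scale), sub in run.outcomes.groupby(["survey_id", "scale"]):
        rows.append({
            "survey_id": survey_id,
            "scale": scale,
            "n_evaluable": int(sub["evaluable"].sum()),
            "pass_rate_pct": round(pass_rate(sub), 2),
        })
    pass_rates = pd.DataFrame(rows)
    pass_rates.to_csv(OUT / "pass_rates.csv", index=False)

    cert_summary = (
        run.certificates.groupby(["survey_id", "overall"]).size()
        .unstack(fill_value=0).reset_index()
    )
    cert_summary.to_csv(OUT / "certificates_summary.csv", index=False)
    run.excluded.to_csv(OUT / "exclusions.csv", index=False)
    # full outcomes are large; keep them as scratch for later inspection
    run.outcomes.to_csv(SIM / "outcomes.csv", index=False)
    run.included.to_csv(SIM / "included.csv", index=False)

    conc = pass_rates[pass_rates["scale"] == "kU/L"]["pass_rate_pct"]
    cls = pass_rates[pass_rates["scale"] == "class"]["pass_rate_pct"]
    print(f"evaluated {len(results)} results; excluded {len(run.excluded)} outliers")
    print(f"  concentration pass rate across surveys: "
          f"{conc.min():.1f}-{conc.max():.1f} % (median {conc.median():.1f} %)")
    print(f"  class pass rate across surveys:         "
          f"{cls.min():.1f}-{cls.max():.1f} % (median {cls.median():.1f} %)")
    print(f"wrote pass_rates.csv, certificates_summary.csv, exclusions.csv to {OUT}")


if __name__ == "__main__":
    main()
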