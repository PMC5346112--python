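"""Simulate the six-year ring-trial study the rest of the analysis evaluates.

Seventeen surveys, three allergen sources (bee venom, wasp venom, birch
pollen), five-sample panels with paired dilutions, six manufacturer
collectives (four major, two below the pooling threshold), 160 labs per
survey, 15-25 % lab noise, a 100 kU/L saturation ceiling and 1 % injected
gross transfer errors.  Raw tables go to scratch/sim/ (they are inputs for
the later steps, not results).
"""

from pathlib import Path

from ringtrial.io import write_device_profiles, write_results
from ringtrial.simulate import OutlierSpec, default_config, device_profiles, simulate_study

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    config = default_config(SEED, outliers=OutlierSpec(rate=0.01))
    results, ledger = simulate_study(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_results(results, OUT / "results.csv")
    write_device_profiles(device_profiles(config), OUT / "devices.csv")
    ledger.to_csv(OUT / "ground_truth.csv", index=False)
    (OUT / "survey_dates.csv").write_text(
        "survey_id,date\n"
        + "".join(f"{p.survey_id},{p.date}\n" for p in config.panels),
        encoding="utf-8",
    )

    n_censored = int(ledger["censored"].sum())
    n_outliers = int(ledger["injected_outlier"].sum())
    print(f"simulated {len(results)} results across {len(config.panels)} surveys")
    print(f"  censored at the device top: {n_censored} "
          f"({100 * n_censored / len(results):.1f} %)")
    print(f"  injected gross errors:      {n_outliers} "
          f"({100 * n_outliers / len(results):.2f} %)")
    print(f"wrote raw tables to {OUT}")


if __name__ == "__main__":
    main()
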