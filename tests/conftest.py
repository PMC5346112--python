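import numpy as np
import pandas as pd
import pytest

from ringtrial.panel_model import DeviceProfile, RESULT_COLUMNS


def make_results(rows):
    """Build a tidy result table from (participant, manufacturer, conc, class)
    tuples or full dicts; missing keys fall back to a single-survey default."""
    records = []
    for i, row in enumerate(rows):
        if isinstance(row, dict):
            rec = {
                "survey_id": "RRT-1",
                "participant_id": f"P{i + 1:03d}",
                "manufacturer_code": "F1",
                "analyte": "bee_venom",
                "sample_id": "S1",
                "concentration_ku_l": np.nan,
                "allergen_class": np.nan,
            }
            rec.update(row)
        else:
            pid, code, conc, cls = row
            rec = {
                "survey_id": "RRT-1",
                "participant_id": pid,
                "manufacturer_code": code,
                "analyte": "bee_venom",
                "sample_id": "S1",
                "concentration_ku_l": conc,
                "allergen_class": cls,
            }
        records.append(rec)
    df = pd.DataFrame(records, columns=RESULT_COLUMNS)
    df["concentration_ku_l"] = df["concentration_ku_l"].astype(float)
    df["allergen_class"] = df["allergen_class"].astype(float)
    return df


@pytest.fixture
def results_factory():
    return make_results


@pytest.fixture
def devices():
    """Profiles for the codes used throughout the unit tests."""
    codes = ["F1", "F2", "F3", "F7", "F48", "F64", "F138", "F201", "F202"]
    return {c: DeviceProfile(c, top_calibration=100.0, top_class=6.0) for c in codes}
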