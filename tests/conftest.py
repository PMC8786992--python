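import numpy as np
import pandas as pd
import pytest

from radrepro import (
    DEFAULT_DESIGN,
    FeatureTable,
    ReconstructionDesign,
)


@pytest.fixture
def two_setting_design() -> ReconstructionDesign:
    return ReconstructionDesign(
        setting_labels=("FBP", "IR60"),
        reference_label="FBP",
        blending_percent={"FBP": 0, "IR60": 60},
    )


def make_table(values: dict, metadata: pd.DataFrame | None = None,
               design: ReconstructionDesign = DEFAULT_DESIGN) -> FeatureTable:
    """Build a FeatureTable from {(patient, setting, feature): value}."""
    rows = [
        {"patient_id": p, "setting": s, "feature": f, "value": v}
        for (p, s, f), v in values.items()
    ]
    vals = pd.DataFrame(rows)
    if metadata is None:
        pids = sorted(vals["patient_id"].unique())
        metadata = pd.DataFrame(
            {
                "patient_id": pids,
                "scanner": ["scannerA" if i % 2 == 0 else "scannerB" for i in range(len(pids))],
                "tube_voltage": ["100kVp" if i < len(pids) / 2 else "120kVp" for i in range(len(pids))],
                "tumour_volume_cm3": np.linspace(10.0, 60.0, len(pids)),
            }
        ).set_index("patient_id")
    return FeatureTable(design=design, values=vals, metadata=metadata)


@pytest.fixture
def small_complete_table() -> FeatureTable:
    """4 patients x 6 settings x 2 features, fully observed."""
    rng = np.random.default_rng(42)
    values = {}
    for i, p in enumerate(["P1", "P2", "P3", "P4"]):
        for j, s in enumerate(DEFAULT_DESIGN.setting_labels):
            values[(p, s, "original_firstorder_Mean")] = float(i + 0.1 * j + rng.normal(0, 0.01))
            values[(p, s, "original_glcm_Contrast")] = float(2 * i + rng.normal(0, 0.01))
    return make_table(values)
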