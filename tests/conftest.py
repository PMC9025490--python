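import numpy as np
import pandas as pd
import pytest

from dimsmark.spectra_io import CohortManifest, CompoundRecord
from dimsmark.synthetic_data import PE_MARKER_PANEL

#: Printed (detected_count, group_size, frequency) worked examples used by
#: several suites: 2-dp rounding of count/size reproduces the reported panel.
PRINTED_FREQUENCY_PAIRS = [
    (1, 25, 0.04),
    (2, 25, 0.08),
    (3, 25, 0.12),
    (2, 3, 0.67),
    (3, 3, 1.00),
    (1, 20, 0.05),
    (1, 31, 0.03),
    (2, 31, 0.06),
    (3, 31, 0.10),
]

STUDY_GROUP_SIZES = {"group1": 25, "group2": 3, "group3": 20, "group4": 31}


@pytest.fixture
def panel_library() -> list[CompoundRecord]:
    """The nine-compound marker panel as a compound library."""
    return [entry.compound for entry in PE_MARKER_PANEL]


@pytest.fixture
def panel_frequency_table() -> pd.DataFrame:
    """Long-form frequency table of the marker panel at its design prevalences."""
    rows = []
    for entry in PE_MARKER_PANEL:
        for group, size in STUDY_GROUP_SIZES.items():
            p = entry.group_probs.get(group, 0.0)
            rows.append(
                {
                    "compound_id": entry.compound.compound_id,
                    "group": group,
                    "detected_count": round(p * size),
                    "group_size": size,
                    "frequency": p,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def study_manifest() -> CohortManifest:
    samples = {}
    for group, n in STUDY_GROUP_SIZES.items():
        for i in range(1, n + 1):
            sid = f"{group}_s{i:02d}"
            samples[sid] = (group, [f"{sid}_r1.csv", f"{sid}_r2.csv"])
    return CohortManifest(samples)
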