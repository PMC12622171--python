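import numpy as np
import pandas as pd
import pytest

import mdmscreen as m
from mdmscreen.panels import SEMIQUANT_EXCEEDANCE_TARGETS


@pytest.fixture(scope="session")
def semiquant_panel():
    return m.builtin_semiquant_panel()


@pytest.fixture(scope="session")
def calibrated_config(semiquant_panel):
    """Study-condition generator config: 19-metabolite panel, elevation
    probabilities calibrated to the published exceedance fractions,
    50 affected vs 47 reference participants. Built once per session."""
    return m.calibrate_to_table(
        SEMIQUANT_EXCEEDANCE_TARGETS, n_td=47, n_asd=50, panel=semiquant_panel
    )


@pytest.fixture()
def small_panel():
    return m.MetabolitePanel(
        [
            m.PanelEntry("met_a", "Metabolite A", "phenylalanine", "high", lod=0.4),
            m.PanelEntry("met_b", "Metabolite B", "tryptophan", "high"),
            m.PanelEntry("met_c", "Metabolite C", "yeast_other", "low", lod=0.1),
        ]
    )


@pytest.fixture()
def small_cohort(small_panel):
    """Hand-built 5-participant cohort with one censored and one missing cell."""
    index = pd.Index(["P1", "P2", "P3", "P4", "P5"], name="participant_id")
    meta = pd.DataFrame(
        {
            "group": ["TD", "TD", "TD", "ASD", "ASD"],
            "age_years": [4.0, 6.5, 8.0, 5.0, np.nan],
            "sex": ["F", "M", "F", "M", "M"],
            "creatinine": [5.0, 2.0, 4.0, 8.0, 2.5],
        },
        index=index,
    )
    values = pd.DataFrame(
        {
            "met_a": [10.0, 4.0, 8.0, 80.0, np.nan],
            "met_b": [1.0, 2.0, 1.5, 3.0, 40.0],
            "met_c": [2.0, 1.0, 1.6, 0.2, np.nan],
        },
        index=index,
    )
    lod_mask = pd.DataFrame(False, index=index, columns=values.columns)
    lod_mask.loc["P5", "met_a"] = True  # censored
    # met_c for P5 is plain missing (no flag)
    return m.Cohort(meta, values, lod_mask, small_panel)


def random_normalized(rng, n, panel):
    """NormalizedMatrix of i.i.d. positive values for oracle fixtures."""
    ids = panel.ids()
    index = pd.Index([f"S{i}" for i in range(n)], name="participant_id")
    values = pd.DataFrame(
        rng.lognormal(0.0, 1.0, size=(n, len(ids))), index=index, columns=ids
    )
    mask = pd.DataFrame(False, index=index, columns=ids)
    return m.NormalizedMatrix(values, mask, "zero", panel.content_hash())
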