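import numpy as np
import pandas as pd
import pytest

from fluorosep import ConfidenceEllipse, SpectraMatrix, fit_pca
from fluorosep.synthetic_data import SyntheticConfig, generate_spectra


def circle(cx: float, cy: float, r: float, sample_id: str = "") -> ConfidenceEllipse:
    """Ellipse object representing a circle of radius r."""
    return ConfidenceEllipse([cx, cy], np.eye(2), r * r, sample_id)


def tiny_matrix(values, wavelengths, sample_ids, blanks=None, condition="c1"):
    """Assemble a SpectraMatrix from bare arrays for unit tests."""
    values = np.asarray(values, float)
    n = values.shape[0]
    blanks = [False] * n if blanks is None else blanks
    reps = {}
    rep_idx = []
    for sid in sample_ids:
        reps[sid] = reps.get(sid, 0) + 1
        rep_idx.append(reps[sid])
    meta = pd.DataFrame({
        "well_id": [f"W{i}" for i in range(n)],
        "sample_id": sample_ids,
        "replicate": rep_idx,
        "is_blank": blanks,
        "condition": condition,
    })
    return SpectraMatrix(values, np.asarray(wavelengths, float), meta)


@pytest.fixture(scope="session")
def default_plate():
    """One synthetic plate with the study design (36 x 5 + 6 blanks, 301 wl)."""
    return generate_spectra(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_cloud(default_plate):
    from fluorosep import quench_normalize, select_window

    return fit_pca(select_window(quench_normalize(default_plate), 430, 550), k=2)
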