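import numpy as np
import pandas as pd
import pytest

from tilquant.model import PANEL, RegionGeometry, TissueSample


def make_sample(
    x,
    y,
    region=None,
    window=None,
    patient_id="P001",
    timepoint="baseline",
    **marker_columns,
):
    """Build a TissueSample from coordinate arrays and marker columns.

    Markers absent from ``marker_columns`` default to all-negative; region
    defaults to stroma; the window defaults to the tight bounding box.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    data = {
        "cell_id": [f"c{i:04d}" for i in range(n)],
        "x_um": x,
        "y_um": y,
    }
    for m in PANEL:
        col = np.asarray(marker_columns.get(m, np.zeros(n)), dtype=np.int8)
        data[m] = col
    for key, val in marker_columns.items():
        if key.endswith("_intensity"):
            data[key] = np.asarray(val, dtype=float)
    data["region"] = region if region is not None else ["stroma"] * n
    if window is None:
        upper = max(float(x.max(initial=0.0)), float(y.max(initial=0.0)), 1.0)
        window = (0.0, 0.0, upper + 1.0, upper + 1.0)
    return TissueSample(
        patient_id=patient_id,
        timepoint=timepoint,
        cells=pd.DataFrame(data),
        geometry=RegionGeometry(window=window),
    )


def random_sample(rng, n, size=1000.0, marker_p=0.3, regions=("tumor", "stroma")):
    """Random cell table with independent marker flags (no spatial structure)."""
    x = rng.uniform(0, size, n)
    y = rng.uniform(0, size, n)
    markers = {m: (rng.random(n) < marker_p).astype(np.int8) for m in PANEL}
    region = rng.choice(regions, size=n)
    return make_sample(x, y, region=list(region), window=(0, 0, size, size), **markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
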