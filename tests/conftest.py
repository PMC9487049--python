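import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import Point

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from immunotime import (
    CellRecord,
    FieldGeometry,
    LesionSample,
    MarkerPanel,
    default_rules,
)

PANEL9 = MarkerPanel.nine_color()


def make_cell(cell_id, x, y, field_id="F1", compartment="stroma", **positive_markers):
    calls = {m: False for m in PANEL9.markers}
    for m, v in positive_markers.items():
        calls[m.replace("_", "-")] = bool(v)
    return CellRecord(cell_id, field_id, x, y, calls, compartment)


def make_lesion(cells, width=650.0, height=500.0, nests=None, sample_id="S1",
                field_ids=("F1",), lesion_type="primary"):
    """Single- or multi-field lesion with disc nests given as (cx, cy, r)."""
    nest_polys = [Point(cx, cy).buffer(r, quad_segs=64) for cx, cy, r in (nests or [])]
    fields = [FieldGeometry(fid, width, height, list(nest_polys)) for fid in field_ids]
    return LesionSample(sample_id, "P1", lesion_type, fields, cells)


@pytest.fixture
def panel9():
    return PANEL9


@pytest.fixture
def rules9():
    return default_rules(PANEL9)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_lesion(rng, n_cells=200, width=650.0, height=500.0, field_ids=("F1",),
                  marker_probs=None):
    """Random cells with independent marker calls, for oracle comparisons."""
    marker_probs = marker_probs or {"CD8": 0.3, "CK": 0.4, "CD68": 0.2, "CD163": 0.15,
                                    "FoxP3": 0.1, "CD103": 0.15, "PD-1": 0.15,
                                    "PD-L1": 0.2}
    cells = []
    for i in range(n_cells):
        fid = field_ids[rng.integers(len(field_ids))]
        calls = {m: bool(rng.random() < marker_probs.get(m, 0.0)) for m in PANEL9.markers}
        cells.append(
            CellRecord(f"c{i}", fid, float(rng.uniform(0, width)),
                       float(rng.uniform(0, height)), calls,
                       "tumor" if rng.random() < 0.4 else "stroma")
        )
    return make_lesion(cells, width, height, nests=[(200, 200, 120)],
                       field_ids=field_ids)
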