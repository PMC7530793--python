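"""Shared session-scoped fixtures: scenes are generated once and reused."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mplexpheno import fixtures, panels, phenotyping, segmentation


@pytest.fixture(scope="session")
def sparse_mp1():
    return fixtures.make_fixture("sparse-mp1")


@pytest.fixture(scope="session")
def sparse_mp1_truth(sparse_mp1):
    return sparse_mp1.truth()


@pytest.fixture(scope="session")
def sparse_mp1_unmixed(sparse_mp1):
    return sparse_mp1.unmixed()


@pytest.fixture(scope="session")
def sparse_mp1_cells(sparse_mp1_unmixed):
    return segmentation.segment_and_measure(sparse_mp1_unmixed, panels.MP1)


@pytest.fixture(scope="session")
def sparse_mp1_thresholds(sparse_mp1_truth, sparse_mp1_cells):
    """Quantile-matched thresholds against the ground-truth positive fractions."""
    th = {}
    for m in panels.panel_markers(panels.MP1):
        if m == "DAPI":
            continue
        ref = float((sparse_mp1_truth.abundance(m) > 0).mean())
        th[m] = phenotyping.derive_threshold(
            sparse_mp1_cells, m, "quantile-match", reference_positive_fraction=ref
        )
    return th


@pytest.fixture(scope="session")
def hotspot_mp1():
    return fixtures.make_fixture("hotspot-mp1")


@pytest.fixture(scope="session")
def hotspot_mp1_cells(hotspot_mp1):
    um = hotspot_mp1.unmixed()
    return segmentation.segment_and_measure(um, panels.MP1)


@pytest.fixture(scope="session")
def hotspot_mp1_contexts(hotspot_mp1, hotspot_mp1_cells):
    centres = hotspot_mp1.truth().hotspot_centres
    ctx = [
        "hotspot"
        if any(np.hypot(r.y - cy, r.x - cx) <= rad for cy, cx, rad in centres)
        else "sparse"
        for r in hotspot_mp1_cells.itertuples()
    ]
    return pd.Series(ctx, index=hotspot_mp1_cells.index)


@pytest.fixture(scope="session")
def mp2_cells():
    fx = fixtures.make_fixture("mp2")
    return segmentation.segment_and_measure(fx.unmixed(), panels.MP2)
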