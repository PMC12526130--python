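"""Shared fixtures: small synthetic tissues and hand-built cell maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gbstruct as gb


def make_cell_map(xy, types, sample_id="T1", label_set=None):
    """CellMap from coordinate array and type list, ids c0, c1, ..."""
    xy = np.asarray(xy, dtype=float)
    if label_set is None:
        label_set = tuple(sorted(set(types)))
    return gb.CellMap(
        pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(xy))],
                "x": xy[:, 0],
                "y": xy[:, 1],
                "cell_type": list(types),
                "sample_id": sample_id,
            }
        ),
        label_set=label_set,
    )


@pytest.fixture(scope="session")
def template():
    return gb.default_template()


@pytest.fixture(scope="session")
def small_sample(template):
    """One ordered (λ=0) synthetic section, small enough for fast tests."""
    cfg = gb.SynthConfig(n_cells=1500, canvas_um=400, n_vessels=1, seed=0)
    return gb.generate_sample(template, cfg, seed=11, sample_id="S01")


@pytest.fixture(scope="session")
def random_cells():
    """200 uniform random cells with two type labels, for graph oracles."""
    rng = np.random.default_rng(42)
    xy = rng.uniform(0, 300, size=(200, 2))
    types = rng.choice(["A", "B"], size=200)
    return make_cell_map(xy, types)


@pytest.fixture(scope="session")
def small_cohort(template):
    """Four samples spanning the disorder schedule, with expression and
    survival; sized for speed, used by tests that need only ordering
    behavior (not absolute recovery quality)."""
    cfg = gb.SynthConfig(n_cells=1200, canvas_um=400, n_vessels=1, seed=0)
    return gb.generate_cohort(
        template, cfg, n_samples=4, lambdas=[0.0, 0.33, 0.66, 1.0], seed=5
    )
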