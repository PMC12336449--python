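"""Shared fixtures: simulated panels reused across test modules."""

from __future__ import annotations

import pytest

from foxmdyn import pipeline, synthetic


@pytest.fixture(scope="session")
def panel():
    """Default screening-dose panel at analysis scale (two batches)."""
    cfg = synthetic.default_panel_config(seed=1, n_cells=pipeline.PANEL_N_CELLS)
    return synthetic.simulate_panel(cfg)


@pytest.fixture(scope="session")
def panel_analysis(panel):
    """Condition-level fPCA + clustering of the default panel."""
    return pipeline.analyze_panel(panel)


@pytest.fixture(scope="session")
def small_panel():
    """Cheaper panel for featurization / fate tests."""
    cfg = synthetic.default_panel_config(seed=3, n_cells=40)
    return synthetic.simulate_panel(cfg)
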