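import numpy as np
import pytest

from he2plex.synthetic import (DEFAULT_MARKERS, TissueSimConfig,
                               simulate_paired_roi)

# 3-marker panel for fast tests: one tumour marker, one T-cell marker, one broad
SMALL_MARKERS = ["MelanA", "CD8a", "HLA-ABC"]
SMALL_EXPRESSION = np.array([
    [0.9, 0.0, 0.5],   # tumour
    [0.0, 0.9, 0.6],   # CD8 T
    [0.0, 0.0, 0.6],   # CD4 T
    [0.0, 0.0, 0.6],   # B
    [0.0, 0.0, 0.5],   # endothelial
    [0.0, 0.0, 0.4],   # other
])


def small_sim_config(seed=0, **overrides) -> TissueSimConfig:
    cfg = TissueSimConfig(canvas_size=64, n_cells=60,
                          marker_panel=list(SMALL_MARKERS),
                          expression=SMALL_EXPRESSION.copy(),
                          tumour_centre_margin_px=4, seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_scene():
    return simulate_paired_roi(small_sim_config())


@pytest.fixture(scope="session")
def small_rois():
    return [simulate_paired_roi(small_sim_config(seed=s))[0] for s in range(3)]


@pytest.fixture(scope="session")
def full_panel_scene():
    cfg = TissueSimConfig(canvas_size=96, n_cells=140, seed=1,
                          tumour_centre_margin_px=6)
    assert cfg.marker_panel == DEFAULT_MARKERS
    return simulate_paired_roi(cfg)
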