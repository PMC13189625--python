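import numpy as np
import pandas as pd
import pytest

from synprox import (CountSimConfig, ImageSimConfig, SegmentationConfig,
                     SpectralCountTable, simulate_count_table,
                     simulate_puncta_image)


@pytest.fixture
def toy_table() -> SpectralCountTable:
    """Six proteins spanning ratios ~0.5 to 25 (hand-checkable)."""
    counts = pd.DataFrame(
        {
            "bait_1": [9, 10, 2, 40, 5, 0],
            "bait_2": [9, 14, 2, 38, 5, 0],
            "ctrl_1": [3, 0, 5, 2, 5, 4],
            "ctrl_2": [3, 0, 3, 2, 5, 4],
        },
        index=pd.Index(["pA", "pB", "pC", "pD", "pE", "pF"], name="protein_id"),
    )
    conditions = {"bait_1": "bait", "bait_2": "bait",
                  "ctrl_1": "control", "ctrl_2": "control"}
    return SpectralCountTable(counts=counts, conditions=conditions)


@pytest.fixture(scope="session")
def default_count_sim():
    table, truth = simulate_count_table(CountSimConfig(seed=7))
    return table, truth


# small fast image-simulation settings shared by image-arm tests
SMALL_IMG = dict(width_px=256, height_px=256, ref_density_per_um2=0.2,
                 cand_density_per_um2=0.2)


@pytest.fixture(scope="session")
def small_image():
    cfg = ImageSimConfig(seed=11, coloc_fraction=0.5, **SMALL_IMG)
    stack, truth = simulate_puncta_image(cfg)
    return cfg, stack, truth


@pytest.fixture
def seg_config() -> SegmentationConfig:
    """Particle-analysis window used throughout the image-arm tests."""
    return SegmentationConfig(min_area_px=12)
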