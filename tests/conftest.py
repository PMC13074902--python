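"""Shared fixtures: small random VOIs and a tiny pipeline configuration."""

from __future__ import annotations

import numpy as np
import pytest

from tumorad import ImageVolume, VOIMask
from tumorad.io_formats import RunConfig


def random_fixture(rng: np.random.Generator, max_shape=(8, 8, 4), max_bins=8):
    """One small random image/mask pair plus a bin count, or None if the
    draw produced too few in-mask voxels to be interesting."""
    shape = tuple(int(rng.integers(3, m + 1)) for m in max_shape)
    n_bins = int(rng.integers(2, max_bins + 1))
    vals = rng.integers(0, 24, size=shape).astype(float)
    mask = rng.random(shape) < rng.uniform(0.4, 0.9)
    if mask.sum() < 5:
        return None
    spacing = tuple(float(s) for s in rng.uniform(0.2, 1.5, size=3))
    return ImageVolume(vals, spacing), VOIMask(mask, spacing), n_bins


@pytest.fixture
def strip_voi():
    """1D strip helper: build a 1xNx1 VOI from a list of intensities."""

    def make(values, spacing=(1.0, 1.0, 1.0)):
        arr = np.asarray(values, dtype=float).reshape(1, -1, 1)
        mask = np.ones_like(arr, dtype=bool)
        return ImageVolume(arr, spacing), VOIMask(mask, spacing)

    return make


@pytest.fixture
def tiny_config(tmp_path):
    """A scaled-down full-pipeline configuration that runs in seconds."""
    cfg = RunConfig()
    cfg.seed = 11
    cfg.output_dir = str(tmp_path / "out")
    cfg.cohort.group_labels = ("TREAT-A", "TREAT-C", "CONTROL")
    cfg.cohort.group_sizes = (4, 4, 3)
    cfg.cohort.group_dt_days = (4.5, 3.5, 4.5)
    cfg.cohort.contrasts = ("T2",)
    cfg.cohort.baseline_diameter_mean = 3.5
    cfg.cohort.baseline_diameter_sd = 0.3
    cfg.stats.n_perm = 300
    return cfg
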