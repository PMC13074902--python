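"""File formats and run configuration.

Volumes and masks travel as NIfTI (.nii / .nii.gz); tabular artifacts as
UTF-8 comma-separated files with a mandatory header row and empty cells for
missing values; configuration as flat YAML.  Every output table written by
the pipeline carries the configuration hash and root seed so a result file
is re-derivable from itself plus the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .volumes import GeometryError, ImageVolume, VOIMask

__all__ = [
    "RunConfig",
    "TextureConfig",
    "StatsConfig",
    "CohortConfig",
    "read_volume_pair",
    "write_volume",
    "write_mask",
    "load_config",
    "save_config",
    "validate_config",
    "config_hash",
    "ConfigError",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration content; message lists all problems."""


# ---------------------------------------------------------------------------
# NIfTI volumes


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: VOIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume_pair(image_path: str | Path, mask_path: str | Path) -> tuple[ImageVolume, VOIMask]:
    """Load an aligned NIfTI image/mask pair with strict validation.

    The grids and affines must match exactly; mask values must be (within
    1e-6 of) 0 or 1, anything else is rejected rather than thresholded.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    idata = np.asarray(img.dataobj, dtype=np.float64)
    mdata = np.asarray(msk.dataobj, dtype=np.float64)
    if idata.shape != mdata.shape:
        raise GeometryError(
            f"image shape {idata.shape} != mask shape {mdata.shape} "
            f"({image_path} vs {mask_path})"
        )
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise GeometryError(f"affine mismatch between {image_path} and {mask_path}")
    rounded = np.round(mdata)
    if not (np.all(np.abs(mdata - rounded) < 1e-6) and np.all(np.isin(rounded, (0.0, 1.0)))):
        bad = np.unique(mdata[np.abs(mdata - rounded) >= 1e-6])
        offending = bad if bad.size else np.setdiff1d(np.unique(rounded), (0.0, 1.0))
        raise ValueError(f"mask is not binary; offending values include {offending[:5]}")
    spacing = _spacing_from(img)
    return (
        ImageVolume(data=idata, spacing=spacing, affine=img.affine),
        VOIMask(data=rounded.astype(bool), spacing=spacing, affine=msk.affine),
    )


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class TextureConfig:
    n_bins: int = 32
    distance: int = 1
    connectivity: int = 26
    direction_mode: str = "merged"


@dataclass
class StatsConfig:
    n_perm: int = 10_000
    alpha: float = 0.05
    correction: str = "fdr"
    t_statistic: str = "pooled"


@dataclass
class CohortConfig:
    """Simulation design: labels, sizes, mean doubling times and effects."""

    group_labels: tuple[str, ...] = ("TREAT-A", "TREAT-B", "TREAT-C", "CONTROL")
    group_sizes: tuple[int, ...] = (29, 23, 23, 6)
    group_dt_days: tuple[float, ...] = (4.6, 4.8, 3.5, 4.5)
    effect_group: str | None = None
    effect_core_fraction_mult: float = 1.0
    effect_noise_sd_mult: float = 1.0
    effect_contrast_mult: float = 1.0
    timepoints: tuple[float, float] = (8.0, 26.0)
    contrasts: tuple[str, ...] = ("T1", "T2")
    baseline_diameter_mean: float = 6.0
    baseline_diameter_sd: float = 0.5
    sgr_sd: float = 1.5
    voxel_spacing: tuple[float, float, float] = (0.109, 0.25, 1.0)


@dataclass
class RunConfig:
    input_dir: str = "."
    output_dir: str = "out"
    seed: int = 0
    control_label: str = "CONTROL"
    texture: TextureConfig = field(default_factory=TextureConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)


_SECTION_TYPES = {"texture": TextureConfig, "stats": StatsConfig, "cohort": CohortConfig}


def _coerce(value, template):
    if isinstance(template, tuple) and not isinstance(value, tuple):
        return tuple(value)
    return value


def load_config(path: str | Path | None) -> RunConfig:
    """Load a flat YAML config; an empty / absent file yields full defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        return cfg
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    errors: list[str] = []
    for key, val in raw.items():
        if key in _SECTION_TYPES:
            section = getattr(cfg, key)
            known = {f.name for f in dataclasses.fields(section)}
            if not isinstance(val, dict):
                errors.append(f"{key}: must be a mapping")
                continue
            for k2, v2 in val.items():
                if k2 not in known:
                    errors.append(f"{key}.{k2}: unknown key")
                else:
                    setattr(section, k2, _coerce(v2, getattr(section, k2)))
        elif key in {f.name for f in dataclasses.fields(RunConfig)}:
            setattr(cfg, key, _coerce(val, getattr(cfg, key)))
        else:
            errors.append(f"{key}: unknown key")
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid config:\n  " + "\n  ".join(problems))
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Collect every out-of-range parameter; empty list means valid."""
    errors: list[str] = []
    t, s, c = cfg.texture, cfg.stats, cfg.cohort
    if t.n_bins < 2:
        errors.append(f"texture.n_bins: must be >= 2, got {t.n_bins}")
    if t.distance < 1:
        errors.append(f"texture.distance: must be >= 1, got {t.distance}")
    if t.connectivity not in (6, 18, 26):
        errors.append(f"texture.connectivity: must be 6, 18 or 26, got {t.connectivity}")
    if t.direction_mode not in ("merged", "average"):
        errors.append(f"texture.direction_mode: must be merged|average, got {t.direction_mode!r}")
    if s.n_perm < 100:
        errors.append(f"stats.n_perm: must be >= 100, got {s.n_perm}")
    if not (0 < s.alpha < 1):
        errors.append(f"stats.alpha: must be in (0, 1), got {s.alpha}")
    if s.correction not in ("fdr", "bonferroni"):
        errors.append(f"stats.correction: must be fdr|bonferroni, got {s.correction!r}")
    if s.t_statistic not in ("pooled", "welch"):
        errors.append(f"stats.t_statistic: must be pooled|welch, got {s.t_statistic!r}")
    if len(c.group_labels) != len(set(c.group_labels)):
        errors.append(f"cohort.group_labels: duplicates in {c.group_labels}")
    if not (len(c.group_labels) == len(c.group_sizes) == len(c.group_dt_days)):
        errors.append("cohort: group_labels, group_sizes and group_dt_days must have equal length")
    if any(n < 1 for n in c.group_sizes):
        errors.append(f"cohort.group_sizes: every group needs >= 1 subject, got {c.group_sizes}")
    if any(d <= 0 for d in c.group_dt_days):
        errors.append(f"cohort.group_dt_days: doubling times must be > 0, got {c.group_dt_days}")
    if not all(b > a for a, b in zip(c.timepoints, c.timepoints[1:])):
        errors.append(f"cohort.timepoints: must be strictly increasing, got {c.timepoints}")
    if cfg.control_label not in c.group_labels:
        errors.append(
            f"control_label: {cfg.control_label!r} not among groups {c.group_labels}"
        )
    return errors


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(x) for x in obj]
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration."""
    canon = yaml.safe_dump(_as_plain(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
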