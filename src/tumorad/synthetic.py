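"""Synthetic preclinical tumor-MRI cohorts with known ground truth.

Generates ellipsoidal tumor phantoms with the qualitative morphology of an
aggressive orthotopic mammary carcinoma: a hyper/hypo-intense necrotic core
(contrast-dependent), a peritumoral edema rim outlining the mass, a
lobulated margin, and additive Gaussian noise.  Cohorts pair a baseline and
an endpoint acquisition per subject and contrast, with exponential growth at
a known per-subject specific growth rate (SGR), longitudinal caliper tables
for two measurement modalities, and an explicit ground-truth manifest so
that downstream tests never re-derive truth from the pipeline under test.

Every output is a pure function of its parameter object including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

try:  # SciPy >= 1.15
    from scipy.special import sph_harm_y as _sph_harm_y

    def _sph_harm(m: int, ell: int, azimuth: np.ndarray, polar: np.ndarray) -> np.ndarray:
        return _sph_harm_y(ell, m, polar, azimuth)

except ImportError:  # pragma: no cover - older SciPy
    from scipy.special import sph_harm as _sph_harm_legacy

    def _sph_harm(m: int, ell: int, azimuth: np.ndarray, polar: np.ndarray) -> np.ndarray:
        return _sph_harm_legacy(m, ell, azimuth, polar)

from .volumes import ImageVolume, VOIMask

__all__ = [
    "IntensityLevels",
    "PhantomParams",
    "GroupSpec",
    "CohortSpec",
    "TextureEffect",
    "STRONG_EFFECT",
    "Cohort",
    "generate_phantom",
    "grow_phantom",
    "generate_cohort",
    "default_cohort_spec",
    "CONTRAST_INTENSITIES",
]


@dataclass(frozen=True)
class IntensityLevels:
    """Mean intensity per tissue compartment (arbitrary MR-like units)."""

    background: float = 20.0
    rim: float = 100.0
    core: float = 160.0
    edema: float = 130.0

    def __post_init__(self) -> None:
        if self.rim == self.core:
            raise ValueError("rim and core intensities must be distinct")


#: Default compartment intensities per contrast.  On T2-like images the
#: necrotic core and edema are hyperintense relative to viable rim tissue;
#: on T1-like images the core is hypointense.
CONTRAST_INTENSITIES: dict[str, IntensityLevels] = {
    "T1": IntensityLevels(background=20.0, rim=100.0, core=60.0, edema=80.0),
    "T2": IntensityLevels(background=20.0, rim=100.0, core=160.0, edema=130.0),
}


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of one phantom render.

    ``tumor_diameters`` are the AP/TS/CC extents in mm along the three grid
    axes.  ``core_fraction`` is the fraction of the (lobulated) tumor radius
    occupied by the necrotic core.  ``lobulation_amplitude`` perturbs the
    boundary radius by a low-order spherical-harmonic field; 0 gives an
    exact ellipsoid.  ``shape_seed`` controls the lobulation field (held
    fixed across timepoints of one subject so growth is shape-preserving);
    ``seed`` controls the noise field.
    """

    grid_shape: tuple[int, int, int] = (96, 48, 24)
    voxel_spacing: tuple[float, float, float] = (0.109, 0.25, 1.0)
    tumor_diameters: tuple[float, float, float] = (6.0, 6.0, 6.0)
    core_fraction: float = 0.3
    edema_thickness: float = 1.0
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    noise_sd: float = 5.0
    background_noise_sd: float | None = None  # defaults to noise_sd
    lobulation_amplitude: float = 0.08
    seed: int = 0
    shape_seed: int | None = None  # defaults to seed

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"spacings must be > 0, got {self.voxel_spacing}")
        if any(d <= 0 for d in self.tumor_diameters):
            raise ValueError(f"diameters must be > 0, got {self.tumor_diameters}")
        if not (0.0 <= self.core_fraction < 1.0):
            raise ValueError(f"core_fraction must be in [0, 1), got {self.core_fraction}")
        if self.edema_thickness < 0:
            raise ValueError("edema_thickness must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        axes = "AP (axis 0)", "TS (axis 1)", "CC (axis 2)"
        for name, n, sp, diam in zip(
            axes, self.grid_shape, self.voxel_spacing, self.tumor_diameters
        ):
            needed = diam * (1.0 + max(self.lobulation_amplitude, 0.0)) + 2 * self.edema_thickness
            if needed > n * sp:
                raise ValueError(
                    f"tumor too large for grid along {name}: needs {needed:.2f} mm, "
                    f"grid extent is {n * sp:.2f} mm"
                )


def _lobulation_field(theta: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Low-order real spherical-harmonic radial perturbation, max |f| = 1."""
    f = np.zeros_like(theta)
    for ell in (2, 3):
        for m in range(-ell, ell + 1):
            c = rng.normal()
            y = _sph_harm(m, ell, phi, theta)
            f += c * (np.real(y) if m >= 0 else np.imag(y))
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_phantom(params: PhantomParams) -> tuple[ImageVolume, VOIMask]:
    """Render one phantom: intensity volume plus binary tumor mask.

    The mask covers rim + core (edema is peritumoral, outside the VOI, as it
    would be excluded by a rater segmenting the tumor margin).  Deterministic
    for a fixed parameter object.
    """
    shape = params.grid_shape
    spacing = np.asarray(params.voxel_spacing, dtype=np.float64)
    radii = np.asarray(params.tumor_diameters, dtype=np.float64) / 2.0

    # physical coordinates of voxel centers, tumor at grid center
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * sp
        for n, sp in zip(shape, spacing)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    u, v, w = xx / radii[0], yy / radii[1], zz / radii[2]
    rho = np.sqrt(u**2 + v**2 + w**2)

    boundary = np.ones(shape)
    if params.lobulation_amplitude > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.where(rho > 0, w / np.maximum(rho, 1e-12), 0.0), -1, 1))
            phi = np.arctan2(v, u) + math.pi
        shape_rng = np.random.default_rng(
            params.shape_seed if params.shape_seed is not None else params.seed
        )
        boundary = 1.0 + params.lobulation_amplitude * _lobulation_field(theta, phi, shape_rng)

    mask = rho <= boundary
    if not mask.any():
        raise ValueError("phantom parameters produced an empty tumor mask")
    core = rho <= params.core_fraction * boundary

    lv = params.intensity_levels
    img = np.full(shape, lv.background, dtype=np.float64)
    if params.edema_thickness > 0:
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        img[(dist > 0) & (dist <= params.edema_thickness)] = lv.edema
    img[mask] = lv.rim
    img[core] = lv.core

    noise_rng = np.random.default_rng(params.seed)
    unit_noise = noise_rng.standard_normal(shape)
    bg_sd = params.background_noise_sd if params.background_noise_sd is not None else params.noise_sd
    sd_field = np.where(mask, params.noise_sd, bg_sd)
    img = img + sd_field * unit_noise

    vol = ImageVolume(data=img, spacing=tuple(spacing))
    voi = VOIMask(data=mask, spacing=tuple(spacing))
    return vol, voi


def grow_phantom(baseline: PhantomParams, sgr: float, delta_days: float) -> PhantomParams:
    """Scale a phantom by exponential growth at ``sgr`` %/day over ``delta_days``.

    Each linear dimension scales by the cube root of the volume factor
    exp(sgr·Δt/100); negative sgr shrinks the tumor.
    """
    if delta_days <= 0:
        raise ValueError(f"delta_days must be > 0, got {delta_days}")
    linear = math.exp(sgr * delta_days / 100.0) ** (1.0 / 3.0)
    new_d = tuple(d * linear for d in baseline.tumor_diameters)
    return replace(baseline, tumor_diameters=new_d)


@dataclass(frozen=True)
class TextureEffect:
    """Multiplicative endpoint-only texture perturbation for one group.

    Effects act on generator knobs, not on feature values, so recovered
    feature shifts are emergent: ``core_fraction_mult`` scales the necrotic
    core fraction, ``noise_sd_mult`` the in-mask noise, and
    ``contrast_mult`` the core-rim intensity difference.
    """

    core_fraction_mult: float = 1.0
    noise_sd_mult: float = 1.0
    contrast_mult: float = 1.0

    @property
    def is_null(self) -> bool:
        return self.core_fraction_mult == self.noise_sd_mult == self.contrast_mult == 1.0


#: Pre-registered strong effect used in recovery experiments.
STRONG_EFFECT = TextureEffect(core_fraction_mult=2.0, noise_sd_mult=1.5, contrast_mult=1.3)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    sgr_pct_per_day: float
    sgr_sd: float = 1.5
    effect: TextureEffect = field(default_factory=TextureEffect)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"group {self.label!r}: n_subjects must be >= 1")
        if not math.isfinite(self.sgr_pct_per_day):
            raise ValueError(f"group {self.label!r}: SGR must be finite")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    timepoints: tuple[float, float] = (8.0, 26.0)
    contrasts: tuple[str, ...] = ("T1", "T2")
    baseline_diameter_mean: float = 6.0
    baseline_diameter_sd: float = 0.5
    caliper_noise_cv: float = 0.03
    voxel_spacing: tuple[float, float, float] = (0.109, 0.25, 1.0)
    phantom_defaults: PhantomParams = field(default_factory=PhantomParams)
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate group labels in cohort spec: {labels}")
        if not all(t2 > t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError(f"timepoints must be strictly increasing, got {self.timepoints}")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default study design: four groups sized 29/23/23/6, days 8 and 26.

    Doubling times: control and two treatment arms at 4.5–4.8 days, one
    accelerated arm at 3.5 days (SGR = 100·ln2/DT).
    """

    def sgr(dt_days: float) -> float:
        return 100.0 * math.log(2.0) / dt_days

    groups = (
        GroupSpec("TREAT-A", 29, sgr(4.6)),
        GroupSpec("TREAT-B", 23, sgr(4.8)),
        GroupSpec("TREAT-C", 23, sgr(3.5)),  # accelerated growth arm
        GroupSpec("CONTROL", 6, sgr(4.5)),
    )
    return CohortSpec(groups=groups, seed=seed)


def _grid_for(diameters: tuple[float, float, float], spec: CohortSpec,
              lobulation: float, edema: float) -> tuple[int, int, int]:
    """Smallest comfortable grid for the endpoint tumor (2 mm margin)."""
    shape = []
    for d, sp in zip(diameters, spec.voxel_spacing):
        extent = d * (1.0 + lobulation) + 2 * edema + 2.0
        shape.append(max(8, int(math.ceil(extent / sp))))
    return tuple(shape)  # type: ignore[return-value]


@dataclass(eq=False)
class Cohort:
    """A generated cohort: tables, per-render phantom parameters, truth.

    Images are rendered lazily through :meth:`render` to keep memory flat;
    rendering is deterministic, so repeated calls return identical arrays.
    """

    spec: CohortSpec
    subjects: pd.DataFrame  # subject_id, group
    caliper: pd.DataFrame  # subject_id, group, modality, day, ap_mm, ts_mm, cc_mm
    phantoms: dict[tuple[str, float, str], PhantomParams]
    truth: dict

    def render(self, subject_id: str, day: float, contrast: str) -> tuple[ImageVolume, VOIMask]:
        return generate_phantom(self.phantoms[(subject_id, day, contrast)])

    def iter_renders(self):
        for (sid, day, contrast), params in sorted(self.phantoms.items()):
            yield sid, day, contrast, generate_phantom(params)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full longitudinal cohort from a :class:`CohortSpec`.

    Per subject: baseline diameters drawn around the cohort mean, a true SGR
    drawn around the group mean, endpoint diameters scaled exponentially,
    caliper measurements for two modalities with independent multiplicative
    noise, and one phantom parameterization per (timepoint, contrast).
    Group texture effects perturb the endpoint renders only.
    """
    root = np.random.SeedSequence(spec.seed)
    t1, t2 = spec.timepoints[0], spec.timepoints[-1]
    dt_days = t2 - t1
    base = spec.phantom_defaults

    subj_rows, caliper_rows = [], []
    phantoms: dict[tuple[str, float, str], PhantomParams] = {}
    truth_subjects: dict[str, dict] = {}

    group_seeds = root.spawn(len(spec.groups))
    idx = 0
    for g, gseed in zip(spec.groups, group_seeds):
        subject_seeds = gseed.spawn(g.n_subjects)
        for k, sseed in enumerate(subject_seeds):
            idx += 1
            sid = f"S{idx:03d}"
            rng = np.random.default_rng(sseed)
            diams = tuple(
                float(max(1.0, rng.normal(spec.baseline_diameter_mean, spec.baseline_diameter_sd)))
                for _ in range(3)
            )
            true_sgr = float(rng.normal(g.sgr_pct_per_day, g.sgr_sd))
            end_scale = math.exp(true_sgr * dt_days / 100.0) ** (1.0 / 3.0)
            end_diams = tuple(d * end_scale for d in diams)

            # seeds below 2^31 for reproducible, independent streams
            shape_seed = int(rng.integers(2**31))
            noise_seeds = {
                (day, c): int(rng.integers(2**31))
                for day in (t1, t2)
                for c in spec.contrasts
            }
            grid = _grid_for(end_diams, spec, base.lobulation_amplitude, base.edema_thickness)
            for c in spec.contrasts:
                levels = CONTRAST_INTENSITIES.get(c, base.intensity_levels)
                p1 = replace(
                    base,
                    grid_shape=grid,
                    voxel_spacing=spec.voxel_spacing,
                    tumor_diameters=diams,
                    intensity_levels=levels,
                    seed=noise_seeds[(t1, c)],
                    shape_seed=shape_seed,
                )
                p2 = replace(
                    grow_phantom(p1, true_sgr, dt_days),
                    seed=noise_seeds[(t2, c)],
                )
                if not g.effect.is_null:
                    e = g.effect
                    new_core = min(0.9, p2.core_fraction * e.core_fraction_mult)
                    new_levels = replace(
                        levels,
                        core=levels.rim + (levels.core - levels.rim) * e.contrast_mult,
                    )
                    p2 = replace(
                        p2,
                        core_fraction=new_core,
                        noise_sd=p2.noise_sd * e.noise_sd_mult,
                        background_noise_sd=p2.background_noise_sd
                        if p2.background_noise_sd is not None
                        else p2.noise_sd,
                        intensity_levels=new_levels,
                    )
                phantoms[(sid, t1, c)] = p1
                phantoms[(sid, t2, c)] = p2

            subj_rows.append({"subject_id": sid, "group": g.label})
            for modality in ("us", "mri"):
                for day, dd in ((t1, diams), (t2, end_diams)):
                    noise = rng.normal(1.0, spec.caliper_noise_cv, size=3)
                    caliper_rows.append(
                        {
                            "subject_id": sid,
                            "group": g.label,
                            "modality": modality,
                            "day": day,
                            "ap_mm": dd[0] * noise[0],
                            "ts_mm": dd[1] * noise[1],
                            "cc_mm": dd[2] * noise[2],
                        }
                    )
            truth_subjects[sid] = {
                "group": g.label,
                "true_sgr_pct_per_day": true_sgr,
                "true_dt_days": math.log(2.0) / (true_sgr / 100.0) if true_sgr > 0 else None,
                "baseline_diameters_mm": list(diams),
                "endpoint_diameters_mm": list(end_diams),
            }

    truth = {
        "seed": spec.seed,
        "timepoints": list(spec.timepoints),
        "groups": {
            g.label: {
                "n_subjects": g.n_subjects,
                "mean_sgr_pct_per_day": g.sgr_pct_per_day,
                "mean_dt_days": 100.0 * math.log(2.0) / g.sgr_pct_per_day
                if g.sgr_pct_per_day > 0
                else None,
                "effect": {
                    "core_fraction_mult": g.effect.core_fraction_mult,
                    "noise_sd_mult": g.effect.noise_sd_mult,
                    "contrast_mult": g.effect.contrast_mult,
                },
            }
            for g in spec.groups
        },
        "subjects": truth_subjects,
    }
    return Cohort(
        spec=spec,
        subjects=pd.DataFrame(subj_rows),
        caliper=pd.DataFrame(caliper_rows),
        phantoms=phantoms,
        truth=truth,
    )
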