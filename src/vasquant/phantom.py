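"""Synthetic vessel phantoms and cohort tables.

The voxel phantom is an axis-aligned tube: a blood-filled lumen surrounded
by a vessel wall, embedded in soft tissue, with an optional focal lesion
(a few consecutive axial slices of elevated wall uptake). Compartment
activities clear mono-exponentially from injection, with blood clearing
faster than wall — the mechanism behind SUVmax falling while TBRmax rises
at later uptake times. Scanner resolution is emulated by a Gaussian PSF
and reconstruction noise by additive Gaussian noise clipped at zero;
ground truth (masks and pre-blur values) is recorded alongside.

The tabular cohort simulator generates long-format segment measurements
from an explicit mixed-effects model (fixed time slope, per-patient random
intercept and slope, per-segment intercept, residual noise) with optional
two-observer replicates and imperfect observer slice selection — the
stand-in for the study's patient table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import Image3D, SegmentVOI, Units, VoxelGrid
from .segments import ARTERIAL_SEGMENTS

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "paper_like_spec",
    "make_vessel_phantom",
    "apply_psf",
    "add_noise",
    "simulate_observer",
    "make_cohort_table",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and degradation settings for one vessel phantom.

    SUV values are specified at injection (t = 0) and decay biologically
    with the given compartment half-lives; physical decay is already folded
    into SUV by definition.
    """

    grid: VoxelGrid = VoxelGrid((64, 64, 48), (4.0, 4.0, 4.0))
    center_xy_mm: tuple[float, float] = (128.0, 128.0)
    lumen_radius_mm: float = 12.0
    wall_thickness_mm: float = 6.0
    z_extent: tuple[int, int] = (4, 44)  # axial slice range [lo, hi)
    wall_suv0: float = 1.45
    wall_halflife_bio_min: float = 550.0
    blood_suv0: float = 1.45
    blood_halflife_bio_min: float = 140.0
    lesion_z: tuple[int, int] | None = None  # [lo, hi) slices
    lesion_multiplier: float = 1.5
    tissue_suv: float = 0.5
    psf_fwhm_mm: float = 7.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ValueError("lumen radius and wall thickness must be positive")
        if self.lesion_z is not None and self.lesion_multiplier <= 1:
            raise ValueError("lesion multiplier must exceed 1")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("PSF FWHM and noise SD must be non-negative")


def paper_like_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Preset matching the study conditions: blood clears faster than wall,
    a focal lesion mid-vessel, clinical-PET blur and mild noise."""
    spec = PhantomSpec(lesion_z=(20, 23), seed=seed)
    if spec.blood_halflife_bio_min >= spec.wall_halflife_bio_min:
        raise ValueError("paper-like preset requires blood clearing faster than wall")
    return replace(spec, **overrides) if overrides else spec


@dataclass
class PhantomTruth:
    wall: SegmentVOI
    lumen: SegmentVOI
    tissue: SegmentVOI
    true_wall_suvmax: float
    true_blood_suvmean: float
    lesion_slices: list[int]
    hot_slice_z: int | None

    def __post_init__(self) -> None:
        if np.any(self.wall.mask & self.lumen.mask):
            raise ValueError("wall and lumen masks overlap")
        if self.true_wall_suvmax <= 0 or self.true_blood_suvmean <= 0:
            raise ValueError("truth values must be strictly positive")


def _bio_decay(suv0: float, halflife: float, t_min: float) -> float:
    return suv0 * 2.0 ** (-t_min / halflife)


def make_vessel_phantom(
    spec: PhantomSpec, uptake_time_min: float
) -> tuple[Image3D, PhantomTruth]:
    """Build the phantom volume at one uptake time, plus its ground truth.

    Compartments are painted at their noiseless values, the lesion slices
    multiplied, then PSF blur and noise applied. Truth (masks, pre-blur
    wall SUVmax and blood SUVmean, lesion slices) is recorded before any
    degradation.
    """
    grid = spec.grid
    nx, ny, nz = grid.shape
    zlo, zhi = spec.z_extent
    if not (0 <= zlo < zhi <= nz):
        raise ValueError(f"vessel z extent {spec.z_extent} outside grid (nz={nz})")
    xs = grid.origin[0] + np.arange(nx) * grid.spacing[0]
    ys = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    r = np.sqrt(
        (xs[:, None] - spec.center_xy_mm[0]) ** 2
        + (ys[None, :] - spec.center_xy_mm[1]) ** 2
    )
    outer = spec.lumen_radius_mm + spec.wall_thickness_mm
    if outer >= min(xs.max() - spec.center_xy_mm[0], spec.center_xy_mm[0] - xs.min(),
                    ys.max() - spec.center_xy_mm[1], spec.center_xy_mm[1] - ys.min()):
        raise ValueError("vessel does not fit inside the grid")
    in_z = np.zeros(nz, dtype=bool)
    in_z[zlo:zhi] = True
    lumen2d = r <= spec.lumen_radius_mm
    wall2d = (r > spec.lumen_radius_mm) & (r <= outer)
    lumen = lumen2d[:, :, None] & in_z[None, None, :]
    wall = wall2d[:, :, None] & in_z[None, None, :]
    tissue = ~(lumen | wall)

    wall_suv = _bio_decay(spec.wall_suv0, spec.wall_halflife_bio_min, uptake_time_min)
    blood_suv = _bio_decay(spec.blood_suv0, spec.blood_halflife_bio_min, uptake_time_min)

    values = np.full(grid.shape, spec.tissue_suv, dtype=np.float64)
    values[lumen] = blood_suv
    values[wall] = wall_suv
    lesion_slices: list[int] = []
    hot_z: int | None = None
    true_wall_max = wall_suv
    if spec.lesion_z is not None:
        llo, lhi = spec.lesion_z
        lesion_slices = [z for z in range(llo, lhi) if zlo <= z < zhi]
        for z in lesion_slices:
            values[:, :, z][wall2d] *= spec.lesion_multiplier
        if lesion_slices:
            true_wall_max = wall_suv * spec.lesion_multiplier
            hot_z = lesion_slices[len(lesion_slices) // 2]

    truth = PhantomTruth(
        wall=SegmentVOI("ascending_aorta", grid, wall),
        lumen=SegmentVOI("ascending_aorta_blood_pool", grid, lumen),
        tissue=SegmentVOI("superior_vena_cava", grid, tissue),
        true_wall_suvmax=true_wall_max,
        true_blood_suvmean=blood_suv,
        lesion_slices=lesion_slices,
        hot_slice_z=hot_z,
    )

    img = Image3D(grid, values, Units.SUV)
    if spec.psf_fwhm_mm > 0:
        img = apply_psf(img, spec.psf_fwhm_mm)
    if spec.noise_sd > 0:
        img = add_noise(img, spec.noise_sd, spec.seed)
    return img, truth


def apply_psf(img: Image3D, fwhm_mm: float) -> Image3D:
    """Gaussian PSF blur with σ = FWHM/2.3548 per axis, in millimetres.

    Reflective boundaries keep the total image sum conserved.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return img.with_values(img.values.copy())
    sigma_vox = [fwhm_mm / _FWHM_TO_SIGMA / s for s in img.grid.spacing]
    out = ndimage.gaussian_filter(img.values, sigma_vox, mode="reflect")
    return img.with_values(out)


def add_noise(img: Image3D, sd: float, seed: int) -> Image3D:
    """Additive i.i.d. Gaussian noise, clipped at zero, seeded."""
    if sd < 0:
        raise ValueError("noise SD must be non-negative")
    if sd == 0:
        return img.with_values(img.values.copy())
    rng = np.random.default_rng(seed)
    out = img.values + rng.normal(0.0, sd, size=img.grid.shape)
    return img.with_values(np.clip(out, 0.0, None))


def simulate_observer(
    true_hot_z: int,
    voi: SegmentVOI,
    error_p: float,
    offset_sd_slices: float,
    rng: np.random.Generator,
) -> int:
    """An observer's visual hot-slice pick.

    With probability 1 − error_p the true hot slice is returned; otherwise
    the pick is offset by a rounded Gaussian number of slices (never 0 when
    the offset SD is positive) and clipped to the VOI's slice range.
    """
    if not 0 <= error_p <= 1:
        raise ValueError("error probability must be in [0, 1]")
    zs = voi.z_indices
    if error_p == 0 or offset_sd_slices == 0 or rng.random() >= error_p:
        return int(true_hot_z)
    off = 0
    while off == 0:
        off = int(round(rng.normal(0.0, offset_sd_slices)))
    z = int(np.clip(true_hot_z + off, zs.min(), zs.max()))
    # snap to the nearest slice actually in the VOI
    return int(zs[np.argmin(np.abs(zs - z))])


# ---------------------------------------------------------------------------
# Tabular cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Generating mixed-effects model for a simulated measurement table.

    Defaults emulate the study design: 6 patients, the 10 arterial
    segments, scans at 38/60/90 min. The outcome follows
    ``intercept + slope·t + b0_patient + b1_patient·t + b_segment + ε``,
    and each record is observed by ``n_observers`` raters with independent
    measurement error of SD ``observer_error_sd``.
    """

    n_patients: int = 6
    segments: tuple[str, ...] = ARTERIAL_SEGMENTS
    timepoints_min: tuple[float, ...] = (38.0, 60.0, 90.0)
    intercept: float = 1.12
    slope_per_min: float = 0.0047
    patient_intercept_sd: float = 0.19
    patient_slope_sd: float = 0.002
    segment_sd: float = 0.15
    residual_sd: float = 0.15
    n_observers: int = 2
    observer_error_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("patient_intercept_sd", "patient_slope_sd", "segment_sd",
                     "residual_sd", "observer_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_patients < 1 or self.n_observers < 1:
            raise ValueError("need at least one patient and one observer")


def make_cohort_table(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format cohort table plus the generating truth.

    Returns one row per (patient, segment, timepoint, observer) with the
    latent true outcome and the observed value, and a truth dict holding
    every generating parameter and realised random effect.
    """
    rng = np.random.default_rng(spec.seed)
    b0 = rng.normal(0.0, spec.patient_intercept_sd, spec.n_patients)
    b1 = rng.normal(0.0, spec.patient_slope_sd, spec.n_patients)
    bseg = rng.normal(0.0, spec.segment_sd, len(spec.segments))
    rows = []
    for ip in range(spec.n_patients):
        pid = f"P{ip + 1:02d}"
        for iseg, seg in enumerate(spec.segments):
            for t in spec.timepoints_min:
                latent = (spec.intercept + spec.slope_per_min * t
                          + b0[ip] + b1[ip] * t + bseg[iseg]
                          + rng.normal(0.0, spec.residual_sd))
                for obs in range(1, spec.n_observers + 1):
                    observed = latent + rng.normal(0.0, spec.observer_error_sd)
                    rows.append({
                        "patient_id": pid, "segment": seg,
                        "timepoint_min": t, "observer": f"obs{obs}",
                        "true_value": latent,
                        "suvmax": max(observed, 0.0),
                    })
    truth = {
        "intercept": spec.intercept,
        "slope_per_min": spec.slope_per_min,
        "patient_intercepts": b0.tolist(),
        "patient_slopes": b1.tolist(),
        "segment_effects": bseg.tolist(),
        "residual_sd": spec.residual_sd,
        "observer_error_sd": spec.observer_error_sd,
        "seed": spec.seed,
    }
    return pd.DataFrame(rows), truth
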