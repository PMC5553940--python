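"""SUVmax extraction schemes, blood-pool background, and TBR.

Three regional hot-spot statistics are compared:

* **WS** (whole segment): SUVmax over the full stacked-ROI volume;
* **HS** (hot spot): SUVmax on the single axial slice with the most intense
  uptake — automated (the argmax slice) or observer-picked via override;
* **MDS** (most diseased segment): mean of the per-slice SUVmax over the hot
  slice and its proximal/distal neighbours (slices outside the VOI drop out
  of the mean — averaging more slices is what pulls MDS below HS).

The target-to-background ratio divides a wall SUVmax by a blood-pool
SUVmean; the body-size normalisation factor cancels in the ratio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import Image3D, SegmentVOI
from .segments import validate_segment
from .suv import Normalisation

__all__ = [
    "Method",
    "SegmentMeasurement",
    "BackgroundMeasurement",
    "suvmax_ws",
    "hot_slice",
    "suvmax_hs",
    "suvmax_mds",
    "blood_pool_suvmean",
    "tbr_max",
    "quantify_study",
    "MEASUREMENT_COLUMNS",
]


class Method(enum.Enum):
    WS = "WS"
    HS = "HS"
    MDS = "MDS"


@dataclass(frozen=True)
class SegmentMeasurement:
    patient_id: str
    segment: str
    timepoint_min: float
    method: Method
    normalisation: Normalisation
    suvmax: float
    tbr_max: float | None = None
    observer: str | None = None

    def __post_init__(self) -> None:
        validate_segment(self.segment)
        if self.suvmax < 0:
            raise ValueError("suvmax must be non-negative")
        if self.tbr_max is not None and self.tbr_max < 0:
            raise ValueError("tbr_max must be non-negative")


@dataclass(frozen=True)
class BackgroundMeasurement:
    patient_id: str
    region: str
    timepoint_min: float
    suvmean: float
    n_slices: int

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValueError("blood-pool VOI must span at least 3 axial slices")
        if self.suvmean < 0:
            raise ValueError("suvmean must be non-negative")


def _check_alignment(img: Image3D, voi: SegmentVOI) -> None:
    if img.grid != voi.grid:
        raise ValueError(
            f"VOI for {voi.segment!r} lives on a different grid than the image; "
            "transfer it first"
        )


def suvmax_ws(img: Image3D, voi: SegmentVOI) -> float:
    """Whole-segment SUVmax: maximum voxel value inside the full VOI."""
    _check_alignment(img, voi)
    return float(img.values[voi.mask].max())


def hot_slice(img: Image3D, voi: SegmentVOI) -> int:
    """z-index of the axial slice holding the within-VOI global maximum.

    Ties are broken toward the lowest z-index for determinism.
    """
    _check_alignment(img, voi)
    best_z, best_v = -1, -np.inf
    for z, roi in voi.slice_rois:
        v = img.values[:, :, z][roi].max()
        if v > best_v:  # strict: first (lowest-z) slice wins ties
            best_z, best_v = z, v
    return best_z


def _slice_max(img: Image3D, voi: SegmentVOI, z: int) -> float:
    roi = voi.mask[:, :, z]
    return float(img.values[:, :, z][roi].max())


def suvmax_hs(img: Image3D, voi: SegmentVOI, slice_override: int | None = None) -> float:
    """Hot-spot SUVmax on one axial slice.

    Without an override this is the per-slice max on the automated hot slice
    and equals :func:`suvmax_ws` exactly. An override models an observer's
    visual slice pick and must intersect the VOI.
    """
    _check_alignment(img, voi)
    z = hot_slice(img, voi) if slice_override is None else int(slice_override)
    if not voi.mask[:, :, z].any():
        raise ValueError(f"slice {z} does not intersect the VOI for {voi.segment!r}")
    return _slice_max(img, voi, z)


def suvmax_mds(img: Image3D, voi: SegmentVOI, center: int | None = None) -> float:
    """Most-diseased-segment SUVmax.

    Mean of the per-slice maxima over {center-1, center, center+1}
    intersected with the VOI; the center defaults to the automated hot
    slice, and neighbours absent from the VOI are dropped from the mean.
    """
    _check_alignment(img, voi)
    c = hot_slice(img, voi) if center is None else int(center)
    if not voi.mask[:, :, c].any():
        raise ValueError(f"center slice {c} does not intersect the VOI")
    zs = [z for z in (c - 1, c, c + 1)
          if 0 <= z < voi.grid.shape[2] and voi.mask[:, :, z].any()]
    return float(np.mean([_slice_max(img, voi, z) for z in zs]))


def blood_pool_suvmean(
    img: Image3D,
    voi: SegmentVOI,
    patient_id: str = "",
    timepoint_min: float = 0.0,
    erode: bool = False,
) -> BackgroundMeasurement:
    """Blood-pool SUVmean over a lumen VOI spanning >= 3 axial slices.

    Optional 1-voxel morphological erosion suppresses wall spill-in,
    mimicking ROIs drawn in the center of the blood pool.
    """
    _check_alignment(img, voi)
    mask = voi.mask
    if voi.n_slices < 3:
        raise ValueError(
            f"blood-pool VOI for {voi.segment!r} spans {voi.n_slices} slices; "
            "at least 3 axial slices are required"
        )
    if erode:
        mask = ndimage.binary_erosion(mask)
        if not mask.any():
            raise ValueError("1-voxel erosion emptied the blood-pool mask")
    n_slices = int(np.count_nonzero(mask.any(axis=(0, 1))))
    if n_slices < 3:
        raise ValueError("eroded blood-pool VOI spans fewer than 3 axial slices")
    return BackgroundMeasurement(
        patient_id=patient_id,
        region=voi.segment,
        timepoint_min=timepoint_min,
        suvmean=float(img.values[mask].mean()),
        n_slices=n_slices,
    )


def tbr_max(suvmax_wall: float, background: BackgroundMeasurement) -> float:
    """Target-to-background ratio: wall SUVmax / blood-pool SUVmean."""
    if background.suvmean <= 0:
        raise ValueError("background SUVmean must be positive for TBR")
    return suvmax_wall / background.suvmean


MEASUREMENT_COLUMNS = [
    "patient_id", "segment", "timepoint_min", "method", "normalisation",
    "observer", "suvmax", "background_region", "background_suvmean", "tbr_max",
]


def quantify_study(
    suv_volumes: dict[str, dict[float, Image3D]],
    vois: dict[str, list[SegmentVOI]],
    background_vois: dict[str, list[SegmentVOI]] | None = None,
    methods: tuple[Method, ...] = (Method.WS, Method.HS, Method.MDS),
    normalisation: Normalisation = Normalisation.BW,
    norm_factors: dict[str, dict[float, float]] | None = None,
    segments: list[str] | None = None,
) -> pd.DataFrame:
    """Batch driver: one record per (patient, segment, timepoint, method).

    ``suv_volumes[patient][timepoint]`` are SUV images under the BW
    normalisation; ``norm_factors[patient][timepoint]`` optionally rescales
    them to another normalisation (ratio of factors). Background VOIs feed
    the TBR denominator (mean of available measurements per patient and
    timepoint). A configured segment missing its VOI yields a row with NaN
    values, never a silently dropped record. Output ordering is
    deterministic (patient, segment, timepoint, method).
    """
    background_vois = background_vois or {}
    rows: list[dict] = []
    for patient in sorted(suv_volumes):
        voi_by_seg = {v.segment: v for v in vois.get(patient, [])}
        wanted = segments if segments is not None else sorted(voi_by_seg)
        for seg in wanted:
            validate_segment(seg)
            for t in sorted(suv_volumes[patient]):
                img = suv_volumes[patient][t]
                scale = 1.0
                if norm_factors is not None:
                    scale = norm_factors[patient][t]
                bg = None
                bgs = [
                    blood_pool_suvmean(img, bvoi, patient, t)
                    for bvoi in background_vois.get(patient, [])
                ]
                if bgs:
                    bg_mean = float(np.mean([b.suvmean for b in bgs]))
                    bg_region = "+".join(sorted(b.region for b in bgs))
                    bg = (bg_region, bg_mean)
                for method in methods:
                    row = {
                        "patient_id": patient, "segment": seg,
                        "timepoint_min": t, "method": method.value,
                        "normalisation": normalisation.value, "observer": None,
                        "suvmax": np.nan, "background_region": None,
                        "background_suvmean": np.nan, "tbr_max": np.nan,
                    }
                    voi = voi_by_seg.get(seg)
                    if voi is not None:
                        if method is Method.WS:
                            s = suvmax_ws(img, voi)
                        elif method is Method.HS:
                            s = suvmax_hs(img, voi)
                        else:
                            s = suvmax_mds(img, voi)
                        row["suvmax"] = s * scale
                        if bg is not None:
                            row["background_region"] = bg[0]
                            row["background_suvmean"] = bg[1] * scale
                            row["tbr_max"] = row["suvmax"] / row["background_suvmean"]
                    rows.append(row)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
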