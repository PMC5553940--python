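"""Decay correction and standardized uptake value (SUV) computation.

SUV is the decay-corrected tissue activity concentration divided by injected
dose per unit of a body-size normaliser. Three normalisers are supported:

* **BW** — body weight (grams): the conventional dimensionless g/ml SUV;
* **LBM** — lean body mass (Janmahasatian, sex-specific), often called SUL;
* **BSA** — body surface area (DuBois), in cm² — SUV(BSA) carries different
  units and sits on a ~0.05 scale rather than ~2.

The injected dose is decayed to scan start (single whole-body pass). An
optional multiplicative plasma-glucose correction to 5.0 mmol/l is off by
default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .imaging import Image3D, Units

__all__ = [
    "F18_HALF_LIFE_MIN",
    "Sex",
    "Normalisation",
    "TracerDose",
    "Subject",
    "ScanContext",
    "decayed_dose",
    "lean_body_mass",
    "body_surface_area",
    "suv_factor",
    "suv_image",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Normalisation(enum.Enum):
    BW = "BW"
    LBM = "LBM"
    BSA = "BSA"


@dataclass(frozen=True)
class TracerDose:
    """Injected tracer activity and timing (study clock, minutes)."""

    injected_activity_mbq: float
    injection_time_min: float = 0.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be positive")
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")


@dataclass(frozen=True)
class Subject:
    weight_kg: float
    height_m: float
    sex: Sex
    glucose_mmol_l: float | None = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if self.height_m <= 0:
            raise ValueError("height must be positive")
        if self.bmi < 12:
            raise ValueError(
                f"BMI {self.bmi:.1f} < 12: outside the validity range of the "
                "lean-body-mass formula"
            )

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2


@dataclass(frozen=True)
class ScanContext:
    """When the scan starts and how SUV is normalised."""

    scan_start_min: float
    normalisation: Normalisation = Normalisation.BW
    glucose_corrected: bool = False

    def uptake_time(self, dose: TracerDose) -> float:
        dt = self.scan_start_min - dose.injection_time_min
        if dt <= 0:
            raise ValueError("scan start must be after injection")
        return dt


def decayed_dose(dose: TracerDose, at_time_min: float) -> float:
    """Injected activity (MBq) physically decayed to *at_time_min*."""
    dt = at_time_min - dose.injection_time_min
    if dt < 0:
        raise ValueError("cannot evaluate dose before injection")
    return dose.injected_activity_mbq * 2.0 ** (-dt / dose.half_life_min)


def lean_body_mass(subject: Subject) -> float:
    """Janmahasatian lean body mass (kg), sex-specific.

    male:   9270·W / (6680 + 216·BMI)
    female: 9270·W / (8780 + 244·BMI)
    """
    w, bmi = subject.weight_kg, subject.bmi
    if subject.sex is Sex.MALE:
        return 9270.0 * w / (6680.0 + 216.0 * bmi)
    return 9270.0 * w / (8780.0 + 244.0 * bmi)


def body_surface_area(subject: Subject) -> float:
    """DuBois body surface area (m²): 0.007184 · W^0.425 · (100·H)^0.725."""
    return 0.007184 * subject.weight_kg**0.425 * (100.0 * subject.height_m) ** 0.725


def suv_factor(subject: Subject, dose: TracerDose, ctx: ScanContext) -> float:
    """Multiplier turning an activity concentration (Bq/ml) into SUV.

    BW/LBM: normaliser in grams; BSA: normaliser in cm² (hence the much
    smaller SUV scale). The dose is decayed to scan start. If glucose
    correction is on, the factor is multiplied by glucose/5.0 mmol/l.
    """
    ctx.uptake_time(dose)  # validates scan after injection
    dose_bq = decayed_dose(dose, ctx.scan_start_min) * 1e6
    if ctx.normalisation is Normalisation.BW:
        normaliser = subject.weight_kg * 1000.0  # g
    elif ctx.normalisation is Normalisation.LBM:
        normaliser = lean_body_mass(subject) * 1000.0  # g
    else:
        normaliser = body_surface_area(subject) * 1e4  # cm²
    factor = normaliser / dose_bq
    if ctx.glucose_corrected:
        if subject.glucose_mmol_l is None:
            raise ValueError("glucose correction requested but glucose is missing")
        factor *= subject.glucose_mmol_l / 5.0
    return factor


def suv_image(img: Image3D, factor: float) -> Image3D:
    """Apply an SUV factor voxelwise; units flip from Bq/ml to SUV."""
    if img.units is not Units.BQ_PER_ML:
        raise ValueError(f"expected Bq/ml input, got {img.units}")
    return Image3D(img.grid, img.values * factor, Units.SUV)
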