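"""Run configuration, study-table ingestion, and provenance.

A StudyTable is the long-format measurement table the statistics layer
consumes — either written by :func:`vasquant.voi.quantify_study`, by the
cohort simulator, or ingested from the deposited per-patient table after
export to CSV (a column-mapping file translates foreign column names).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .segments import ALL_SEGMENTS

__all__ = ["RunConfig", "StudyTable", "read_study_table", "provenance_block"]

REQUIRED_COLUMNS = ["patient_id", "segment", "timepoint_min", "method", "suvmax"]
OPTIONAL_COLUMNS = ["normalisation", "observer", "background_region",
                    "background_suvmean", "tbr_max"]

_KNOWN_KEYS = {
    "volumes", "masks", "metadata", "segments", "methods", "normalisations",
    "background_region", "rebin_method", "icc_alpha", "lmm_random_slope",
    "lmm_segment_intercept", "lmm_time_as_factor", "out_dir", "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    volumes: str | None = None
    masks: str | None = None
    metadata: str | None = None
    segments: tuple[str, ...] = ()
    methods: tuple[str, ...] = ("WS", "HS", "MDS")
    normalisations: tuple[str, ...] = ("BW",)
    background_region: str = "vena_cava_mean"
    rebin_method: str = "NEAREST"
    icc_alpha: float = 0.05
    lmm_random_slope: bool = True
    lmm_segment_intercept: bool = True
    lmm_time_as_factor: bool = False
    out_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("segments", "methods", "normalisations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for m in cfg.methods:
            if m not in ("WS", "HS", "MDS"):
                raise ValueError(f"unknown method {m!r}")
        for n in cfg.normalisations:
            if n not in ("BW", "LBM", "BSA"):
                raise ValueError(f"unknown normalisation {n!r}")
        for s in cfg.segments:
            if s not in ALL_SEGMENTS:
                raise ValueError(f"unknown segment {s!r}")
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyTable:
    """Long-format measurement records with ingestion bookkeeping."""

    records: pd.DataFrame
    n_dropped: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"study table missing required columns: {missing}")


def read_study_table(
    path: str | Path,
    dialect: str = "csv",
    column_map: dict[str, str] | str | Path | None = None,
) -> StudyTable:
    """Read a long-format study table from CSV.

    ``dialect='csv'`` expects this package's own column names;
    ``dialect='sav-export'`` reads a CSV exported from a statistical
    package, with *column_map* (dict or YAML/JSON file) translating source
    column names to the required ones. Rows missing the outcome are
    dropped and counted, never silently discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("csv", "sav-export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if dialect == "sav-export":
        if column_map is None:
            raise ValueError("sav-export dialect requires a column mapping")
        if not isinstance(column_map, dict):
            p = Path(column_map)
            text = p.read_text()
            column_map = (json.loads(text) if p.suffix == ".json"
                          else yaml.safe_load(text))
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            "provide a column mapping if the source names differ"
        )
    n0 = len(df)
    df = df.dropna(subset=["suvmax"]).reset_index(drop=True)
    return StudyTable(records=df, n_dropped=n0 - len(df), source=str(path))


def provenance_block(config_hash: str, seed: int) -> dict:
    """Provenance stamped into every output (reruns are byte-identical)."""
    return {"tool": "vasquant", "version": __version__,
            "config_hash": config_hash, "seed": seed}
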