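"""Delimited-text readers/writers and run configuration.

Spectra travel as CSV with the wavenumber in the first column and one
column per accumulation (dark frames flagged by a ``dark_`` column-name
prefix); manifests, feature matrices, and QC tables are plain CSV;
configurations, models, ledgers, and reports are JSON/YAML. Every run can
emit a checksum manifest so outputs are reproducible from (config, seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .classify import ModelSpec
from .preprocess import PreprocessConfig
from .spectra import RawAcquisition, Spectrum
from .synthetic import CohortSpec

__all__ = [
    "write_acquisition",
    "read_acquisition",
    "write_spectrum",
    "read_spectrum",
    "write_manifest",
    "read_manifest",
    "RunConfig",
    "checksum_manifest",
]


def write_acquisition(path: str | Path, acq: RawAcquisition) -> None:
    """Acquisition as CSV: wavenumber, acq_01..acq_N, dark_01..dark_M."""
    cols = {"wavenumber": acq.wavenumbers}
    for i, row in enumerate(acq.repeats, 1):
        cols[f"acq_{i:02d}"] = row
    for i, row in enumerate(acq.darks, 1):
        cols[f"dark_{i:02d}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)


def _validated_axis(df: pd.DataFrame, path: Path) -> np.ndarray:
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: no spectral columns found")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    diffs = np.diff(axis)
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        # +3: header line, 1-based numbering, and the offending row is the
        # second element of the first decreasing pair.
        raise ValueError(f"{path}: wavenumber axis not strictly increasing at line {bad[0] + 3}")
    return axis


def read_acquisition(path: str | Path, exposure_s: float = 1.0, **meta: Any) -> RawAcquisition:
    """Read an acquisition CSV, validating the axis and column layout."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    axis = _validated_axis(df, path)
    acq_cols = [c for c in df.columns[1:] if not c.startswith("dark")]
    dark_cols = [c for c in df.columns[1:] if c.startswith("dark")]
    if not acq_cols:
        raise ValueError(f"{path}: no accumulation columns")
    if not dark_cols:
        raise ValueError(f"{path}: no dark-frame columns")
    return RawAcquisition(
        wavenumbers=axis,
        repeats=df[acq_cols].to_numpy(dtype=float).T,
        darks=df[dark_cols].to_numpy(dtype=float).T,
        exposure_s=exposure_s,
        meta=meta,
    )


def write_spectrum(path: str | Path, s: Spectrum) -> None:
    pd.DataFrame({"wavenumber": s.wavenumbers, "intensity": s.intensities}).to_csv(path, index=False)


def read_spectrum(path: str | Path, stage: str = "raw", **meta: Any) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    axis = _validated_axis(df, path)
    return Spectrum(axis, df.iloc[:, 1].to_numpy(dtype=float), stage=stage, meta=meta)


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    required = {"measurement_id", "patient_id", "pct_cancer", "pct_normal", "pct_fat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one end-to-end analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    qc_threshold: float = 0.6
    model: ModelSpec = field(default_factory=ModelSpec)
    model_ids: tuple[str, ...] = ("A", "B", "C", "FAT")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["class_mixture"] = dict(self.cohort.class_mixture)
        d["model_ids"] = list(self.model_ids)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

        def build(klass, sub):
            if sub is None:
                return klass()
            fields = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - fields
            if bad:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(bad)}")
            sub = dict(sub)
            for key in ("exposure_range_s", "c_grid", "gamma_grid"):
                if key in sub and isinstance(sub[key], list):
                    sub[key] = tuple(sub[key])
            return klass(**sub)

        return cls(
            cohort=build(CohortSpec, data.get("cohort")),
            preprocess=build(PreprocessConfig, data.get("preprocess")),
            qc_threshold=float(data.get("qc_threshold", 0.6)),
            model=build(ModelSpec, data.get("model")),
            model_ids=tuple(data.get("model_ids", ("A", "B", "C", "FAT"))),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def checksum_manifest(paths: list[Path]) -> dict[str, str]:
    """SHA-256 per output file, for the reproducibility manifest."""
    out = {}
    for p in sorted(paths):
        out[p.name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return out
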