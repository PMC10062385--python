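"""Core spectral containers.

A :class:`Spectrum` is the unit flowing through the whole pipeline: a strictly
increasing Raman-shift axis (cm^-1), an intensity vector, and a processing-stage
tag that records how far along the preprocessing chain the data has travelled.
A :class:`RawAcquisition` bundles the N repeat exposures and dark frames
recorded at one probed tissue point.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

#: Processing stages, in pipeline order.
STAGES = (
    "raw",
    "averaged",
    "dark_subtracted",
    "response_corrected",
    "calibrated",
    "baseline_removed",
    "snv",
)

TISSUE_CLASSES = ("cancer", "normal", "fat")


def stage_index(stage: str) -> int:
    """Position of *stage* in the pipeline order; raises on unknown stages."""
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown processing stage {stage!r}; expected one of {STAGES}") from None


def default_axis(start: float = 600.0, stop: float = 1800.0, spacing: float = 1.8) -> np.ndarray:
    """Fingerprint-region wavenumber axis.

    Defaults span 600-1800 cm^-1 at ~1.8 cm^-1 spacing, the spectral
    resolution typical of fibre-probe dispersive Raman systems.
    """
    if spacing <= 0:
        raise ValueError("axis spacing must be positive")
    return np.arange(start, stop + spacing / 2, spacing, dtype=float)


def _validate_axis(wavenumbers: np.ndarray) -> np.ndarray:
    axis = np.asarray(wavenumbers, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("wavenumber axis must be a 1-D array with at least two points")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return axis


@dataclass(eq=False)
class Spectrum:
    """One spectrum plus its processing-stage tag.

    Parameters
    ----------
    wavenumbers : strictly increasing Raman shifts in cm^-1.
    intensities : intensity per axis point (counts for early stages,
        dimensionless after SNV).
    stage : one of :data:`STAGES`.
    meta : free-form provenance (identifiers, pipeline history, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    stage: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.wavenumbers.shape:
            raise ValueError(
                f"intensity length {self.intensities.shape} does not match axis {self.wavenumbers.shape}"
            )
        stage_index(self.stage)

    @property
    def n_points(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def spacing(self) -> float:
        """Median axis spacing in cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def replace(
        self,
        *,
        wavenumbers: np.ndarray | None = None,
        intensities: np.ndarray | None = None,
        stage: str | None = None,
        extra_meta: Mapping[str, Any] | None = None,
    ) -> "Spectrum":
        """Derived spectrum with updated fields; metadata is carried forward."""
        meta = dict(self.meta)
        if extra_meta:
            meta.update(extra_meta)
        return Spectrum(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=self.intensities if intensities is None else intensities,
            stage=self.stage if stage is None else stage,
            meta=meta,
        )


@dataclass(eq=False)
class RawAcquisition:
    """Repeat spectra and dark frames recorded at one probed point.

    ``repeats`` is an (N, P) matrix of the N accumulations, ``darks`` an
    (M, P) matrix of laser-off frames sharing the detector offset.
    """

    wavenumbers: np.ndarray
    repeats: np.ndarray
    darks: np.ndarray
    exposure_s: float
    laser_power_mw: float = 100.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.repeats = np.atleast_2d(np.asarray(self.repeats, dtype=float))
        self.darks = np.atleast_2d(np.asarray(self.darks, dtype=float))
        p = self.wavenumbers.size
        if self.repeats.shape[0] < 1 or self.repeats.shape[1] != p:
            raise ValueError(f"repeats must be (N>=1, {p}); got {self.repeats.shape}")
        if self.darks.shape[0] < 1 or self.darks.shape[1] != p:
            raise ValueError(f"darks must be (M>=1, {p}); got {self.darks.shape}")
        if not self.exposure_s > 0:
            raise ValueError("exposure must be positive")

    @property
    def n_accumulations(self) -> int:
        return int(self.repeats.shape[0])

    def truncated(self, n: int) -> "RawAcquisition":
        """Acquisition restricted to the first *n* accumulations."""
        if not 1 <= n <= self.n_accumulations:
            raise ValueError(
                f"cannot keep {n} accumulations out of {self.n_accumulations} available"
            )
        return RawAcquisition(
            wavenumbers=self.wavenumbers,
            repeats=self.repeats[:n].copy(),
            darks=self.darks.copy(),
            exposure_s=self.exposure_s,
            laser_power_mw=self.laser_power_mw,
            meta=dict(self.meta),
        )
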