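"""Spectral quality scoring and the exclusion gate.

The quality factor scores, between 0 and 1, how much of an SNV-normalized
spectrum's variance is structured (smooth Raman bands) versus stochastic
noise: ``qf = 1 - ||x - smooth(x)||^2 / ||x - mean(x)||^2`` with a fixed
Savitzky-Golay smoother (window 9 samples, polynomial order 3). Smooth
band-dominated spectra leave almost no smoothing residual (qf near 1) while
white noise leaves most of its energy in the residual (qf well below the
gate). This residual-energy form is a reconstruction of the quality metric
used in fibre-probe Raman practice: it is bounded, affine-invariant, and
monotone in signal-to-noise ratio.

Spectra with qf strictly below the threshold (default 0.6) are excluded;
a spectrum exactly at the threshold is kept.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum
from .preprocess import snv

__all__ = ["QualityReport", "quality_factor", "qc_filter"]

_WINDOW = 9
_POLYORDER = 3


@dataclass(frozen=True)
class QualityReport:
    """Quality factor, gate decision, and the energies behind them."""

    qf: float
    threshold: float
    passed: bool
    residual_energy: float
    total_energy: float
    measurement_id: str | None = None


def quality_factor(s: Spectrum, threshold: float = 0.6) -> QualityReport:
    """Quality factor of an SNV spectrum (SNV is applied internally if needed)."""
    if s.stage == "snv":
        x = s.intensities
    elif s.stage == "baseline_removed":
        x = snv(s).intensities
    else:
        raise ValueError(
            f"quality factor is defined on SNV (or baseline-removed) spectra, got stage {s.stage!r}"
        )
    if x.size < _WINDOW:
        raise ValueError(f"spectrum of {x.size} points is shorter than the smoothing window ({_WINDOW})")
    smooth = savgol_filter(x, _WINDOW, _POLYORDER)
    residual = float(np.sum((x - smooth) ** 2))
    total = float(np.sum((x - np.mean(x)) ** 2))
    qf = float(np.clip(1.0 - residual / total, 0.0, 1.0)) if total > 0 else 0.0
    return QualityReport(
        qf=qf,
        threshold=threshold,
        passed=qf >= threshold,
        residual_energy=residual,
        total_energy=total,
        measurement_id=s.meta.get("measurement_id"),
    )


def qc_filter(
    spectra: Sequence[Spectrum],
    threshold: float = 0.6,
) -> tuple[list[Spectrum], list[Spectrum], list[QualityReport]]:
    """Partition spectra at the quality gate.

    Returns (kept, excluded, reports) with one report per input spectrum in
    input order. The gate is strict: qf < threshold excludes, qf equal to
    the threshold keeps.
    """
    kept: list[Spectrum] = []
    excluded: list[Spectrum] = []
    reports: list[QualityReport] = []
    for s in spectra:
        rep = quality_factor(s, threshold=threshold)
        reports.append(rep)
        (kept if rep.passed else excluded).append(s)
    return kept, excluded, reports
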