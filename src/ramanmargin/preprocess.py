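"""Spectral preprocessing chain.

Six steps, in order: (1) averaging of the repeat accumulations, (2) dark
frame subtraction, (3) instrument-response correction against a certified
luminescence standard, (4) wavenumber-axis calibration against a
polycarbonate reference (with resampling to a uniform grid), (5) BubbleFill
baseline removal, and (6) standard normal variate (SNV) normalization.

BubbleFill estimates the autofluorescence background as the upper envelope
of circles ("bubbles") grown from below the spectrum: on each span the
largest circle that fits is lifted until it touches the data, the touch
point splits the span, and the recursion stops once spans are narrower than
a minimum bubble width. Narrow Raman peaks cannot be entered by wide
bubbles, so the envelope tracks only the smooth background.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .spectra import RawAcquisition, Spectrum, stage_index
from .synthetic import POLYCARBONATE_PEAKS, ReferenceStandard

__all__ = [
    "PreprocessConfig",
    "CalibrationModel",
    "BaselineFit",
    "average_accumulations",
    "subtract_dark",
    "correct_instrument_response",
    "fit_calibration",
    "apply_calibration",
    "bubblefill",
    "remove_baseline",
    "snv",
    "run_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    min_bubble_width: smallest bubble span in cm^-1; peaks narrower than
        this survive baseline removal. Default 50 cm^-1, comfortably wider
        than tissue Raman bands (~10-20 cm^-1 FWHM).
    resample_spacing: uniform grid spacing in cm^-1 after calibration.
        Default 1.8 cm^-1, the native spectral resolution: resampling finer
        than the detector would manufacture smoothness and inflate
        smoothness-based quality scores.
    calibration_degree: polynomial degree of the axis-correction map.
    baseline_removal: ablation switch for the BubbleFill step.
    """

    min_bubble_width: float = 50.0
    resample_spacing: float = 1.8
    calibration_degree: int = 1
    baseline_removal: bool = True
    response_floor: float = 1e-3


def _require_stage(s: Spectrum, *allowed: str) -> None:
    if s.stage not in allowed:
        raise ValueError(f"expected spectrum at stage {allowed}, got {s.stage!r}")


def average_accumulations(acq: RawAcquisition) -> Spectrum:
    """Pointwise arithmetic mean of the N repeat spectra."""
    if acq.repeats.shape[0] < 1:
        raise ValueError("acquisition has no repeat spectra")
    mean = acq.repeats.mean(axis=0)
    return Spectrum(
        acq.wavenumbers,
        mean,
        stage="averaged",
        meta={**acq.meta, "n_accumulations": acq.n_accumulations, "exposure_s": acq.exposure_s,
              "pipeline": ["averaged"]},
    )


def subtract_dark(s: Spectrum, darks: np.ndarray) -> Spectrum:
    """Subtract the mean laser-off frame from an averaged spectrum."""
    _require_stage(s, "averaged")
    darks = np.atleast_2d(np.asarray(darks, dtype=float))
    if darks.shape[0] < 1 or darks.shape[1] != s.n_points:
        raise ValueError(f"dark frames must be (M>=1, {s.n_points}); got {darks.shape}")
    out = s.intensities - darks.mean(axis=0)
    return s.replace(intensities=out, stage="dark_subtracted",
                     extra_meta={"pipeline": s.meta.get("pipeline", []) + ["dark_subtracted"]})


def correct_instrument_response(
    s: Spectrum,
    standard_measured: Spectrum | np.ndarray,
    standard_certified: np.ndarray,
    floor: float = 1e-3,
) -> Spectrum:
    """Divide out the instrument transfer function.

    The transfer function is estimated as measured/certified from a
    luminescence standard recorded on the same axis; values below
    ``floor`` (relative to the median response) indicate a dead spectral
    region and are rejected rather than amplified.
    """
    _require_stage(s, "dark_subtracted", "averaged")
    measured = standard_measured.intensities if isinstance(standard_measured, Spectrum) else np.asarray(standard_measured, dtype=float)
    certified = np.asarray(standard_certified, dtype=float)
    if measured.shape != (s.n_points,) or certified.shape != (s.n_points,):
        raise ValueError("standard curves must share the spectrum's axis length")
    if np.any(certified <= 0):
        raise ValueError("certified standard curve must be positive everywhere")
    response = measured / certified
    if np.any(response <= floor * np.median(response)):
        raise ValueError("instrument response falls below the usable floor; cannot correct")
    out = s.intensities / response
    return s.replace(intensities=out, stage="response_corrected",
                     extra_meta={"pipeline": s.meta.get("pipeline", []) + ["response_corrected"]})


@dataclass(eq=False)
class CalibrationModel:
    """Low-order polynomial mapping observed axis positions to true cm^-1.

    ``coefficients`` are in ascending power order (numpy.polynomial
    convention). ``residuals`` are reference-minus-mapped values per matched
    peak, after fitting.
    """

    coefficients: np.ndarray
    matched_observed: np.ndarray
    matched_reference: np.ndarray
    residuals: np.ndarray

    def __call__(self, axis: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(axis, dtype=float), self.coefficients)

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))


def _refine_peak(y: np.ndarray, axis: np.ndarray, idx: int) -> float:
    """Sub-sample peak position by parabolic interpolation through 3 points."""
    if idx <= 0 or idx >= y.size - 1:
        return float(axis[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(axis[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    spacing = axis[min(idx + 1, axis.size - 1)] - axis[max(idx - 1, 0)]
    return float(axis[idx] + delta * spacing / 2.0)


def fit_calibration(
    polycarbonate: Spectrum,
    reference_peaks: Sequence[float] = POLYCARBONATE_PEAKS,
    degree: int = 1,
    prominence: float = 0.1,
    match_window: float = 15.0,
) -> CalibrationModel:
    """Least-squares polynomial mapping detected reference peaks to their table positions.

    Peaks are detected as local maxima with prominence above ``prominence``
    x the data range and localized to sub-sample precision by parabolic
    interpolation; each reference position is matched to the nearest
    detection within ``match_window`` cm^-1. At least three matches are
    required and the fitted map must be strictly increasing over the axis.
    """
    y = polycarbonate.intensities
    axis = polycarbonate.wavenumbers
    idx, _ = find_peaks(y, prominence=prominence * float(np.ptp(y)))
    if idx.size == 0:
        raise ValueError("no peaks detected in the calibration spectrum")
    detected = np.array([_refine_peak(y, axis, i) for i in idx])

    obs, ref = [], []
    for p in reference_peaks:
        d = np.abs(detected - p)
        j = int(np.argmin(d))
        if d[j] <= match_window:
            obs.append(detected[j])
            ref.append(float(p))
    if len(obs) < 3:
        raise ValueError(f"only {len(obs)} reference peaks matched; need at least 3")
    obs_a, ref_a = np.array(obs), np.array(ref)
    coeffs = np.polynomial.polynomial.polyfit(obs_a, ref_a, deg=degree)
    mapped = np.polynomial.polynomial.polyval(axis, coeffs)
    if not np.all(np.diff(mapped) > 0):
        raise ValueError("fitted calibration map is not strictly increasing over the axis")
    residuals = ref_a - np.polynomial.polynomial.polyval(obs_a, coeffs)
    return CalibrationModel(
        coefficients=coeffs,
        matched_observed=obs_a,
        matched_reference=ref_a,
        residuals=residuals,
    )


def apply_calibration(
    s: Spectrum,
    model: CalibrationModel,
    spacing: float = 1.0,
) -> Spectrum:
    """Correct the axis and resample to a uniform grid by linear interpolation.

    The grid is anchored at the first calibrated sample: for a near-identity
    map the new nodes then coincide with the original samples, so the
    interpolation does not mix (and thereby smooth) neighbouring noise.
    """
    _require_stage(s, "response_corrected", "dark_subtracted", "averaged")
    corrected = model(s.wavenumbers)
    if not np.all(np.diff(corrected) > 0):
        raise ValueError("calibrated axis is not strictly increasing")
    n_steps = int(np.floor((corrected[-1] - corrected[0]) / spacing))
    new_axis = corrected[0] + spacing * np.arange(n_steps + 1)
    out = np.interp(new_axis, corrected, s.intensities)
    return Spectrum(
        new_axis,
        out,
        stage="calibrated",
        meta={**s.meta, "pipeline": s.meta.get("pipeline", []) + ["calibrated"]},
    )


@dataclass(eq=False)
class BaselineFit:
    """Additive decomposition input = baseline + raman (exact by construction)."""

    baseline: np.ndarray
    raman: np.ndarray
    min_bubble_width: float


def _grow_bubble(y: np.ndarray, alignment: str) -> tuple[np.ndarray, int]:
    """Largest circle under a span, lifted until it touches the data.

    Edge spans use half-bubbles (double width, apex at the spectrum edge) so
    the envelope can hug the endpoints.
    """
    n = y.size
    x = np.arange(n, dtype=float)
    if alignment == "left":
        radius, middle = float(n), 0.0
    elif alignment == "right":
        radius, middle = float(n), float(n - 1)
    else:
        radius, middle = (n - 1) / 2.0, (n - 1) / 2.0
    arc = np.sqrt(np.maximum(radius**2 - (x - middle) ** 2, 0.0)) - radius
    gap = y - arc
    t = int(np.argmin(gap))
    return arc + gap[t], t


def bubblefill(
    s: Spectrum | np.ndarray,
    min_bubble_width: float = 50.0,
    smooth: bool = True,
    detrend_order: int = 4,
) -> BaselineFit:
    """BubbleFill baseline estimation.

    A low-order polynomial trend (default quartic — autofluorescence decays,
    further bent by the instrument-response correction, are strongly curved,
    and circles of bounded radius cannot follow a steep convex slope) is
    removed first and counted as part of the baseline.
    The detrended data are scaled to a square pixel aspect so circle
    geometry is meaningful, then bubbles are grown recursively: each span's
    bubble is lifted until it touches the data, the touch point splits the
    span, and spans narrower than ``min_bubble_width`` stop the recursion.
    The baseline is the upper envelope of all arcs plus the trend, lightly
    smoothed by a moving average of width ``min_bubble_width / 4``; the
    Raman component is input minus baseline, so the decomposition
    reconstructs the input exactly.
    """
    if isinstance(s, Spectrum):
        y = s.intensities
        spacing = s.spacing
    else:
        y = np.asarray(s, dtype=float)
        spacing = 1.0
    n = y.size
    if min_bubble_width <= spacing:
        raise ValueError("min_bubble_width must exceed the axis spacing")
    min_w = max(3, int(round(min_bubble_width / spacing)))
    if n < min_w:
        raise ValueError(f"spectrum of {n} points is shorter than one bubble width ({min_w})")

    # Polynomial detrend: the smooth trend belongs to the baseline. The
    # order stays far below what any Raman band could imprint on a
    # 1200 cm^-1 span.
    x = np.arange(n, dtype=float)
    line_coeffs = np.polynomial.polynomial.polyfit(x, y, detrend_order)
    trend = np.polynomial.polynomial.polyval(x, line_coeffs)
    yd = y - trend
    span_range = float(yd.max() - yd.min())
    if span_range <= 0:
        baseline = trend.copy()
    else:
        # Square aspect: full detrended range <-> n pixels.
        yn = (yd - yd.min()) / span_range * n
        envelope = np.full(n, -np.inf)
        queue: list[tuple[int, int]] = [(0, n)]
        while queue:
            start, stop = queue.pop()
            width = stop - start
            if width < min_w:
                continue
            if start == 0 and stop == n:
                alignment = "centered"
            elif start == 0:
                alignment = "left"
            elif stop == n:
                alignment = "right"
            else:
                alignment = "centered"
            bubble, t_rel = _grow_bubble(yn[start:stop], alignment)
            envelope[start:stop] = np.maximum(envelope[start:stop], bubble)
            t = start + t_rel
            if t_rel == 0:
                queue.append((start + 1, stop))
            elif t_rel == width - 1:
                queue.append((start, stop - 1))
            else:
                queue.append((start, t + 1))
                queue.append((t, stop))
        envelope = np.where(np.isfinite(envelope), envelope, yn.min())
        baseline = envelope / n * span_range + yd.min() + trend
        if smooth:
            w = max(1, min_w // 4)
            baseline = uniform_filter1d(baseline, size=w, mode="nearest")
    return BaselineFit(baseline=baseline, raman=y - baseline, min_bubble_width=min_bubble_width)


def remove_baseline(
    s: Spectrum,
    min_bubble_width: float = 50.0,
) -> tuple[Spectrum, BaselineFit]:
    """BubbleFill step as a stage transition; returns the fit for audit."""
    _require_stage(s, "calibrated", "response_corrected", "dark_subtracted", "averaged")
    fit = bubblefill(s, min_bubble_width=min_bubble_width)
    out = s.replace(intensities=fit.raman, stage="baseline_removed",
                    extra_meta={"pipeline": s.meta.get("pipeline", []) + ["baseline_removed"]})
    return out, fit


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: subtract the mean, divide by the sample (n-1) sd."""
    x = s.intensities
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    out = (x - float(np.mean(x))) / sd
    return s.replace(intensities=out, stage="snv",
                     extra_meta={"pipeline": s.meta.get("pipeline", []) + ["snv"]})


def run_pipeline(
    acq: RawAcquisition,
    standard: ReferenceStandard,
    calibration: CalibrationModel,
    config: PreprocessConfig | None = None,
) -> Spectrum:
    """Apply the six preprocessing steps in order, recording provenance."""
    config = config or PreprocessConfig()
    step = "averaging"
    try:
        s = average_accumulations(acq)
        step = "dark subtraction"
        s = subtract_dark(s, acq.darks)
        step = "instrument response correction"
        s = correct_instrument_response(
            s, standard.measured, standard.certified, floor=config.response_floor
        )
        step = "axis calibration"
        s = apply_calibration(s, calibration, spacing=config.resample_spacing)
        if config.baseline_removal:
            step = "baseline removal"
            s, _ = remove_baseline(s, min_bubble_width=config.min_bubble_width)
        step = "SNV normalization"
        s = snv(s)
    except ValueError as exc:
        raise ValueError(f"pipeline failed at {step}: {exc}") from exc
    return s
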