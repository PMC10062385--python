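"""Synthetic cohort generator.

Emulates an *ex vivo* breast Raman study: ~20 patients, ~330-390 probe
acquisitions of three tissue classes (cancer, normal, fat), each acquisition
consisting of N repeat exposures plus dark frames. Spectra are sums of
fingerprint-region vibrational bands on top of a smooth autofluorescence
baseline, with patient-level random effects, detector noise, and planted
failure modes (noise-swamped acquisitions and histology-label mismatches)
so that every downstream stage of the analysis is testable without any
measured data.

The class band profiles follow the usual biomolecular assignments: cancer
shows the strongest phenylalanine ring-breathing band at 1004 cm^-1 (pure
fat lacks it entirely), normal stroma is dominated by the collagen C-C
stretch near 940 cm^-1, and adipose tissue by the lipid acyl bands at 1129
and ~1302 cm^-1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import RawAcquisition, Spectrum, TISSUE_CLASSES, default_axis

__all__ = [
    "BandProfile",
    "CohortSpec",
    "ReferenceStandard",
    "POLYCARBONATE_PEAKS",
    "make_class_profiles",
    "render_signature",
    "generate_acquisition",
    "generate_cohort",
    "generate_reference_standard",
    "generate_polycarbonate",
]


@dataclass(frozen=True)
class BandProfile:
    """One vibrational band: centre and FWHM in cm^-1, relative amplitude per class."""

    center: float
    fwhm: float
    amplitude_by_class: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("band width must be positive")
        for cls, amp in self.amplitude_by_class.items():
            if amp < 0:
                raise ValueError(f"negative amplitude for class {cls!r} at {self.center} cm^-1")


# (center, fwhm, cancer, normal, fat); relative amplitudes follow the
# qualitative orderings of per-class band statistics in tissue Raman work:
# cancer > normal at 1004 (phenylalanine; absent in pure fat), normal > cancer
# at 940 (collagen), fat dominant at 1129 and 1302 (lipid acyl chains).
_DEFAULT_BANDS: tuple[tuple[float, float, float, float, float], ...] = (
    (760.0, 12.0, 0.45, 0.30, 0.05),   # tryptophan ring breathing
    (785.0, 12.0, 0.40, 0.25, 0.05),   # DNA/RNA base ring breathing
    (940.0, 14.0, 0.55, 0.90, 0.10),   # C-C stretch, collagen
    (1004.0, 10.0, 1.00, 0.55, 0.00),  # phenylalanine symmetric ring breathing
    (1129.0, 12.0, 0.35, 0.25, 1.00),  # lipid acyl backbone
    (1159.0, 12.0, 0.45, 0.30, 0.05),  # C-C/C-N stretch, proteins
    (1176.0, 12.0, 0.40, 0.25, 0.05),  # C-H bending, DNA/RNA bases
    (1208.0, 12.0, 0.45, 0.30, 0.10),  # ring breathing, DNA/RNA + phenylalanine
    (1246.0, 14.0, 0.55, 0.45, 0.10),  # amide III
    (1266.0, 14.0, 0.50, 0.40, 0.15),  # amide III
    (1302.0, 14.0, 0.50, 0.40, 1.20),  # CH2/CH3 twist, lipids
    (1600.0, 14.0, 0.60, 0.40, 0.10),  # C=C, phenylalanine
)

# Generic strong lipid bands beyond the discriminative registry, for visual
# realism of fat spectra only. Not part of the emulated study conditions and
# therefore off by default.
_LIPID_EXTRA_BANDS: tuple[tuple[float, float, float, float, float], ...] = (
    (1440.0, 18.0, 0.30, 0.35, 1.60),  # CH2 scissoring
    (1655.0, 20.0, 0.45, 0.40, 1.00),  # C=C stretch, unsaturated lipids
)


def make_class_profiles(include_lipid_extras: bool = False) -> list[BandProfile]:
    """Default per-class band profiles for the three tissue classes.

    Every registry band appears exactly once; all amplitudes are
    non-negative and the fat amplitude at 1004 cm^-1 is exactly zero.
    """
    rows = _DEFAULT_BANDS + (_LIPID_EXTRA_BANDS if include_lipid_extras else ())
    return [
        BandProfile(center=c, fwhm=w, amplitude_by_class={"cancer": a, "normal": b, "fat": f})
        for c, w, a, b, f in rows
    ]


def _lineshape(axis: np.ndarray, center: float, fwhm: float, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return np.exp(-4.0 * math.log(2.0) * ((axis - center) / fwhm) ** 2)
    if kind == "lorentzian":
        return 1.0 / (1.0 + (2.0 * (axis - center) / fwhm) ** 2)
    raise ValueError(f"unknown lineshape {kind!r}")


def render_signature(
    axis: np.ndarray,
    profiles: Sequence[BandProfile],
    tissue_class: str,
    band_factors: Mapping[float, float] | float | None = None,
    lineshape: str = "gaussian",
) -> np.ndarray:
    """Noise-free relative Raman signature of one tissue class.

    ``band_factors`` optionally perturbs individual band amplitudes (keyed by
    band centre) or scales them all by a scalar; used for patient- and
    measurement-level random effects.
    """
    if tissue_class not in TISSUE_CLASSES:
        raise ValueError(f"unknown tissue class {tissue_class!r}; expected one of {TISSUE_CLASSES}")
    out = np.zeros_like(np.asarray(axis, dtype=float))
    for band in profiles:
        amp = band.amplitude_by_class.get(tissue_class, 0.0)
        if isinstance(band_factors, Mapping):
            amp *= band_factors.get(band.center, 1.0)
        elif band_factors is not None:
            amp *= float(band_factors)
        if amp != 0.0:
            out += amp * _lineshape(axis, band.center, band.fwhm, lineshape)
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated protocol: 20 patients, 388 acquisitions in
    total, N=10 accumulations at 0.1-4 s exposure, and planted failures
    (58 noise-swamped acquisitions, 58 compositions matching no histology
    category, 34 label mismatches of which 28 are fat signatures carried by
    protein-labelled records) so that the clean remainder is 238 measurements
    in proportions 87 cancer : 58 normal : 93 fat.

    Counts are expressed at the detector: the acquisition protocol adjusts
    exposure to hit a target intensity, so ``raman_counts``/``baseline_scale``
    are the recorded amplitudes regardless of the drawn exposure time.
    """

    n_patients: int = 20
    measurements_per_patient: float = 19.4
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"cancer": 87 / 238, "normal": 58 / 238, "fat": 93 / 238}
    )
    n_accumulations: int = 10
    n_darks: int = 2
    exposure_range_s: tuple[float, float] = (0.1, 4.0)
    raman_counts: float = 500.0
    noise_sd: float = 50.0
    baseline_scale: float = 5000.0
    dark_counts: float = 100.0
    patient_effect_sd: float = 0.10
    measurement_effect_sd: float = 0.05
    planted_qc_failures: int = 58
    planted_no_category: int = 58
    planted_label_mismatches: int = 34
    mismatch_fat_fraction: float = 28 / 34
    qc_noise_multiplier: float = 20.0
    lineshape: str = "gaussian"
    include_lipid_extras: bool = False
    axis_start: float = 600.0
    axis_stop: float = 1800.0
    axis_spacing: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_accumulations < 1 or self.n_darks < 1:
            raise ValueError("n_patients, n_accumulations, and n_darks must be >= 1")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_mixture.values()):
            raise ValueError("class mixture proportions must be non-negative")
        lo, hi = self.exposure_range_s
        if not (0.1 - 1e-12 <= lo <= hi <= 4.0 + 1e-12):
            raise ValueError("exposure range must lie within [0.1, 4] s")
        n_planted = self.planted_qc_failures + self.planted_no_category + self.planted_label_mismatches
        if min(self.planted_qc_failures, self.planted_no_category, self.planted_label_mismatches) < 0:
            raise ValueError("planted counts must be non-negative")
        if n_planted > self.total_measurements:
            raise ValueError(
                f"{n_planted} planted failures exceed {self.total_measurements} measurements"
            )
        if not 0.0 <= self.mismatch_fat_fraction <= 1.0:
            raise ValueError("mismatch_fat_fraction must be in [0, 1]")

    @property
    def total_measurements(self) -> int:
        return int(round(self.n_patients * self.measurements_per_patient))

    @property
    def n_clean(self) -> int:
        return self.total_measurements - (
            self.planted_qc_failures + self.planted_no_category + self.planted_label_mismatches
        )

    def axis(self) -> np.ndarray:
        return default_axis(self.axis_start, self.axis_stop, self.axis_spacing)


def _smooth_baseline(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Relative autofluorescence shape: broad exponential decay + low-order polynomial."""
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    tau = rng.uniform(0.25, 0.45)  # decay constant as a fraction of the span
    decay = rng.uniform(0.5, 1.0) * np.exp(-u / tau)
    poly = rng.uniform(0.3, 0.6) + rng.uniform(-0.15, 0.15) * u + rng.uniform(-0.1, 0.25) * u**2
    shape = decay + poly
    return np.maximum(shape, 0.05)


def generate_acquisition(
    profiles: Sequence[BandProfile],
    tissue_class: str,
    patient_effect: Mapping[float, float] | float | None,
    spec: CohortSpec,
    seed: int,
    *,
    exposure_s: float | None = None,
    quality_fail: bool = False,
    meta: Mapping[str, object] | None = None,
) -> RawAcquisition:
    """One probe acquisition: N repeat spectra plus dark frames.

    Each repeat is (band sum x patient effect + smooth baseline) x exposure
    + dark offset + independent per-repeat Gaussian noise, with the photon
    rate auto-gained so the product with exposure equals the configured
    detector counts. ``quality_fail`` plants a noise-swamped acquisition
    (no Raman signal, inflated noise) destined to fail the quality gate.
    """
    if tissue_class not in TISSUE_CLASSES:
        raise ValueError(f"unknown tissue class {tissue_class!r}; expected one of {TISSUE_CLASSES}")
    rng = np.random.default_rng(seed)
    axis = spec.axis()
    if exposure_s is None:
        exposure_s = float(rng.uniform(*spec.exposure_range_s))

    # Per-measurement band jitter on top of the patient-level effect.
    factors: dict[float, float] = {}
    for band in profiles:
        f = 1.0
        if isinstance(patient_effect, Mapping):
            f *= patient_effect.get(band.center, 1.0)
        elif patient_effect is not None:
            f *= float(patient_effect)
        if spec.measurement_effect_sd > 0:
            f *= max(0.0, 1.0 + rng.normal(0.0, spec.measurement_effect_sd))
        factors[band.center] = f

    signature = render_signature(axis, profiles, tissue_class, factors, spec.lineshape)
    baseline = spec.baseline_scale * _smooth_baseline(axis, rng)

    signal_amp = 0.0 if quality_fail else spec.raman_counts
    noise_sd = spec.noise_sd * (spec.qc_noise_multiplier if quality_fail else 1.0)

    # Auto-gain: rate * exposure == target counts at the detector.
    rate = (signal_amp * signature + baseline) / exposure_s
    clean = rate * exposure_s + spec.dark_counts
    repeats = clean[None, :] + rng.normal(0.0, noise_sd, size=(spec.n_accumulations, axis.size)) if noise_sd > 0 else np.tile(clean, (spec.n_accumulations, 1))
    darks = spec.dark_counts + (
        rng.normal(0.0, spec.noise_sd, size=(spec.n_darks, axis.size)) if spec.noise_sd > 0 else np.zeros((spec.n_darks, axis.size))
    )

    md = {"tissue_class": tissue_class, "quality_fail": bool(quality_fail)}
    if meta:
        md.update(meta)
    return RawAcquisition(
        wavenumbers=axis,
        repeats=repeats,
        darks=darks,
        exposure_s=exposure_s,
        meta=md,
    )


def _class_counts(mixture: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n measurements over the mixture."""
    raw = {c: mixture.get(c, 0.0) * n for c in TISSUE_CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    rem = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    return counts


def _draw_composition(rng: np.random.Generator, label: str) -> tuple[float, float, float]:
    """Cell-composition percentages meeting exactly the given label's threshold.

    Thresholds: cancer >= 80%, normal >= 80%, fat >= 70%. With percentages
    summing to 100 the remaining classes necessarily stay below their own
    thresholds, so exactly one rule fires.
    """
    if label == "cancer":
        p = rng.uniform(80.0, 100.0)
        u = rng.uniform()
        return p, (100.0 - p) * u, (100.0 - p) * (1.0 - u)
    if label == "normal":
        p = rng.uniform(80.0, 100.0)
        u = rng.uniform()
        return (100.0 - p) * u, p, (100.0 - p) * (1.0 - u)
    if label == "fat":
        p = rng.uniform(70.0, 100.0)
        u = rng.uniform()
        return (100.0 - p) * u, (100.0 - p) * (1.0 - u), p
    if label == "none":
        # No threshold met: every class strictly below its own cut-off.
        while True:
            c = rng.uniform(5.0, 79.0)
            n = rng.uniform(5.0, min(79.0, 95.0 - c))
            f = 100.0 - c - n
            if 0.0 <= f < 70.0:
                return c, n, f
    raise ValueError(f"unknown composition label {label!r}")


def generate_cohort(
    spec: CohortSpec,
    profiles: Sequence[BandProfile] | None = None,
) -> tuple[list[RawAcquisition], pd.DataFrame]:
    """Full synthetic cohort: acquisitions plus a measurement manifest.

    The manifest carries the columns a real study would provide (patient and
    sample identifiers, grid position, exposure, cell-composition
    percentages) plus ground-truth columns (``spectral_class``,
    ``planted_quality_failure``, ``planted_mismatch``) that only a simulator
    can know; downstream code never reads the truth columns.
    """
    if profiles is None:
        profiles = make_class_profiles(spec.include_lipid_extras)
    rng = np.random.default_rng(spec.seed)
    total = spec.total_measurements

    # Patient-level random effects: one multiplicative factor per band.
    patient_ids = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    patient_factors = {
        pid: {
            band.center: max(0.05, 1.0 + rng.normal(0.0, spec.patient_effect_sd))
            for band in profiles
        }
        for pid in patient_ids
    }

    # Near-even patient allocation.
    base, extra = divmod(total, spec.n_patients)
    alloc = np.array([base + (1 if i < extra else 0) for i in range(spec.n_patients)])
    slot_patients = np.repeat(np.arange(spec.n_patients), alloc)
    rng.shuffle(slot_patients)

    # Roles: clean measurements plus the three planted failure modes.
    roles = (
        ["clean"] * spec.n_clean
        + ["qc"] * spec.planted_qc_failures
        + ["nocat"] * spec.planted_no_category
        + ["mismatch"] * spec.planted_label_mismatches
    )
    rng.shuffle(roles)

    clean_counts = _class_counts(spec.class_mixture, spec.n_clean)
    clean_classes = sum(([c] * n for c, n in clean_counts.items()), [])
    rng.shuffle(clean_classes)
    clean_iter = iter(clean_classes)

    n_fat_sig = int(round(spec.planted_label_mismatches * spec.mismatch_fat_fraction))
    mismatch_kinds = ["fat_signature"] * n_fat_sig + ["protein_signature"] * (
        spec.planted_label_mismatches - n_fat_sig
    )
    rng.shuffle(mismatch_kinds)
    mismatch_iter = iter(mismatch_kinds)

    # Non-fat mixture for drawing the composition class of fat-signature mismatches.
    cn_weights = np.array([spec.class_mixture.get("cancer", 0.5), spec.class_mixture.get("normal", 0.5)])
    cn_weights = cn_weights / cn_weights.sum() if cn_weights.sum() > 0 else np.array([0.5, 0.5])
    mixture_classes = list(TISSUE_CLASSES)
    mixture_weights = np.array([spec.class_mixture.get(c, 0.0) for c in mixture_classes])
    mixture_weights = mixture_weights / mixture_weights.sum()

    acquisitions: list[RawAcquisition] = []
    rows: list[dict[str, object]] = []
    for i, role in enumerate(roles):
        pid = patient_ids[slot_patients[i]]
        mid = f"M{i + 1:03d}"
        exposure = float(rng.uniform(*spec.exposure_range_s))
        quality_fail = False
        if role == "clean":
            spectral = composition = next(clean_iter)
        elif role == "qc":
            # Composition is valid; the spectrum itself is noise-swamped.
            spectral = composition = str(rng.choice(mixture_classes, p=mixture_weights))
            quality_fail = True
        elif role == "nocat":
            spectral = str(rng.choice(mixture_classes, p=mixture_weights))
            composition = "none"
        else:  # mismatch: spectral class contradicts the composition-derived label
            kind = next(mismatch_iter)
            if kind == "fat_signature":
                spectral = "fat"
                composition = str(rng.choice(["cancer", "normal"], p=cn_weights))
            else:
                spectral = str(rng.choice(["cancer", "normal"], p=cn_weights))
                composition = "fat"
        pct_c, pct_n, pct_f = _draw_composition(rng, composition)
        acq_seed = int(rng.integers(0, 2**31 - 1))
        acq = generate_acquisition(
            profiles,
            spectral,
            patient_factors[pid],
            spec,
            acq_seed,
            exposure_s=exposure,
            quality_fail=quality_fail,
            meta={"measurement_id": mid, "patient_id": pid},
        )
        acquisitions.append(acq)
        rows.append(
            {
                "measurement_id": mid,
                "patient_id": pid,
                "sample_id": f"{pid}-S{1 + i % 2}",
                "pos_x_mm": round(float(rng.uniform(0, 40)), 1),
                "pos_y_mm": round(float(rng.uniform(0, 40)), 1),
                "circle_diameter_mm": 3.0,
                "exposure_s": round(exposure, 3),
                "pct_cancer": round(pct_c, 2),
                "pct_normal": round(pct_n, 2),
                "pct_fat": round(pct_f, 2),
                "spectral_class": spectral,
                "planted_quality_failure": quality_fail,
                "planted_mismatch": role == "mismatch",
            }
        )
    manifest = pd.DataFrame(rows)
    return acquisitions, manifest


def generate_planted_features(
    planted_centers: Sequence[float],
    seed: int,
    positive_class: str = "cancer",
    negative_class: str = "normal",
    n_patients: int = 28,
    measurements_per_patient: int = 10,
    patient_effect_sd: float = 0.10,
    measurement_effect_sd: float = 0.05,
    noise_sd: float = 0.15,
    intensity_scale: float = 500.0 / 75.0,
    profiles: Sequence[BandProfile] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Band-level features where the class difference is confined to planted bands.

    Emulates the band-intensity features of two unimodal tissue classes on
    an SNV-like scale: at every planted band the classes keep their own
    registry amplitudes, everywhere else both classes sit at the midpoint,
    so only the planted bands carry a systematic difference. Patient- and
    measurement-level multiplicative effects plus additive noise provide
    the variance structure of real cohorts. Returns (features, binary
    labels, patient groups); used by the selection-recovery tests.
    """
    if profiles is None:
        profiles = make_class_profiles()
    planted = set(float(c) for c in planted_centers)
    rng = np.random.default_rng(seed)
    names = [f"{b.center:g}" for b in profiles]
    rows: list[list[float]] = []
    labels: list[int] = []
    groups: list[str] = []
    for p in range(n_patients):
        is_pos = p % 2 == 0
        pe = rng.normal(0.0, patient_effect_sd, len(profiles))
        for _ in range(measurements_per_patient):
            me = rng.normal(0.0, measurement_effect_sd, len(profiles))
            feat = []
            for j, band in enumerate(profiles):
                a_pos = band.amplitude_by_class.get(positive_class, 0.0)
                a_neg = band.amplitude_by_class.get(negative_class, 0.0)
                if band.center in planted:
                    amp = a_pos if is_pos else a_neg
                else:
                    amp = 0.5 * (a_pos + a_neg)
                feat.append(amp * intensity_scale * (1.0 + pe[j] + me[j]) + rng.normal(0.0, noise_sd))
            rows.append(feat)
            labels.append(int(is_pos))
            groups.append(f"P{p + 1:02d}")
    return pd.DataFrame(rows, columns=names), np.array(labels), np.array(groups)


@dataclass(eq=False)
class ReferenceStandard:
    """Measured luminescence standard plus its certified relative-intensity curve.

    ``response`` is the hidden instrument transfer function the correction
    step is supposed to recover; it is exposed so oracle tests can compare
    against ground truth.
    """

    measured: Spectrum
    certified: np.ndarray
    response: np.ndarray


def generate_reference_standard(
    axis: np.ndarray,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> ReferenceStandard:
    """NIST-style intensity standard (certified smooth curve x hidden response)."""
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    certified = 0.3 + np.exp(-(((axis - 1000.0) / 500.0) ** 2))
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    response = 0.75 + 0.3 * np.exp(-(((axis - 850.0) / 250.0) ** 2)) + 0.15 * u
    measured_values = certified * response
    if noise_sd > 0:
        measured_values = measured_values * (1.0 + rng.normal(0.0, noise_sd, size=axis.size))
    measured = Spectrum(axis, measured_values, stage="raw", meta={"kind": "reference_standard"})
    return ReferenceStandard(measured=measured, certified=certified, response=response)


#: Reference polycarbonate peak positions (cm^-1) used for axis calibration.
POLYCARBONATE_PEAKS: tuple[float, ...] = (635.0, 705.0, 888.0, 1113.0, 1178.0, 1235.0, 1603.0)

_POLYCARBONATE_AMPLITUDES: tuple[float, ...] = (0.70, 0.55, 0.80, 0.60, 0.75, 0.65, 1.00)


def generate_polycarbonate(
    axis: np.ndarray,
    true_shift: float = 0.0,
    seed: int = 0,
    *,
    scale: float = 1.0,
    fwhm: float = 9.0,
    noise_sd: float = 0.003,
) -> Spectrum:
    """Polycarbonate calibration spectrum with peaks displaced by a known map.

    Peaks are rendered at ``scale * p + true_shift`` for every reference
    position ``p`` in :data:`POLYCARBONATE_PEAKS`, so calibration-recovery
    tests know the planted transform exactly.
    """
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    y = np.full(axis.size, 0.05)
    for p, a in zip(POLYCARBONATE_PEAKS, _POLYCARBONATE_AMPLITUDES):
        y += a * np.exp(-4.0 * math.log(2.0) * ((axis - (scale * p + true_shift)) / fwhm) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=axis.size)
    return Spectrum(axis, y, stage="raw", meta={"kind": "polycarbonate", "true_shift": true_shift, "scale": scale})
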