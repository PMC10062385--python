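"""Histology labeling, the fat-consistency screen, and the exclusion ledger.

Measurements are labeled from cell-composition percentages inside the 3-mm
registration circle: cancer if at least 80% tumour cells, normal if at
least 80% normal cells, fat if at least 70% adipose cells; anything else
fails to qualify for a category. Because registration between probe
positions and stained sections is imperfect, a spectrum's histology label
can contradict its measured signature; a fat-detection classifier trained
on the retained data flags such records (a fat signature carried by a
protein-tissue label, or vice versa), which are excluded as suspected
labeling errors. The ledger accounts for every measurement from the raw
count down to the final dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import train_weighted_svm
from .features import BandSet, DEFAULT_BANDS, FeatureMatrix, build_feature_matrix
from .preprocess import CalibrationModel, PreprocessConfig, run_pipeline
from .quality import quality_factor
from .spectra import RawAcquisition, Spectrum
from .synthetic import ReferenceStandard

__all__ = [
    "assign_label",
    "fat_consistency_screen",
    "ExclusionLedger",
    "DatasetBundle",
    "build_dataset",
]

_CANCER_MIN = 80.0
_NORMAL_MIN = 80.0
_FAT_MIN = 70.0


def assign_label(pct_cancer: float, pct_normal: float, pct_fat: float) -> str:
    """Histology label from composition percentages.

    Rules checked in the fixed order cancer (>= 80%), normal (>= 80%),
    fat (>= 70%); all thresholds are inclusive. Returns ``"excluded"``
    when no category qualifies.
    """
    for name, pct in (("cancer", pct_cancer), ("normal", pct_normal), ("fat", pct_fat)):
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"{name} percentage {pct} outside [0, 100]")
    if pct_cancer >= _CANCER_MIN:
        return "cancer"
    if pct_normal >= _NORMAL_MIN:
        return "normal"
    if pct_fat >= _FAT_MIN:
        return "fat"
    return "excluded"


def fat_consistency_screen(
    features: FeatureMatrix,
    labels: Sequence[str] | None = None,
    C: float = 1.0,
    gamma: float = 1.0,
) -> np.ndarray:
    """Flag records whose predicted fat status contradicts their label.

    A fat-vs-rest linear SVM is trained on the given measurements (adipose
    spectra are so distinct from protein-rich tissue that a minority of
    mislabeled records does not move the boundary) and applied back to
    them; a record is flagged when the model's call disagrees with the
    composition-derived label.
    """
    labels = np.asarray(labels if labels is not None else features.labels)
    y_fat = (labels == "fat").astype(int)
    if np.unique(y_fat).size < 2:
        raise ValueError("fat screen needs both fat and non-fat measurements to train")
    model = train_weighted_svm(features.values, y_fat, C=C, gamma=gamma)
    predicted_fat = model.posterior(features.values.to_numpy()) >= 0.5
    return predicted_fat != (y_fat == 1)


@dataclass(eq=False)
class ExclusionLedger:
    """Accounting from the raw measurement count to the final dataset."""

    initial: int
    excluded_low_quality: int
    excluded_no_category: int
    excluded_signature_mismatch: int
    final: int
    final_class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        excluded = (
            self.excluded_low_quality + self.excluded_no_category + self.excluded_signature_mismatch
        )
        if self.initial != self.final + excluded:
            raise ValueError("ledger does not conserve measurements")
        if self.final_class_counts and sum(self.final_class_counts.values()) != self.final:
            raise ValueError("final class counts do not sum to the final dataset size")

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "excluded": {
                "low_quality": self.excluded_low_quality,
                "no_category": self.excluded_no_category,
                "signature_mismatch": self.excluded_signature_mismatch,
            },
            "final": self.final,
            "final_class_counts": dict(self.final_class_counts),
        }


@dataclass(eq=False)
class DatasetBundle:
    """Final labeled dataset: features, per-record table, spectra, and the ledger."""

    features: FeatureMatrix
    records: pd.DataFrame
    spectra: list[Spectrum]
    ledger: ExclusionLedger
    qc_table: pd.DataFrame


def build_dataset(
    acquisitions: Sequence[RawAcquisition],
    manifest: pd.DataFrame,
    standard: ReferenceStandard,
    calibration: CalibrationModel,
    pre_config: PreprocessConfig | None = None,
    qc_threshold: float = 0.6,
    bands: BandSet = DEFAULT_BANDS,
) -> DatasetBundle:
    """Pipeline -> quality gate -> labeling -> fat screen -> ledger.

    Exclusions are applied in that order (quality first, then
    no-category, then signature mismatch), each recorded per measurement in
    the returned records table and summarized in the ledger.
    """
    if len(acquisitions) != len(manifest):
        raise ValueError("manifest rows must align with acquisitions")
    pre_config = pre_config or PreprocessConfig()

    records = manifest.reset_index(drop=True).copy()
    spectra = [run_pipeline(a, standard, calibration, pre_config) for a in acquisitions]

    reports = [quality_factor(s, threshold=qc_threshold) for s in spectra]
    records["quality_factor"] = [r.qf for r in reports]
    records["qc_passed"] = [r.passed for r in reports]

    labels = [
        assign_label(row.pct_cancer, row.pct_normal, row.pct_fat)
        for row in records.itertuples()
    ]
    records["label"] = labels

    reason = np.full(len(records), "none", dtype=object)
    reason[~records["qc_passed"].to_numpy()] = "low_quality"
    no_cat = (reason == "none") & (records["label"].to_numpy() == "excluded")
    reason[no_cat] = "no_category"

    surviving = reason == "none"
    if not surviving.any():
        raise ValueError("no measurements survive the quality and category gates")
    surv_idx = np.flatnonzero(surviving)
    surv_features = build_feature_matrix(
        [spectra[i] for i in surv_idx],
        bands,
        labels=records["label"].to_numpy()[surv_idx],
        patients=records["patient_id"].to_numpy()[surv_idx],
    )
    # The fat screen needs both fat and non-fat survivors; a single-status
    # cohort (e.g. a cancer-vs-normal fixture) has nothing to screen.
    surv_labels = records["label"].to_numpy()[surv_idx]
    if np.unique(surv_labels == "fat").size == 2:
        flags = fat_consistency_screen(surv_features)
        reason[surv_idx[flags]] = "signature_mismatch"
    records["exclusion_reason"] = reason
    records.loc[records["exclusion_reason"] != "none", "label"] = "excluded"

    final_mask = reason == "none"
    final_idx = np.flatnonzero(final_mask)
    final_labels = records["label"].to_numpy()[final_idx]
    features = build_feature_matrix(
        [spectra[i] for i in final_idx],
        bands,
        labels=final_labels,
        patients=records["patient_id"].to_numpy()[final_idx],
    )

    classes, counts = np.unique(final_labels, return_counts=True)
    ledger = ExclusionLedger(
        initial=len(records),
        excluded_low_quality=int(np.sum(reason == "low_quality")),
        excluded_no_category=int(np.sum(reason == "no_category")),
        excluded_signature_mismatch=int(np.sum(reason == "signature_mismatch")),
        final=int(final_mask.sum()),
        final_class_counts={str(c): int(n) for c, n in zip(classes, counts)},
    )
    qc_table = records[["measurement_id", "quality_factor", "qc_passed", "exclusion_reason"]].copy()
    return DatasetBundle(
        features=features,
        records=records,
        spectra=[spectra[i] for i in final_idx],
        ledger=ledger,
        qc_table=qc_table,
    )
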