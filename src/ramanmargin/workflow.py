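"""End-to-end analysis orchestration.

``run_all`` ties the stages together for one configuration and seed:
generate (or load) the cohort, fit the axis calibration from the
polycarbonate reference, build the labeled dataset through preprocessing /
quality gate / labeling / fat screen, then train and evaluate each
requested model. Everything is deterministic given (config, seed).
"""
from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import pandas as pd

from .classify import ModelSpec, accumulation_study, run_model
from .cohort import DatasetBundle, build_dataset
from .io import RunConfig
from .preprocess import fit_calibration
from .spectra import RawAcquisition
from .synthetic import (
    CohortSpec,
    ReferenceStandard,
    generate_cohort,
    generate_polycarbonate,
    generate_reference_standard,
)

__all__ = ["make_references", "run_all", "RunResult"]


def make_references(spec: CohortSpec):
    """Reference standard and polycarbonate calibration spectrum for a cohort."""
    axis = spec.axis()
    standard = generate_reference_standard(axis, seed=spec.seed + 1, noise_sd=0.0)
    polycarbonate = generate_polycarbonate(axis, true_shift=0.0, seed=spec.seed + 2)
    return standard, polycarbonate


class RunResult:
    """Cohort, dataset bundle, and per-model reports of one full run."""

    def __init__(
        self,
        config: RunConfig,
        acquisitions: list[RawAcquisition],
        manifest: pd.DataFrame,
        standard: ReferenceStandard,
        calibration,
        bundle: DatasetBundle,
        reports: dict[str, dict],
    ) -> None:
        self.config = config
        self.acquisitions = acquisitions
        self.manifest = manifest
        self.standard = standard
        self.calibration = calibration
        self.bundle = bundle
        self.reports = reports

    @property
    def ledger(self):
        return self.bundle.ledger


def run_all(config: RunConfig | None = None, seed: int | None = None) -> RunResult:
    """Generate a cohort and run the complete analysis for every model id."""
    config = config or RunConfig()
    if seed is not None:
        config = replace(
            config,
            seed=seed,
            cohort=replace(config.cohort, seed=seed),
            model=replace(config.model, seed=seed),
        )
    spec = config.cohort
    acquisitions, manifest = generate_cohort(spec)
    standard, polycarbonate = make_references(spec)
    calibration = fit_calibration(polycarbonate, degree=config.preprocess.calibration_degree)
    bundle = build_dataset(
        acquisitions,
        manifest,
        standard,
        calibration,
        pre_config=config.preprocess,
        qc_threshold=config.qc_threshold,
    )
    reports = {
        model_id: run_model(bundle.features, model_id, spec=config.model)
        for model_id in config.model_ids
    }
    return RunResult(config, acquisitions, manifest, standard, calibration, bundle, reports)


def run_accumulation_study(
    config: RunConfig | None = None,
    seed: int | None = None,
    n_list: Sequence[int] = (10, 5, 1),
    model_ids: Sequence[str] = ("B",),
) -> dict[int, dict[str, dict]]:
    """Reduced-accumulation re-analysis under one configuration."""
    config = config or RunConfig()
    if seed is not None:
        config = replace(
            config,
            seed=seed,
            cohort=replace(config.cohort, seed=seed),
            model=replace(config.model, seed=seed),
        )
    spec = config.cohort
    acquisitions, manifest = generate_cohort(spec)
    standard, polycarbonate = make_references(spec)
    calibration = fit_calibration(polycarbonate, degree=config.preprocess.calibration_degree)
    return accumulation_study(
        acquisitions,
        manifest,
        standard,
        calibration,
        pre_config=config.preprocess,
        n_list=n_list,
        model_ids=model_ids,
        qc_threshold=config.qc_threshold,
        model_spec=config.model,
    )
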