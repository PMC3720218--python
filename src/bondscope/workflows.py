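"""End-to-end experiment shapes.

These orchestrate the library into the standard model-development
experiments: comparing descriptor selections under a shared seed,
sweeping the maximum sphere count, ablating descriptor groups one at a
time, and comparing a trained model against the fixed-value baseline per
bond type.  Reports carry provenance (seeds plus content hashes of the
catalog and the data) and are bit-reproducible given those.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import pandas as pd

from .dataset import (
    BondRecord,
    DatasetSplit,
    build_records,
    deduplicate,
    design_matrix,
)
from .descriptors import DescriptorCatalog, build_catalog
from .models import (
    EnsembleConfig,
    Metrics,
    RFConfig,
    asnn_predict,
    baseline_fixed_values,
    evaluate,
    train_ensemble,
    train_rf,
)


@dataclass
class ExperimentReport:
    name: str
    n_descriptors: int
    group_counts: dict[str, int]
    oob_metrics: Metrics | None
    test_metrics: Metrics | None = None
    per_bond_type: dict[str, Metrics] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def data_hash(records: list[BondRecord]) -> str:
    text = "\n".join(
        f"{r.mol_id}|{r.bond}|{r.element_pair}|{r.order}|{r.bde}" for r in records
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _records_for_catalog(labeled, catalog, dedup: bool):
    records = build_records(labeled, catalog)
    if dedup:
        records, _ = deduplicate(records)
    return records


def _fit_report(name, catalog, records, rf_config, importance=False):
    X, y = design_matrix(records)
    result = train_rf(X, y, rf_config, compute_importance=importance)
    report = ExperimentReport(
        name=name,
        n_descriptors=len(catalog),
        group_counts=catalog.group_counts(),
        oob_metrics=result.oob_metrics,
        provenance={
            "seed": rf_config.seed,
            "catalog_hash": catalog.content_hash(),
            "data_hash": data_hash(records),
            "n_bonds": len(records),
        },
    )
    return report, result


def run_selection_experiment(
    labeled,
    presets: list[str],
    rf_config: RFConfig | None = None,
    max_sphere: int | None = None,
    dedup: bool = True,
) -> list[ExperimentReport]:
    """One OOB-validated report per descriptor preset, same seed for all."""
    if not presets:
        raise ValueError("at least one preset is required")
    rf_config = rf_config or RFConfig()
    reports = []
    for preset in presets:
        catalog = build_catalog(preset, max_sphere=max_sphere)
        records = _records_for_catalog(labeled, catalog, dedup)
        report, _ = _fit_report(preset, catalog, records, rf_config)
        reports.append(report)
    return reports


def run_group_ablation(
    labeled,
    base_preset: str = "selection2",
    rf_config: RFConfig | None = None,
    max_sphere: int | None = None,
    dedup: bool = True,
) -> list[ExperimentReport]:
    """Retrain after removing one descriptor group at a time."""
    rf_config = rf_config or RFConfig()
    base = build_catalog(base_preset, max_sphere=max_sphere)
    reports = []
    records = _records_for_catalog(labeled, base, dedup)
    report, _ = _fit_report(base_preset, base, records, rf_config)
    reports.append(report)
    for group in sorted(base.group_counts()):
        defs = tuple(d for d in base.definitions if (d.group or d.family) != group)
        catalog = DescriptorCatalog(
            defs, preset=f"{base_preset}-minus-{group}", max_sphere=base.max_sphere
        )
        records = _records_for_catalog(labeled, catalog, dedup)
        report, _ = _fit_report(catalog.preset, catalog, records, rf_config)
        reports.append(report)
    return reports


def run_sphere_sweep(
    labeled,
    max_list: list[int],
    rf_config: RFConfig | None = None,
    preset: str = "selection3",
    dedup: bool = True,
) -> list[ExperimentReport]:
    """Reports for increasing sphere-layer counts of one preset."""
    if not max_list or min(max_list) < 1:
        raise ValueError("sphere counts must be >= 1")
    rf_config = rf_config or RFConfig()
    reports = []
    for n_spheres in max_list:
        catalog = build_catalog(preset, max_sphere=n_spheres)
        records = _records_for_catalog(labeled, catalog, dedup)
        report, _ = _fit_report(f"{preset}@{n_spheres}", catalog, records, rf_config)
        reports.append(report)
    return reports


def _per_bond_type(records, predictions) -> dict[str, Metrics]:
    groups: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        groups.setdefault("-".join(r.element_pair), []).append(idx)
    return {
        key: evaluate([predictions[i] for i in idxs], [records[i].bde for i in idxs])
        for key, idxs in sorted(groups.items())
    }


def run_baseline_comparison(
    split: DatasetSplit,
    model: str = "asnn",
    rf_config: RFConfig | None = None,
    ensemble_config: EnsembleConfig | None = None,
) -> tuple[ExperimentReport, ExperimentReport]:
    """Paired per-bond-type reports: trained model vs fixed-value baseline
    on the same test records."""
    X_train, y_train = design_matrix(split.train)
    X_test, y_test = design_matrix(split.test)
    if model == "asnn":
        fitted = train_ensemble(X_train, y_train, ensemble_config)
        predictions = asnn_predict(fitted, X_test)
        name = "asnn"
    elif model == "rf":
        fitted = train_rf(X_train, y_train, rf_config, compute_importance=False)
        predictions = fitted.predict(X_test)
        name = "rf"
    else:
        raise ValueError(f"unknown model {model!r}")
    n_desc = X_train.shape[1]
    model_report = ExperimentReport(
        name=name,
        n_descriptors=n_desc,
        group_counts={},
        oob_metrics=None,
        test_metrics=evaluate(predictions, y_test),
        per_bond_type=_per_bond_type(split.test, predictions),
        provenance={"seed": split.seed, "data_hash": data_hash(split.train)},
    )
    baseline = baseline_fixed_values(split.train)
    base_pred, fallback = baseline.predict(split.test)
    baseline_report = ExperimentReport(
        name="fixed-values",
        n_descriptors=0,
        group_counts={},
        oob_metrics=None,
        test_metrics=evaluate(base_pred, y_test),
        per_bond_type=_per_bond_type(split.test, base_pred),
        provenance={
            "seed": split.seed,
            "data_hash": data_hash(split.train),
            "n_fallback": int(fallback.sum()),
        },
    )
    return model_report, baseline_report


def report_table(reports: list[ExperimentReport]) -> pd.DataFrame:
    """Flatten reports into the familiar
    name / descriptor count / RMSD / MAD / MaxError table."""
    rows = []
    for r in reports:
        metrics = r.oob_metrics or r.test_metrics
        rows.append(
            {
                "name": r.name,
                "n_descriptors": r.n_descriptors,
                "rmsd": metrics.rmsd if metrics else None,
                "mad": metrics.mad if metrics else None,
                "max_error": metrics.max_error if metrics else None,
                "r2": metrics.r2 if metrics else None,
            }
        )
    return pd.DataFrame(rows)
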