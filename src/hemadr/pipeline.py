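"""Study orchestration: tuning grids, final reductions and all four
preservation analyses, with seeds, provenance and tabular report output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synth_cohort import CohortConfig, CohortTable, build_default_panel, sample_cohort
from .preprocess import preprocess_pipeline
from .reducers import (DependencyError, Embedding, ReducerConfig,
                       reduce_matrix, subsample_for_reduction)
from .dr_quality import METRIC_NAMES, QualityReport, kfold_quality_assessment
from .cluster_preservation import cluster_preservation_report
from .biological_preservation import (cll_divergence_test,
                                      crossvalidated_classification,
                                      diurnal_preservation, make_age_task,
                                      make_sex_task, performance_drop_test)

__all__ = ["StudyConfig", "StudyReport", "run_neighbour_grid",
           "run_component_grid", "run_full_study", "write_report"]

DEFAULT_COMPONENT_GRID = (2, 4, 6, 8, 10, 20, 30)
DEFAULT_NEIGHBOUR_GRID = (5, 15, 30, 50, 100)
DEFAULT_SAMPLE_SIZES = (5_000, 10_000, 20_000, 40_000, 80_000, 160_000)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full evaluation run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    methods: tuple[str, ...] = ("pca", "grp", "umap", "trimap", "pacmap")
    component_grid: tuple[int, ...] = DEFAULT_COMPONENT_GRID
    neighbour_grid: tuple[int, ...] = DEFAULT_NEIGHBOUR_GRID
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    final_components: int = 6
    k_neighbours_metrics: int = 50
    metric: str = "manhattan"
    folds: int = 10
    impute_regressor: str = "gbt"
    run_quality: bool = True
    run_clusters: bool = True
    run_diurnal: bool = True
    run_classification: bool = True
    run_divergence: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    quality: pd.DataFrame | None = None
    clusters: pd.DataFrame | None = None
    diurnal: pd.DataFrame | None = None
    classification: pd.DataFrame | None = None
    divergence: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)


def _quality_rows(report: QualityReport, **extra) -> list[dict]:
    rows = []
    for fold, vals in report.fold_values.iterrows():
        row = {"method": report.method, "fold": int(fold), **extra}
        row.update({m: float(vals[m]) for m in METRIC_NAMES})
        rows.append(row)
    return rows


def _reduce_or_record(X, cfg: ReducerConfig, failures: list[dict]):
    try:
        return reduce_matrix(X, cfg)
    except DependencyError as exc:
        failures.append({"method": cfg.method, "stage": "reduce",
                         "error": str(exc)})
        return None


def run_neighbour_grid(config: StudyConfig, table: CohortTable | None = None,
                       X: np.ndarray | None = None) -> StudyReport:
    """Quality metrics across (method, n_neighbours, sample_size).

    Subsamples are matched across methods at each grid point: the subsample
    index depends only on (seed, sample_size). Only neighbour-based methods
    are swept; stage errors are recorded per cell and the run continues.
    """
    X = _resolve_matrix(config, table, X)
    report = StudyReport(manifest=_manifest(config))
    rows: list[dict] = []
    neighbour_methods = [m for m in config.methods
                         if m in ("umap", "trimap", "pacmap")]
    for size in config.sample_sizes:
        if size > len(X):
            continue
        sub, idx = subsample_for_reduction(X, size, seed=config.seed)
        for n_nb in config.neighbour_grid:
            for method in neighbour_methods:
                cfg = ReducerConfig(method=method, metric=config.metric,
                                    n_components=config.final_components,
                                    n_neighbors=n_nb, n_inliers=n_nb,
                                    seed=config.seed)
                emb = _reduce_or_record(sub, cfg, report.failures)
                if emb is None:
                    continue
                q = kfold_quality_assessment(
                    sub, emb, k_neighbours=min(config.k_neighbours_metrics,
                                               size // config.folds // 2 - 1),
                    folds=config.folds, seed=config.seed, metric=config.metric)
                rows.extend(_quality_rows(q, n_neighbors=n_nb, sample_size=size,
                                          n_components=config.final_components))
    report.quality = pd.DataFrame(rows)
    return report


def run_component_grid(config: StudyConfig, table: CohortTable | None = None,
                       X: np.ndarray | None = None) -> StudyReport:
    """Quality metrics across n_components with neighbours fixed at 50."""
    X = _resolve_matrix(config, table, X)
    report = StudyReport(manifest=_manifest(config))
    rows: list[dict] = []
    for n_comp in config.component_grid:
        for method in config.methods:
            cfg = ReducerConfig(method=method, metric=config.metric,
                                n_components=n_comp, seed=config.seed)
            emb = _reduce_or_record(X, cfg, report.failures)
            if emb is None:
                continue
            q = kfold_quality_assessment(
                X, emb, k_neighbours=config.k_neighbours_metrics,
                folds=config.folds, seed=config.seed, metric=config.metric)
            rows.extend(_quality_rows(q, n_components=n_comp,
                                      n_neighbors=cfg.n_neighbors,
                                      sample_size=len(X)))
    report.quality = pd.DataFrame(rows)
    return report


def _resolve_matrix(config: StudyConfig, table, X):
    if X is not None:
        return np.asarray(X, dtype=float)
    if table is None:
        panel = build_default_panel()
        table = sample_cohort(panel, config.cohort)
        table, _, _ = preprocess_pipeline(table, panel, seed=config.seed,
                                          regressor=config.impute_regressor)
    return table.values.to_numpy(dtype=float)


def _manifest(config: StudyConfig) -> dict:
    return {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "versions": {"hemadr": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
    }


def run_full_study(config: StudyConfig) -> StudyReport:
    """Cohort -> preprocessing -> final reductions -> all analyses.

    Any stage failure is recorded in the report's failure manifest and the
    remaining stages still run.
    """
    report = StudyReport(manifest=_manifest(config))
    panel = build_default_panel()
    raw = sample_cohort(panel, config.cohort)
    table, scaler, prov = preprocess_pipeline(
        raw, panel, seed=config.seed, regressor=config.impute_regressor)
    report.manifest["preprocess"] = prov
    X = table.values.to_numpy(dtype=float)

    embeddings: dict[str, Embedding] = {}
    for method in config.methods:
        cfg = ReducerConfig(method=method, metric=config.metric,
                            n_components=config.final_components,
                            seed=config.seed)
        emb = _reduce_or_record(X, cfg, report.failures)
        if emb is not None:
            embeddings[method] = emb

    if config.run_quality:
        rows = []
        for method, emb in embeddings.items():
            q = kfold_quality_assessment(
                X, emb, k_neighbours=min(config.k_neighbours_metrics,
                                         len(X) // config.folds // 2 - 1),
                folds=config.folds, seed=config.seed, metric=config.metric)
            rows.extend(_quality_rows(q, n_components=config.final_components,
                                      sample_size=len(X)))
        report.quality = pd.DataFrame(rows)

    if config.run_clusters:
        configs = [replace(emb.config) for emb in embeddings.values()]
        try:
            cl = cluster_preservation_report(X, configs, seed=config.seed)
            report.clusters = pd.DataFrame([asdict(c) for c in cl])
        except DependencyError as exc:
            report.failures.append({"stage": "clusters", "error": str(exc)})

    if config.run_diurnal:
        rows = []
        hours = table.draw_hour
        for method, emb in embeddings.items():
            for c, fit in enumerate(diurnal_preservation(emb, hours)):
                rows.append({"method": method, "component": c,
                             "mesor": fit.mesor, "amplitude": fit.amplitude,
                             "acrophase_h": fit.acrophase_h,
                             "p_amplitude": fit.p_amplitude,
                             "significant": fit.significant})
        for col in ("neutrophil_fraction", "eosinophil_fraction"):
            fit = diurnal_preservation(
                table.values[col].to_numpy()[:, None], hours)[0]
            rows.append({"method": f"original:{col}", "component": 0,
                         "mesor": fit.mesor, "amplitude": fit.amplitude,
                         "acrophase_h": fit.acrophase_h,
                         "p_amplitude": fit.p_amplitude,
                         "significant": fit.significant})
        report.diurnal = pd.DataFrame(rows)

    if config.run_classification:
        rows = []
        for task_name, maker in (("sex_20_50", make_sex_task),
                                 ("age_young_old", make_age_task)):
            try:
                Xt, yt = maker(table)
                rep0 = crossvalidated_classification(
                    Xt, yt, folds=config.folds, seed=config.seed,
                    task=task_name, representation="original")
                rows.append(_classification_row(rep0, None))
                for method, emb in embeddings.items():
                    Xe, ye = maker(table, features=emb.coordinates)
                    repr_ = crossvalidated_classification(
                        Xe, ye, folds=config.folds, seed=config.seed,
                        task=task_name, representation=method)
                    drop = performance_drop_test(rep0, repr_)
                    rows.append(_classification_row(repr_, drop))
            except (ValueError, DependencyError) as exc:
                report.failures.append({"stage": f"classification:{task_name}",
                                        "error": str(exc)})
        report.classification = pd.DataFrame(rows)

    if config.run_divergence:
        rows = []
        flags = table.meta["cll_flag"].to_numpy()
        if flags.sum() >= 2:
            div = cll_divergence_test(table, flags)
            rows.append({"representation": "original",
                         "n_dimensions": len(div.dimensions),
                         "n_significant": div.n_significant,
                         "n_flagged": div.n_flagged})
            for method, emb in embeddings.items():
                div = cll_divergence_test(emb.coordinates, flags)
                rows.append({"representation": method,
                             "n_dimensions": len(div.dimensions),
                             "n_significant": div.n_significant,
                             "n_flagged": div.n_flagged})
            report.divergence = pd.DataFrame(rows)
        else:
            report.failures.append({"stage": "divergence",
                                    "error": "fewer than 2 flagged samples"})
    return report


def _classification_row(rep, drop) -> dict:
    row = {"task": rep.task, "representation": rep.representation,
           "validation_accuracy": rep.validation_accuracy,
           "validation_mcc": rep.validation_mcc,
           "fold_accuracy_mean": float(np.mean(rep.fold_accuracy)),
           "fold_mcc_mean": float(np.mean(rep.fold_mcc)),
           "n_train": rep.n_train, "n_validation": rep.n_validation}
    if drop is not None:
        row["drop_p_accuracy"] = drop["accuracy"][1]
        row["drop_p_mcc"] = drop["mcc"][1]
    return row


_TABLES = ("quality", "clusters", "diurnal", "classification", "divergence")


def write_report(report: StudyReport, directory) -> list[Path]:
    """Write CSV tables plus a manifest JSON; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _TABLES:
        df = getattr(report, name)
        if df is not None:
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
    manifest = dict(report.manifest)
    manifest["failures"] = report.failures
    manifest["tables"] = [p.name for p in written]
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written.append(path)
    return written
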