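"""Preprocessing of CBC tables: log transform, clipping, scaling, imputation.

The pipeline order is log -> clip -> impute -> scale. Missing values are an
explicit NaN mask throughout, never a sentinel number, and imputation never
alters observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth_cohort import CohortTable, ParameterSpec

__all__ = [
    "ClipSpec",
    "FittedScaler",
    "log_transform",
    "clip_parameters",
    "default_clip_specs",
    "zscore_fit",
    "zscore_apply",
    "chained_imputation",
    "preprocess_pipeline",
    "white_cell_count_columns",
]


@dataclass(frozen=True)
class ClipSpec:
    """Winsorisation bounds for one parameter (either side may be open)."""

    parameter: str
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ValueError(f"need low < high for {self.parameter}")


@dataclass(frozen=True)
class FittedScaler:
    """Columnwise means/SDs estimated on the fitting data (NaNs ignored)."""

    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray


def white_cell_count_columns(panel: list[ParameterSpec]) -> list[str]:
    """The columns the log transform targets: log-normal white-cell counts."""
    return [s.name for s in panel if s.lineage == "white-cell" and s.lognormal]


def log_transform(table: CohortTable, columns: list[str]) -> CohortTable:
    """Replace the listed columns by their natural log.

    Missing entries stay missing. A non-positive observed value is a domain
    error: the transform exists to tame right-skewed count distributions and
    a zero count must be handled upstream (e.g. by a detection-limit shift).
    """
    out = table.copy()
    for col in columns:
        if col not in out.values.columns:
            raise KeyError(f"unknown column {col!r}")
        x = out.values[col].to_numpy(dtype=float)
        bad = np.where(~np.isnan(x) & (x <= 0))[0]
        if bad.size:
            raise ValueError(
                f"non-positive value in column {col!r} at row {int(bad[0])}; "
                "log transform requires strictly positive observations")
        out.values[col] = np.log(x)
    return out


def default_clip_specs(table: CohortTable, q_low: float = 0.001,
                       q_high: float = 0.999) -> list[ClipSpec]:
    """Empirical-quantile clip bounds (0.1%/99.9% by default) per parameter."""
    lo = table.values.quantile(q_low)
    hi = table.values.quantile(q_high)
    return [ClipSpec(c, float(lo[c]), float(hi[c])) for c in table.values.columns]


def clip_parameters(table: CohortTable, clips: list[ClipSpec],
                    log=None) -> CohortTable:
    """Winsorise observed values into each spec's [low, high].

    ``log`` is an optional callable receiving a message with the number of
    clipped cells per parameter.
    """
    out = table.copy()
    for spec in clips:
        if spec.parameter not in out.values.columns:
            raise KeyError(f"clip spec references unknown parameter {spec.parameter!r}")
        x = out.values[spec.parameter]
        clipped = x.clip(lower=spec.low, upper=spec.high)
        n_changed = int(((clipped != x) & x.notna()).sum())
        if log is not None and n_changed:
            log(f"clipped {n_changed} cells in {spec.parameter}")
        out.values[spec.parameter] = clipped
    return out


def zscore_fit(table: CohortTable) -> FittedScaler:
    """Columnwise mean/SD ignoring missing entries; zero variance is an error."""
    means = table.values.mean(axis=0, skipna=True)
    sds = table.values.std(axis=0, ddof=0, skipna=True)
    counts = table.values.notna().sum(axis=0)
    for col in table.values.columns:
        if counts[col] < 2 or not np.isfinite(sds[col]) or sds[col] == 0:
            raise ValueError(f"column {col!r} has zero variance or < 2 observed values")
    return FittedScaler(tuple(table.values.columns),
                        means.to_numpy(dtype=float), sds.to_numpy(dtype=float))


def zscore_apply(table: CohortTable, scaler: FittedScaler) -> CohortTable:
    if tuple(table.values.columns) != scaler.columns:
        raise ValueError("scaler columns do not match table columns")
    out = table.copy()
    out.values = (table.values - scaler.means) / scaler.sds
    return out


def chained_imputation(table: CohortTable, n_iterations: int = 5,
                       seed: int = 0, regressor: str = "gbt") -> CohortTable:
    """Single-dataset chained-equation imputation (MICE-style, m=1).

    Each incomplete column is iteratively regressed on all others, starting
    from a columnwise-median fill, for ``n_iterations`` rounds. The
    per-column regressor is pluggable: ``"gbt"`` (gradient-boosted trees,
    default, mirroring a boosted-tree MICE) or ``"ridge"`` (fast linear
    fallback). Deterministic given ``seed``; observed cells are never
    altered. Backed by scikit-learn's IterativeImputer.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    missing_per_col = table.values.isna().sum()
    all_missing = [c for c in table.values.columns
                   if missing_per_col[c] == len(table)]
    if all_missing:
        raise ValueError(f"column(s) entirely missing: {all_missing}")
    if missing_per_col.sum() == 0:
        return table.copy()

    if regressor == "gbt":
        from sklearn.ensemble import HistGradientBoostingRegressor
        est = HistGradientBoostingRegressor(max_iter=60, max_depth=4,
                                            random_state=seed)
    elif regressor == "ridge":
        from sklearn.linear_model import Ridge
        est = Ridge(alpha=1e-3)
    else:
        raise ValueError(f"unknown regressor {regressor!r}")

    imp = IterativeImputer(estimator=est, max_iter=n_iterations,
                           initial_strategy="median", random_state=seed,
                           sample_posterior=False, tol=0.0)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        # tol=0 deliberately runs all n_iterations rounds; the stopping
        # criterion is then never "reached" and sklearn warns about it
        warnings.simplefilter("ignore", ConvergenceWarning)
        completed = imp.fit_transform(table.values.to_numpy(dtype=float))
    out = table.copy()
    filled = pd.DataFrame(completed, columns=table.values.columns,
                          index=table.values.index)
    # keep observed cells bit-identical
    out.values = table.values.where(table.values.notna(), filled)
    return out


def preprocess_pipeline(table: CohortTable, panel: list[ParameterSpec],
                        clips: list[ClipSpec] | None = None,
                        impute_iterations: int = 5, seed: int = 0,
                        regressor: str = "gbt",
                        log=None) -> tuple[CohortTable, FittedScaler, dict]:
    """Full preprocessing: log -> clip -> impute -> scale.

    Returns the scaled table, the fitted scaler and a provenance dict
    recording the stage order and settings.
    """
    logged = white_cell_count_columns(panel)
    t = log_transform(table, logged)
    if clips is None:
        clips = default_clip_specs(t)
    t = clip_parameters(t, clips, log=log)
    if t.values.isna().any().any():
        t = chained_imputation(t, n_iterations=impute_iterations, seed=seed,
                               regressor=regressor)
    scaler = zscore_fit(t)
    t = zscore_apply(t, scaler)
    provenance = {
        "order": ["log", "clip", "impute", "scale"],
        "log_columns": logged,
        "n_clip_specs": len(clips),
        "impute_iterations": impute_iterations,
        "impute_regressor": regressor,
        "seed": seed,
    }
    return t, scaler, provenance
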