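"""Biological-preservation assessments of reduced haematology data.

Three angles complement the cluster analysis:

* diurnal rhythm — cosinor (cosine) regression per signal, with a
  zero-amplitude F-test; granulocyte fractions carry the clearest 24 h
  rhythm and any faithful embedding should retain it;
* demographics — gradient-boosted classification of sex (ages 20-50, where
  the haemoglobin difference between the sexes is clearest) and of young
  (< 20) vs old (> 60) patients, scored by accuracy and Matthews correlation
  with a 10-fold CV plus dedicated validation split and a t-test on the
  performance change after reduction;
* divergent populations — per-dimension Welch t-tests comparing a CLL-like
  subpopulation (very high lymphocyte counts) against everyone else, with
  significance at p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reducers import DependencyError, Embedding
from .synth_cohort import CohortTable

__all__ = [
    "CosinorFit",
    "ConfusionMatrix",
    "ClassificationReport",
    "DivergenceReport",
    "cosinor_fit",
    "hourly_profile",
    "diurnal_preservation",
    "make_sex_task",
    "make_age_task",
    "accuracy",
    "mcc",
    "crossvalidated_classification",
    "performance_drop_test",
    "cll_divergence_test",
]


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares cosine fit of one signal at a fixed period."""

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    p_amplitude: float
    residual_sd: float

    @property
    def significant(self) -> bool:
        return self.p_amplitude < 0.05


def cosinor_fit(times_h: np.ndarray, values: np.ndarray,
                period_h: float = 24.0) -> CosinorFit:
    """Fit value = M + A*cos(2*pi*(t - phi)/P) by linearised least squares.

    The model is linear in (M, beta_c, beta_s) with A = sqrt(beta_c^2 +
    beta_s^2) and acrophase phi from atan2. ``p_amplitude`` is the 2-df
    F-test of the harmonic terms against the intercept-only model — the
    probability of observing this amplitude if the true amplitude is zero.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must align")
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct time points")
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    n = len(y)
    df_resid = n - 3
    if df_resid <= 0:
        raise ValueError("need more observations than parameters")
    if rss1 <= 0:  # perfect fit: amplitude either exactly zero or exact
        p = 1.0 if rss0 <= 0 else 0.0
    else:
        f = ((rss0 - rss1) / 2.0) / (rss1 / df_resid)
        p = float(stats.f.sf(f, 2, df_resid))
    amplitude = float(np.hypot(beta[1], beta[2]))
    acrophase = float((np.arctan2(beta[2], beta[1]) / w) % period_h)
    return CosinorFit(float(beta[0]), amplitude, acrophase, period_h, p,
                      float(np.sqrt(rss1 / max(df_resid, 1))))


def hourly_profile(values: np.ndarray, times_h: np.ndarray,
                   n_samples: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Mean and SE of a signal per hour-of-day bin (0-23) on a seeded
    subsample; empty bins are reported as NaN."""
    values = np.asarray(values, dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    n = len(values)
    if n_samples < n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=n_samples, replace=False)
        values, times_h = values[idx], times_h[idx]
    hour = np.floor(times_h).astype(int) % 24
    rows = []
    for h in range(24):
        v = values[hour == h]
        rows.append({
            "hour": h,
            "n": len(v),
            "mean": float(v.mean()) if len(v) else np.nan,
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def diurnal_preservation(embedding: Embedding | np.ndarray,
                         times_h: np.ndarray,
                         period_h: float = 24.0) -> list[CosinorFit]:
    """Cosinor fit per embedding component; a preserved rhythm shows up as a
    significant (p < 0.05) amplitude in at least one component."""
    coords = embedding.coordinates if isinstance(embedding, Embedding) \
        else np.asarray(embedding, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if len(coords) != len(times_h):
        raise ValueError("embedding rows must align with timestamps")
    return [cosinor_fit(times_h, coords[:, c], period_h)
            for c in range(coords.shape[1])]


# ---------------------------------------------------------------------------
# demographic classification


def make_sex_task(table: CohortTable,
                  features: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sex prediction restricted to ages [20, 50]; labels 1 = male."""
    age = table.meta["age_years"].to_numpy()
    keep = (age >= 20.0) & (age <= 50.0)
    X = table.values.to_numpy(dtype=float) if features is None \
        else np.asarray(features, dtype=float)
    y = (table.meta["sex"].to_numpy() == "male").astype(int)
    X, y = X[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("a class is absent after age filtering")
    return X, y


def make_age_task(table: CohortTable,
                  features: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Young (< 20) vs old (> 60) prediction; the 20-60 band is dropped.
    Labels 1 = old."""
    age = table.meta["age_years"].to_numpy()
    keep = (age < 20.0) | (age > 60.0)
    X = table.values.to_numpy(dtype=float) if features is None \
        else np.asarray(features, dtype=float)
    y = (age > 60.0).astype(int)
    X, y = X[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("a class is absent after age filtering")
    return X, y


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    denom = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
             * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom)


@dataclass
class ClassificationReport:
    task: str
    representation: str
    fold_accuracy: np.ndarray
    fold_mcc: np.ndarray
    validation_accuracy: float
    validation_mcc: float
    n_train: int
    n_validation: int


def _default_classifier(seed: int):
    try:
        from xgboost import XGBClassifier
    except ImportError as exc:
        raise DependencyError("gradient-boosting backend (xgboost) missing") from exc
    return XGBClassifier(n_estimators=100, max_depth=4, learning_rate=0.2,
                         n_jobs=1, random_state=seed, verbosity=0,
                         tree_method="hist")


def crossvalidated_classification(features: np.ndarray, labels: np.ndarray,
                                  n_train: int = 170_000,
                                  n_validation: int = 30_000,
                                  folds: int = 10, seed: int = 0,
                                  classifier_factory=None,
                                  task: str = "", representation: str = ""
                                  ) -> ClassificationReport:
    """Stratified k-fold CV plus a dedicated validation split.

    A seeded disjoint train/validation split (caps scaled down at a 17:3
    ratio when the data are smaller); inner fold metrics come from
    stratified folds of the training pool, validation metrics from a model
    trained on the whole pool. The classifier is an adapter — default
    gradient-boosted trees — anything with fit/predict works.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    if n < n_train + n_validation:
        scale = n / (n_train + n_validation)
        n_train = max(folds * 2, int(n_train * scale))
        n_validation = n - n_train
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx, val_idx = perm[:n_train], perm[n_train:n_train + n_validation]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]
    factory = classifier_factory or _default_classifier

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc, fold_mcc = [], []
    for tr, te in skf.split(Xtr, ytr):
        clf = factory(seed)
        clf.fit(Xtr[tr], ytr[tr])
        cm = ConfusionMatrix.from_labels(ytr[te], clf.predict(Xtr[te]))
        fold_acc.append(accuracy(cm))
        fold_mcc.append(mcc(cm))
    clf = factory(seed)
    clf.fit(Xtr, ytr)
    cm_val = ConfusionMatrix.from_labels(yval, clf.predict(Xval))
    return ClassificationReport(task, representation,
                                np.array(fold_acc), np.array(fold_mcc),
                                accuracy(cm_val), mcc(cm_val),
                                n_train, len(yval))


def performance_drop_test(report_original: ClassificationReport,
                          report_reduced: ClassificationReport
                          ) -> dict[str, tuple[float, float]]:
    """Welch t-test on fold accuracy and fold MCC between representations."""
    out = {}
    for name in ("accuracy", "mcc"):
        a = report_original.fold_mcc if name == "mcc" else report_original.fold_accuracy
        b = report_reduced.fold_mcc if name == "mcc" else report_reduced.fold_accuracy
        if len(a) != len(b):
            raise ValueError("fold counts differ")
        if len(a) < 2:
            raise ValueError("need at least 2 folds")
        if np.array_equal(a, b):
            out[name] = (0.0, 1.0)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out[name] = (float(t), float(p))
    return out


# ---------------------------------------------------------------------------
# divergent-population (CLL-like) detection


@dataclass
class DivergenceReport:
    """Per-dimension Welch t-tests of a flagged vs unflagged population."""

    dimensions: list[str]
    t_statistics: np.ndarray
    p_values: np.ndarray
    n_flagged: int
    n_unflagged: int
    alpha: float = 0.001
    group_summary: pd.DataFrame | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def cll_divergence_test(data: np.ndarray | pd.DataFrame | CohortTable,
                        cll_flags: np.ndarray,
                        alpha: float = 0.001) -> DivergenceReport:
    """Unpaired Welch t-test per dimension, flagged vs unflagged samples.

    Also reports medians and IQRs per group per dimension. Significance at
    p < ``alpha`` (0.001 by default).
    """
    if isinstance(data, CohortTable):
        X = data.values.to_numpy(dtype=float)
        names = list(data.values.columns)
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
        names = list(data.columns)
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"dim_{i}" for i in range(X.shape[1])]
    flags = np.asarray(cll_flags, dtype=bool)
    if len(flags) != len(X):
        raise ValueError("flags must align with samples")
    a, b = X[flags], X[~flags]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    q = [25, 50, 75]
    qa, qb = np.percentile(a, q, axis=0), np.percentile(b, q, axis=0)
    summary = pd.DataFrame({
        "dimension": names,
        "flagged_median": qa[1], "flagged_iqr_low": qa[0], "flagged_iqr_high": qa[2],
        "unflagged_median": qb[1], "unflagged_iqr_low": qb[0],
        "unflagged_iqr_high": qb[2],
    })
    return DivergenceReport(names, np.asarray(t, dtype=float),
                            np.asarray(p, dtype=float), len(a), len(b),
                            alpha, summary)
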