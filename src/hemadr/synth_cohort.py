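"""Synthetic complete-blood-count (CBC) cohort generator.

Real routine haemocytometer data cannot be shared, so this module generates
cohorts that carry every statistical structure the downstream evaluation
assumes: ~70 correlated continuous cell characteristics, log-normally
distributed white-cell counts, diurnal periodicity in granulocyte fractions,
a sex effect on a haemoglobin-like parameter within the fertile age window,
age trends, a CLL-like subpopulation with very high lymphocyte counts, and
missing-at-random reticulocyte-mode parameters tied to the pre-2013
laboratory protocol era.

The generative model is a per-lineage latent-factor model: on a latent scale
(log scale for log-normal parameters)

    y = mu + sigma * (sum_f w_f * z_f + eps)            z_f, eps ~ N(0, 1)

where each latent factor ``z_f`` splits into a patient-level and a
sample-level component so repeated draws from one patient are correlated.
Diurnal, sex and age terms are added on the same latent scale; log-normal
parameters are exponentiated last, which keeps them strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpec",
    "CohortConfig",
    "CohortTable",
    "LINEAGES",
    "build_default_panel",
    "sample_cohort",
    "inject_cll",
    "inject_missingness",
]

LINEAGES = ("red-cell", "white-cell", "platelet", "reticulocyte-mode")

#: share of each latent factor that is patient-level (repeated samples from
#: one patient share it); the remainder is sample-level.
_PATIENT_FACTOR_SHARE = 0.5


@dataclass(frozen=True)
class ParameterSpec:
    """Marginal and structural description of one blood-cell parameter."""

    name: str
    lineage: str
    baseline_mean: float
    baseline_sd: float
    lognormal: bool = False
    factor_loadings: tuple[float, ...] = ()
    diurnal_amplitude: float = 0.0  # fraction of baseline_sd
    diurnal_acrophase_h: float = 0.0  # peak hour in [0, 24)
    sex_shift: float = 0.0  # additive shift for males aged 20-50
    age_slope: float = 0.0  # per decade, latent-scale units
    clip_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r} for {self.name}")
        if self.baseline_sd <= 0:
            raise ValueError(f"baseline_sd must be > 0 for {self.name}")
        if self.diurnal_amplitude < 0:
            raise ValueError(f"diurnal_amplitude must be >= 0 for {self.name}")
        if not 0.0 <= self.diurnal_acrophase_h < 24.0:
            raise ValueError(f"acrophase must lie in [0, 24) for {self.name}")


#: age quantile anchors (quantile, age in years); piecewise-linear inverse CDF
DEFAULT_AGE_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.25, 27.0),
    (0.5, 51.0),
    (0.75, 66.0),
    (1.0, 95.0),
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level parameters of the generator.

    Defaults emulate the tertiary-care population the panel is modelled on:
    52.8% of samples from male patients, median age at draw 51 (IQR 27-66),
    roughly nine samples per patient, draws spread over 2005-2020 with
    reticulocyte mode becoming the default protocol in 2013.
    """

    n_samples: int = 10_000
    n_patients: int | None = None  # default: ~n_samples / 8.6
    male_fraction: float = 0.528
    age_quantile_anchors: tuple[tuple[float, float], ...] = DEFAULT_AGE_ANCHORS
    n_latent_factors: int = 4
    cll_fraction: float = 0.001
    cll_lymphocyte_multiplier: float = 30.0
    missing_fraction_pre_cutoff: float = 0.7
    missing_cutoff_year: int = 2013
    year_range: tuple[int, int] = (2005, 2020)
    daytime_fraction: float = 0.85  # share of draws between 06:00 and 18:00
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        n_pat = self.resolved_n_patients
        if n_pat <= 0 or n_pat > self.n_samples:
            raise ValueError("need 1 <= n_patients <= n_samples")
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("male_fraction must lie in (0, 1)")
        if not 0.0 <= self.cll_fraction < 1.0:
            raise ValueError("cll_fraction must lie in [0, 1)")
        if not 0.0 <= self.missing_fraction_pre_cutoff < 1.0:
            raise ValueError("missing_fraction_pre_cutoff must lie in [0, 1)")
        if self.n_latent_factors < 1:
            raise ValueError("n_latent_factors must be >= 1")
        qs = [q for q, _ in self.age_quantile_anchors]
        ages = [a for _, a in self.age_quantile_anchors]
        if sorted(qs) != qs or qs[0] != 0.0 or qs[-1] != 1.0:
            raise ValueError("age anchors must span quantiles 0..1 in order")
        if any(a < 0 for a in ages):
            raise ValueError("anchor ages must be non-negative")

    @property
    def resolved_n_patients(self) -> int:
        if self.n_patients is not None:
            return self.n_patients
        # ~8.6 samples per patient, as in the cohort being emulated
        return max(1, round(self.n_samples / 8.6))


@dataclass
class CohortTable:
    """Samples x parameters matrix plus per-sample metadata.

    ``values`` and ``meta`` share an integer row index. ``meta`` columns:
    patient_id (int), sex ('male'/'female'), age_years (float >= 0),
    draw_time (pandas Timestamp), cll_flag (bool).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta must have the same length")
        if (self.meta["age_years"] < 0).any():
            raise ValueError("negative ages are not allowed")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)

    @property
    def draw_hour(self) -> np.ndarray:
        """Fractional hour-of-day of each blood draw."""
        t = self.meta["draw_time"]
        return (t.dt.hour + t.dt.minute / 60.0).to_numpy()

    @property
    def draw_year(self) -> np.ndarray:
        return self.meta["draw_time"].dt.year.to_numpy()

    def copy(self) -> "CohortTable":
        return CohortTable(self.values.copy(), self.meta.copy())

    def equals(self, other: "CohortTable") -> bool:
        return self.values.equals(other.values) and self.meta.equals(other.meta)

    def to_csv(self, path) -> None:
        pd.concat([self.meta, self.values], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, parse_dates=["draw_time"])
        meta_cols = ["patient_id", "sex", "age_years", "draw_time", "cll_flag"]
        return cls(df.drop(columns=meta_cols), df[meta_cols])

    def to_parquet(self, path) -> None:
        pd.concat([self.meta, self.values], axis=1).to_parquet(path, index=False)

    @classmethod
    def from_parquet(cls, path) -> "CohortTable":
        df = pd.read_parquet(path)
        meta_cols = ["patient_id", "sex", "age_years", "draw_time", "cll_flag"]
        return cls(df.drop(columns=meta_cols), df[meta_cols])


# ---------------------------------------------------------------------------
# default panel


def _loadings(factor: int, weight: float, n_factors: int = 4) -> tuple[float, ...]:
    w = [0.0] * n_factors
    w[factor] = weight
    return tuple(w)


def build_default_panel() -> list[ParameterSpec]:
    """The default 70-parameter CBC-like panel.

    Mimics the structure of a modern haemocytometer's output: reported and
    research-only red-cell, white-cell, platelet and reticulocyte-mode
    characteristics. Latent factors are assigned per lineage (factor 0:
    red-cell/reticulocyte, 1: white-cell counts, 2: white-cell morphology and
    fractions, 3: platelet), which yields the collinearity a PCA exploits.
    Fraction parameters are modelled marginally; they are not constrained to
    sum to one.
    """
    p: list[ParameterSpec] = []
    RC, WC, PLT, RET = LINEAGES

    # --- red cell line (factor 0) ------------------------------------------
    # hemoglobin-like parameter: clear male-female difference at ages 20-50
    p.append(ParameterSpec("hemoglobin_like", RC, 8.6, 1.0, False,
                           _loadings(0, 0.85), sex_shift=1.0, age_slope=-0.05))
    p.append(ParameterSpec("hematocrit", RC, 0.41, 0.05, False,
                           _loadings(0, 0.85), sex_shift=0.03, age_slope=-0.002))
    p.append(ParameterSpec("erythrocyte_count", RC, 4.6, 0.55, False,
                           _loadings(0, 0.8), sex_shift=0.25))
    for name, mean, sd, w in [
        ("mcv", 90.0, 5.5, 0.6), ("mch", 30.0, 2.2, 0.6), ("mchc", 33.5, 1.1, 0.5),
        ("rdw", 13.5, 1.6, -0.4), ("red_cell_size_mean", 88.0, 6.0, 0.6),
        ("red_cell_size_width", 12.0, 1.8, -0.35),
        ("red_cell_complexity_mean", 100.0, 8.0, 0.45),
        ("red_cell_complexity_width", 15.0, 2.5, -0.3),
        ("red_cell_viability_index", 97.0, 1.5, 0.3),
        ("hypochromic_fraction", 2.5, 1.8, -0.5),
        ("macrocytic_fraction", 1.8, 1.2, 0.35),
        ("microcytic_fraction", 1.4, 1.0, -0.45),
    ]:
        p.append(ParameterSpec(name, RC, mean, sd, False, _loadings(0, w)))

    # --- white cell counts (factor 1): log-normal --------------------------
    # baseline_mean / baseline_sd are on the natural-log scale (counts x1e9/L)
    p.append(ParameterSpec("leukocyte_count", WC, np.log(7.5), 0.42, True,
                           _loadings(1, 0.9), diurnal_amplitude=0.25,
                           diurnal_acrophase_h=16.0))
    p.append(ParameterSpec("neutrophil_count", WC, np.log(4.4), 0.50, True,
                           _loadings(1, 0.85), diurnal_amplitude=0.3,
                           diurnal_acrophase_h=16.0))
    p.append(ParameterSpec("lymphocyte_count", WC, np.log(2.0), 0.45, True,
                           _loadings(1, 0.6), diurnal_amplitude=0.15,
                           diurnal_acrophase_h=1.0))
    p.append(ParameterSpec("monocyte_count", WC, np.log(0.55), 0.40, True,
                           _loadings(1, 0.6)))
    p.append(ParameterSpec("eosinophil_count", WC, np.log(0.16), 0.65, True,
                           _loadings(1, 0.45), diurnal_amplitude=0.3,
                           diurnal_acrophase_h=1.0))
    p.append(ParameterSpec("basophil_count", WC, np.log(0.04), 0.55, True,
                           _loadings(1, 0.4)))
    p.append(ParameterSpec("immature_granulocyte_count", WC, np.log(0.03), 0.7,
                           True, _loadings(1, 0.5)))
    p.append(ParameterSpec("blast_like_count", WC, np.log(0.01), 0.6, True,
                           _loadings(1, 0.35)))

    # --- white cell fractions & morphology (factor 2) ----------------------
    # granulocyte fractions carry the clearest diurnal signal: neutrophil
    # fraction peaks late afternoon, eosinophil fraction peaks at night
    p.append(ParameterSpec("neutrophil_fraction", WC, 58.0, 9.0, False,
                           _loadings(2, 0.7), diurnal_amplitude=0.5,
                           diurnal_acrophase_h=16.0))
    p.append(ParameterSpec("eosinophil_fraction", WC, 2.6, 1.7, False,
                           _loadings(2, -0.4), diurnal_amplitude=0.45,
                           diurnal_acrophase_h=1.0))
    p.append(ParameterSpec("lymphocyte_fraction", WC, 28.0, 8.0, False,
                           _loadings(2, -0.75), diurnal_amplitude=0.3,
                           diurnal_acrophase_h=2.0))
    p.append(ParameterSpec("monocyte_fraction", WC, 7.5, 2.2, False,
                           _loadings(2, -0.3)))
    p.append(ParameterSpec("basophil_fraction", WC, 0.55, 0.3, False,
                           _loadings(2, -0.2)))
    for name, mean, sd, w, kw in [
        ("neutrophil_size_mean", 140.0, 6.0, 0.5, {}),
        ("neutrophil_size_width", 18.0, 2.5, 0.3, {}),
        ("neutrophil_complexity_mean", 150.0, 7.0, 0.55, {}),
        ("neutrophil_complexity_width", 20.0, 3.0, 0.3, {}),
        ("neutrophil_lobularity_index", 110.0, 9.0, 0.4, {}),
        ("neutrophil_granularity_index", 125.0, 10.0, 0.45, {}),
        ("lymphocyte_size_mean", 92.0, 4.5, -0.45, {}),
        ("lymphocyte_size_width", 11.0, 1.6, -0.25, {}),
        ("lymphocyte_complexity_mean", 70.0, 5.0, -0.4, {}),
        ("lymphocyte_complexity_width", 9.0, 1.4, -0.2, {}),
        ("monocyte_size_mean", 160.0, 7.0, 0.3, {}),
        ("monocyte_complexity_mean", 115.0, 6.5, 0.3, {}),
        ("eosinophil_granularity_index", 180.0, 12.0, 0.25, {}),
        ("wbc_viability_index", 96.0, 2.0, 0.2, {"age_slope": -0.03}),
        ("nuclear_density_mean", 135.0, 8.0, 0.35, {}),
        ("nuclear_density_width", 17.0, 2.8, 0.25, {}),
        ("cell_membrane_scatter_mean", 105.0, 7.5, 0.3, {}),
        ("cell_membrane_scatter_width", 14.0, 2.2, 0.2, {}),
    ]:
        p.append(ParameterSpec(name, WC, mean, sd, False, _loadings(2, w), **kw))

    # --- platelet line (factor 3) ------------------------------------------
    p.append(ParameterSpec("platelet_count", PLT, 265.0, 65.0, False,
                           _loadings(3, 0.8), sex_shift=-10.0, age_slope=-2.0))
    for name, mean, sd, w in [
        ("mean_platelet_volume", 8.6, 0.9, -0.55),
        ("platelet_distribution_width", 16.5, 1.8, -0.4),
        ("plateletcrit", 0.23, 0.05, 0.75),
        ("platelet_size_mean", 8.2, 1.0, -0.5),
        ("platelet_complexity_mean", 60.0, 6.0, 0.35),
        ("large_platelet_fraction", 28.0, 6.5, -0.55),
        ("platelet_clump_index", 3.0, 1.1, 0.25),
        ("immature_platelet_fraction", 3.4, 1.6, -0.45),
        ("platelet_granularity_index", 55.0, 5.5, 0.3),
    ]:
        p.append(ParameterSpec(name, PLT, mean, sd, False, _loadings(3, w)))

    # --- reticulocyte mode (factor 0, shares red-cell biology) -------------
    # these are the parameters only measured when the sample runs in
    # reticulocyte mode (default protocol only from 2013 onwards)
    for name, mean, sd, w, kw in [
        ("reticulocyte_count", 55.0, 18.0, 0.35, {}),
        ("reticulocyte_fraction", 1.2, 0.4, 0.3, {}),
        ("immature_reticulocyte_fraction", 10.0, 4.0, -0.3, {}),
        ("reticulocyte_hemoglobin_content", 30.0, 2.5, 0.6, {}),
        ("reticulocyte_size_mean", 102.0, 6.0, 0.45, {}),
        ("reticulocyte_size_width", 13.0, 2.0, -0.3, {}),
        ("reticulocyte_complexity_mean", 108.0, 7.0, 0.4, {}),
        ("reticulocyte_complexity_width", 16.0, 2.6, -0.25, {}),
        ("reticulocyte_maturity_index", 88.0, 7.5, 0.35, {}),
        ("reticulocyte_rna_content", 12.0, 3.0, -0.35, {}),
        ("reticulocyte_viability_index", 95.0, 2.2, 0.25, {}),
        ("hypochromic_reticulocyte_fraction", 1.6, 0.9, -0.4, {}),
        ("reticulocyte_volume_mean", 106.0, 7.0, 0.5, {}),
        ("reticulocyte_volume_width", 15.0, 2.4, -0.3, {}),
    ]:
        p.append(ParameterSpec(name, RET, mean, sd, False, _loadings(0, w), **kw))

    assert len(p) == 70, f"default panel must hold 70 parameters, got {len(p)}"
    assert len({s.name for s in p}) == 70
    return p


# ---------------------------------------------------------------------------
# sampling


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream per pipeline stage, all derived from one seed."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "little") % (2**63)])
    return np.random.default_rng(ss)


def _sample_ages(rng: np.random.Generator, n: int,
                 anchors: tuple[tuple[float, float], ...]) -> np.ndarray:
    qs = np.array([q for q, _ in anchors])
    ages = np.array([a for _, a in anchors])
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, qs, ages)


def _sample_draw_times(rng: np.random.Generator, n: int,
                       config: CohortConfig) -> pd.Series:
    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, size=n)
    day_of_year = rng.integers(0, 365, size=n)
    is_day = rng.random(n) < config.daytime_fraction
    hour = np.where(is_day, rng.uniform(6.0, 18.0, n),
                    np.mod(rng.uniform(18.0, 30.0, n), 24.0))
    base = pd.to_datetime(years.astype(str)) + pd.to_timedelta(day_of_year, unit="D")
    t = base + pd.to_timedelta(np.round(hour * 60).astype(int), unit="m")
    return pd.Series(t, name="draw_time")


def sample_cohort(panel: list[ParameterSpec], config: CohortConfig) -> CohortTable:
    """Generate a cohort from a panel; bit-reproducible from ``config.seed``.

    Includes the CLL-like and missingness injections when the corresponding
    config fractions are nonzero (both flow through :func:`inject_cll` and
    :func:`inject_missingness`, which can also be applied separately).
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    n_factors = config.n_latent_factors
    for s in panel:
        if len(s.factor_loadings) not in (0, n_factors):
            raise ValueError(
                f"parameter {s.name!r} has {len(s.factor_loadings)} factor "
                f"loadings but config.n_latent_factors={n_factors}")

    n = config.n_samples
    n_pat = config.resolved_n_patients

    rng_meta = _stage_rng(config.seed, "metadata")
    patient_id = rng_meta.integers(0, n_pat, size=n)
    patient_sex_male = rng_meta.random(n_pat) < config.male_fraction
    sex = np.where(patient_sex_male[patient_id], "male", "female")
    age = _sample_ages(rng_meta, n, tuple(config.age_quantile_anchors))
    draw_time = _sample_draw_times(_stage_rng(config.seed, "drawtime"), n, config)
    hour = (draw_time.dt.hour + draw_time.dt.minute / 60.0).to_numpy()

    rng_fac = _stage_rng(config.seed, "factors")
    z_patient = rng_fac.standard_normal((n_pat, n_factors))
    z_sample = rng_fac.standard_normal((n, n_factors))
    share = _PATIENT_FACTOR_SHARE
    z = np.sqrt(share) * z_patient[patient_id] + np.sqrt(1.0 - share) * z_sample

    rng_noise = _stage_rng(config.seed, "noise")
    male_20_50 = (sex == "male") & (age >= 20.0) & (age <= 50.0)

    cols: dict[str, np.ndarray] = {}
    for s in panel:
        w = np.asarray(s.factor_loadings if s.factor_loadings else [0.0] * n_factors)
        latent = z @ w + rng_noise.standard_normal(n)
        y = s.baseline_mean + s.baseline_sd * latent
        if s.diurnal_amplitude > 0:
            y = y + s.baseline_sd * s.diurnal_amplitude * np.cos(
                2.0 * np.pi * (hour - s.diurnal_acrophase_h) / 24.0)
        if s.sex_shift:
            y = y + s.sex_shift * male_20_50
        if s.age_slope:
            y = y + s.age_slope * (age - 50.0) / 10.0
        cols[s.name] = np.exp(y) if s.lognormal else y

    values = pd.DataFrame(cols)
    meta = pd.DataFrame({
        "patient_id": patient_id,
        "sex": sex,
        "age_years": age,
        "draw_time": draw_time,
        "cll_flag": np.zeros(n, dtype=bool),
    })
    table = CohortTable(values, meta)
    if config.cll_fraction > 0:
        table = inject_cll(table, config)
    if config.missing_fraction_pre_cutoff > 0:
        table = inject_missingness(table, config, panel=panel)
    return table


def inject_cll(table: CohortTable, config: CohortConfig) -> CohortTable:
    """Turn a fraction of patients into a CLL-like subpopulation.

    All samples of the selected patients get their lymphocyte count
    multiplied by ``cll_lymphocyte_multiplier``; the leukocyte count is
    incremented by the added lymphocytes so the total stays consistent.
    """
    for col in ("lymphocyte_count", "leukocyte_count"):
        if col not in table.values.columns:
            raise ValueError(f"table lacks required column {col!r}")
    if config.cll_fraction == 0:
        return table
    out = table.copy()
    rng = _stage_rng(config.seed, "cll")
    patients = np.unique(out.meta["patient_id"].to_numpy())
    n_flag = int(round(config.cll_fraction * len(patients)))
    n_flag = max(n_flag, 1)
    flagged_patients = rng.choice(patients, size=n_flag, replace=False)
    mask = out.meta["patient_id"].isin(flagged_patients).to_numpy()
    lymph = out.values["lymphocyte_count"].to_numpy().copy()
    added = lymph * (config.cll_lymphocyte_multiplier - 1.0)
    lymph[mask] += added[mask]
    leuk = out.values["leukocyte_count"].to_numpy().copy()
    leuk[mask] += added[mask]
    out.values["lymphocyte_count"] = lymph
    out.values["leukocyte_count"] = leuk
    out.meta["cll_flag"] = mask
    return out


def inject_missingness(table: CohortTable, config: CohortConfig,
                       panel: list[ParameterSpec] | None = None,
                       columns: list[str] | None = None) -> CohortTable:
    """Set reticulocyte-mode parameters missing for pre-cutoff samples.

    Missingness probability is ``missing_fraction_pre_cutoff`` for samples
    drawn before ``missing_cutoff_year`` and zero afterwards — it depends
    only on the observed draw year, i.e. it is MAR by construction.
    """
    if columns is None:
        if panel is None:
            raise ValueError("provide either panel or explicit columns")
        columns = [s.name for s in panel if s.lineage == "reticulocyte-mode"]
    if config.missing_fraction_pre_cutoff == 0 or not columns:
        return table
    out = table.copy()
    rng = _stage_rng(config.seed, "missingness")
    pre = out.draw_year < config.missing_cutoff_year
    hit = pre & (rng.random(len(out)) < config.missing_fraction_pre_cutoff)
    out.values.loc[hit, columns] = np.nan
    return out
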