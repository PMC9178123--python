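"""Construction of methane and feed-efficiency phenotypes from weekly records.

Raw sniffer CH4/CO2 breath concentrations are scaled to daily methane
production through heat-producing units (HPU), a metabolic-heat tracer for
CO2 output: a cow's heat production predicts her CO2 exhalation, so the
breath CH4:CO2 ratio times predicted CO2 gives CH4 volume per day.

The eight analysis traits are

* MeP  — methane production, g/d;
* MeC  — methane breath concentration, ``100 * ln(ppm)``;
* MeY  — methane yield, g CH4 per kg dry matter intake;
* MeI  — methane intensity, g CH4 per kg energy-corrected milk;
* RMeP, RMeC — residuals of MeP/MeC after partial regression on ECM and
  metabolic body weight (plus the model's fixed effects);
* RFI1, RFI2 — residual feed intake: residual of DMI on ECM and MBW,
  RFI2 additionally adjusting for weekly body-weight change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Conversion of CH4:CO2 ratio and HPU to litres CH4 per day: 180 L CO2
#: per HPU per hour times 24 h.
_L_PER_HPU_DAY = 180.0 * 24.0
#: Density of CH4 at 20 degrees C, g/L.
CH4_DENSITY_G_PER_L = 0.668
#: Watts per heat-producing unit.
_W_PER_HPU = 1000.0

#: Fixed-effect columns of the repeatability animal model; also used when
#: residualizing traits so that residual traits need only a mean thereafter.
FIXED_EFFECT_COLUMNS = ("eys_class", "lactation_week", "parity")
COVARIATE_COLUMNS = ("age_at_calving_months",)

#: Covariate sets defining the residual traits (partial-regression targets).
RESIDUAL_TRAIT_DEFS: dict[str, tuple[str, tuple[str, ...]]] = {
    "rmep": ("mep", ("ecm", "mbw")),
    "rmec": ("mec", ("ecm", "mbw")),
    "rfi1": ("dmi", ("ecm", "mbw")),
    "rfi2": ("dmi", ("ecm", "mbw", "delta_bw")),
}


class DataError(ValueError):
    """Raised for physically impossible or unusable input values."""


def compute_ecm(milk_kg, fat_kg, protein_kg):
    """Energy-corrected milk (kg/d) from milk volume and fat/protein mass.

    ``ECM = 0.25 milk + 12.2 fat + 7.7 protein``.
    """
    milk_kg = np.asarray(milk_kg, dtype=float)
    fat_kg = np.asarray(fat_kg, dtype=float)
    protein_kg = np.asarray(protein_kg, dtype=float)
    if np.any(milk_kg < 0) or np.any(fat_kg < 0) or np.any(protein_kg < 0):
        raise DataError("milk, fat and protein must be non-negative")
    return 0.25 * milk_kg + 12.2 * fat_kg + 7.7 * protein_kg


def compute_hpu(bw_kg, ecm_kg, days_pregnant):
    """Heat-producing units from body weight, ECM and pregnancy stage.

    Heat output in watts is ``5.6 BW^0.75 + 22 ECM + 1.6e-5 days^3``;
    one HPU is 1000 W, so the sum is divided by 1000.
    """
    bw_kg = np.asarray(bw_kg, dtype=float)
    ecm_kg = np.asarray(ecm_kg, dtype=float)
    days_pregnant = np.asarray(days_pregnant, dtype=float)
    if np.any(bw_kg < 0) or np.any(ecm_kg < 0) or np.any(days_pregnant < 0):
        raise DataError("body weight, ECM and days pregnant must be non-negative")
    watts = 5.6 * bw_kg**0.75 + 22.0 * ecm_kg + 1.6e-5 * days_pregnant**3
    return watts / _W_PER_HPU


def compute_mep(ch4_ppm, co2_ppm, hpu):
    """Methane production (g/d) from breath CH4:CO2 ratio and HPU.

    ``CH4 (L/d) = (CH4/CO2) * 180 * 24 * HPU`` converted to grams with the
    CH4 density at 20 C (0.668 g/L).
    """
    ch4_ppm = np.asarray(ch4_ppm, dtype=float)
    co2_ppm = np.asarray(co2_ppm, dtype=float)
    hpu = np.asarray(hpu, dtype=float)
    if np.any(co2_ppm <= 0):
        raise DataError("CO2 concentration must be positive to form the ratio")
    if np.any(hpu < 0):
        raise DataError("HPU must be non-negative")
    litres = (ch4_ppm / co2_ppm) * _L_PER_HPU_DAY * hpu
    return litres * CH4_DENSITY_G_PER_L


def transform_mec(ch4_ppm):
    """Methane concentration trait: ``100 * ln(ppm)`` of the weekly mean.

    The log makes the right-skewed ppm distribution near-normal; the factor
    100 puts MeC on a scale comparable with the other traits.
    """
    ch4_ppm = np.asarray(ch4_ppm, dtype=float)
    if np.any(ch4_ppm <= 0):
        raise DataError("CH4 concentration must be positive for the log transform")
    return 100.0 * np.log(ch4_ppm)


def compute_ratio_traits(mep, dmi, ecm):
    """Methane yield (MeP/DMI) and intensity (MeP/ECM).

    Zero or missing denominators yield NaN, never an exception: a cow-week
    missing an input is missing for that trait only.
    """
    mep = np.asarray(mep, dtype=float)
    dmi = np.asarray(dmi, dtype=float)
    ecm = np.asarray(ecm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mey = np.where(dmi > 0, mep / np.where(dmi > 0, dmi, np.nan), np.nan)
        mei = np.where(ecm > 0, mep / np.where(ecm > 0, ecm, np.nan), np.nan)
    return mey, mei


@dataclass
class FilterReport:
    """Record counts removed by each editing step."""

    n_input: int = 0
    n_removed_missing_days: int = 0
    n_removed_few_weeks: int = 0
    n_cows_removed: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def apply_editing_filters(
    records: pd.DataFrame,
    min_days_per_week: int = 4,
    min_weeks_per_cow: int = 3,
) -> tuple[pd.DataFrame, FilterReport]:
    """Editing filters on weekly gas records.

    A week is kept only if at most 3 of its 7 days are missing
    (``n_days_observed >= 4``); a cow is kept only with at least three
    surviving weekly records.  Returns the filtered table and a count
    report for the run manifest.
    """
    report = FilterReport(n_input=len(records))
    if len(records) == 0:
        return records.copy(), report
    good_week = records["n_days_observed"] >= min_days_per_week
    report.n_removed_missing_days = int((~good_week).sum())
    kept = records.loc[good_week]
    weeks_per_cow = kept.groupby("cow_id")["week_index"].transform("size")
    good_cow = weeks_per_cow >= min_weeks_per_cow
    report.n_removed_few_weeks = int((~good_cow).sum())
    report.n_cows_removed = int(kept.loc[~good_cow, "cow_id"].nunique())
    out = kept.loc[good_cow].reset_index(drop=True)
    report.n_output = len(out)
    return out, report


def delta_bw(table: pd.DataFrame) -> pd.Series:
    """Weekly body-weight change per cow, kg/week.

    Centered first difference ``(BW_{t+1} - BW_{t-1}) / 2`` on the cow's
    record sequence, falling back to forward/backward differences at the
    ends; NaN for cows with a single record.
    """

    def _per_cow(bw: pd.Series) -> pd.Series:
        v = bw.to_numpy(dtype=float)
        out = np.full(len(v), np.nan)
        if len(v) >= 2:
            out[0] = v[1] - v[0]
            out[-1] = v[-1] - v[-2]
        if len(v) >= 3:
            out[1:-1] = 0.5 * (v[2:] - v[:-2])
        return pd.Series(out, index=bw.index)

    return table.groupby("cow_id", sort=False)["bw_kg"].transform(_per_cow)


def build_trait_table(
    records: pd.DataFrame,
    apply_filters: bool = True,
    co2_reference_ppm: str | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Derive the analysis traits from raw weekly records.

    Expects the long-format weekly record table (one row per cow-week) with
    columns ``cow_id, week_index, eys_class, lactation_week, parity,
    age_at_calving_months, milk_kg, fat_kg, protein_kg, bw_kg, dmi_kg,
    days_pregnant, ch4_ppm, co2_ppm, n_days_observed``.  Returns the trait
    table (direct traits; residual traits via :func:`add_residual_traits`)
    and the editing-filter report.
    """
    if apply_filters:
        records, report = apply_editing_filters(records)
    else:
        report = FilterReport(n_input=len(records), n_output=len(records))
    t = records[
        [
            "cow_id",
            "week_index",
            "eys_class",
            "lactation_week",
            "parity",
            "age_at_calving_months",
            "dmi_kg",
        ]
    ].copy()
    t = t.rename(columns={"dmi_kg": "dmi"})
    t["ecm"] = compute_ecm(
        records["milk_kg"], records["fat_kg"], records["protein_kg"]
    )
    t["mbw"] = records["bw_kg"].to_numpy(dtype=float) ** 0.75
    hpu = compute_hpu(records["bw_kg"], t["ecm"], records["days_pregnant"])
    t["mep"] = compute_mep(records["ch4_ppm"], records["co2_ppm"], hpu)
    t["mec"] = transform_mec(records["ch4_ppm"])
    t["mey"], t["mei"] = compute_ratio_traits(t["mep"], t["dmi"], t["ecm"])
    t["bw_kg"] = records["bw_kg"].to_numpy(dtype=float)
    t["delta_bw"] = delta_bw(t)
    return t, report


class DesignError(ValueError):
    """Raised when a regression design matrix is rank deficient."""


def _design_matrix(
    table: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Fixed effects (reference-coded) plus covariates, with intercept."""
    pieces = [pd.Series(1.0, index=table.index, name="intercept")]
    for col in FIXED_EFFECT_COLUMNS:
        dummies = pd.get_dummies(
            table[col].astype("category"), prefix=col, drop_first=True, dtype=float
        )
        pieces.append(dummies)
    for col in COVARIATE_COLUMNS + tuple(covariates):
        pieces.append(table[col].astype(float))
    X = pd.concat(pieces, axis=1)
    names = list(X.columns)
    return X.to_numpy(dtype=float), names


class TraitResidualizer:
    """Partial-regression residualizer defining the residual traits.

    Fits, by ordinary least squares, the trait on the repeatability model's
    fixed effects (experiment-year-season, lactation week, parity,
    age-at-calving covariate) plus the trait-specific covariates — e.g. ECM
    and metabolic body weight for residual methane production — and returns
    the residuals.  This is the first step of the two-step residual-trait
    approach: the residuals then enter a mean-only animal model.

    Parameters
    ----------
    covariates
        Continuous covariate columns regressed out in addition to the
        fixed effects (e.g. ``("ecm", "mbw")``).

    Attributes
    ----------
    coef_ : OLS coefficients on the fitted design.
    column_names_ : design-matrix column names.
    """

    def __init__(self, covariates: tuple[str, ...] = ("ecm", "mbw")):
        self.covariates = tuple(covariates)

    def get_params(self, deep: bool = True) -> dict:
        return {"covariates": self.covariates}

    def set_params(self, **params) -> "TraitResidualizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y) -> "TraitResidualizer":
        y = np.asarray(y, dtype=float)
        mask = np.isfinite(y)
        for col in self.covariates:
            mask &= np.isfinite(X[col].to_numpy(dtype=float))
        D, names = _design_matrix(X.loc[mask], self.covariates)
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            # identify (approximately) dependent columns via QR pivoting
            _, R = np.linalg.qr(D)
            bad = [names[j] for j in range(D.shape[1]) if abs(R[j, j]) < 1e-8]
            raise DesignError(
                "rank-deficient residualization design; collinear columns: "
                + ", ".join(bad or ["<unidentified>"])
            )
        coef, *_ = np.linalg.lstsq(D, y[mask], rcond=None)
        self.coef_ = coef
        self.column_names_ = names
        self._fit_mask = mask
        return self

    def transform(self, X: pd.DataFrame, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        out = np.full(len(y), np.nan)
        mask = np.isfinite(y)
        for col in self.covariates:
            mask &= np.isfinite(X[col].to_numpy(dtype=float))
        D, names = _design_matrix(X.loc[mask], self.covariates)
        if names != self.column_names_:
            raise DesignError(
                "design columns at transform time differ from the fit; "
                "factor levels must match"
            )
        out[mask] = y[mask] - D @ self.coef_
        return out

    def fit_transform(self, X: pd.DataFrame, y) -> np.ndarray:
        return self.fit(X, y).transform(X, y)


def residualize(
    table: pd.DataFrame, trait: str, covariates: tuple[str, ...]
) -> np.ndarray:
    """OLS residuals of ``trait`` on fixed effects plus ``covariates``."""
    return TraitResidualizer(covariates).fit_transform(table, table[trait])


def add_residual_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Append RMeP, RMeC, RFI1 and RFI2 columns to a trait table."""
    out = table.copy()
    for name, (base, covs) in RESIDUAL_TRAIT_DEFS.items():
        out[name] = residualize(out, base, covs)
    return out
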