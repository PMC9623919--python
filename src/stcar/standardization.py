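"""Indirect standardization: reference rates, expected deaths, SMR, covariates.

The raw standardized mortality ratio SMR_it = O_it / E_it compares each
region-year's observed deaths with the count expected if the region
experienced the reference population's stratum-specific death rates. The
reference scheme here is the one used in prefecture-level Japanese mortality
mapping: stratum rates are formed from the *mean* reference deaths and mean
reference population over the study years (sex x 5-year age group strata),
then applied to each municipality's stratified population year by year.

Also provided: the great-circle distance to the nearest active facility
(e.g. a primary stroke center) as a healthcare-accessibility covariate, and
last-observation-carried-forward filling for covariates surveyed less often
than annually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedPanel",
    "PanelData",
    "default_age_groups",
    "compute_reference_rates",
    "compute_expected_deaths",
    "compute_smr",
    "haversine_km",
    "nearest_facility_distance",
    "fill_covariates_locf",
    "zscore_columns",
]

EARTH_RADIUS_KM = 6371.0


def default_age_groups():
    """Seventeen five-year age bands: 0-4, 5-9, ..., 75-79, 80+."""
    bands = [f"{a}-{a + 4}" for a in range(0, 80, 5)]
    bands.append("80+")
    return bands


@dataclass
class StratifiedPanel:
    """Populations stratified by region x year x sex x age group.

    ``population`` is a long-format DataFrame with columns
    (region_id, year, sex, age_group, population). ``reference_deaths`` is a
    long-format DataFrame (year, sex, age_group, deaths) for the reference
    population (typically the whole study area).
    """

    population: pd.DataFrame
    reference_deaths: pd.DataFrame | None = None
    strata: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"region_id", "year", "sex", "age_group", "population"}
        missing = required - set(self.population.columns)
        if missing:
            raise ValueError(f"population table missing columns {sorted(missing)}")
        if (self.population["population"] < 0).any():
            raise ValueError("populations must be non-negative")
        if not self.strata:
            self.strata = sorted(
                set(zip(self.population["sex"], self.population["age_group"]))
            )
        # every region-year must be present (complete panel)
        counts = self.population.groupby(["region_id", "year"]).size()
        regions = self.population["region_id"].unique()
        years = self.population["year"].unique()
        if len(counts) != len(regions) * len(years):
            raise ValueError("population panel is incomplete: missing region-years")


@dataclass
class PanelData:
    """Region x year panel of deaths, expected deaths and covariates.

    Arrays are indexed [region, year] following ``region_ids`` / ``years``;
    covariates are stacked [region, year, covariate].
    """

    O: np.ndarray
    E: np.ndarray
    X: np.ndarray
    region_ids: list
    years: list
    covariate_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O)
        self.E = np.asarray(self.E, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        N, T = len(self.region_ids), len(self.years)
        if self.O.shape != (N, T) or self.E.shape != (N, T):
            raise ValueError("O and E must be (n_regions, n_years)")
        if self.X.ndim != 3 or self.X.shape[:2] != (N, T):
            raise ValueError("X must be (n_regions, n_years, n_covariates)")
        if np.any(self.O < 0) or not np.issubdtype(self.O.dtype, np.integer):
            if np.any(self.O < 0) or np.any(self.O != np.round(self.O)):
                raise ValueError("O must contain non-negative integers")
            self.O = self.O.astype(int)
        if np.any((self.E <= 0) & (self.O > 0)):
            raise ValueError("E must be positive wherever deaths are observed")
        if not np.isfinite(self.X).all():
            raise ValueError("X must be finite")
        if not self.covariate_names:
            self.covariate_names = [f"x{j}" for j in range(self.X.shape[2])]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    def design_matrix(self) -> np.ndarray:
        """Covariates flattened to (N*T, p), region-major order."""
        return self.X.reshape(self.O.size, self.X.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (region_id, year, O, E, covariates...)."""
        N, T = self.n_regions, self.n_years
        rows = {
            "region_id": np.repeat(self.region_ids, T),
            "year": np.tile(self.years, N),
            "observed": self.O.ravel(),
            "expected": self.E.ravel(),
        }
        for j, name in enumerate(self.covariate_names):
            rows[name] = self.X[:, :, j].ravel()
        return pd.DataFrame(rows)


def compute_reference_rates(ref: StratifiedPanel) -> pd.Series:
    """Mean-over-years stratum death rates of the reference population.

    rate_k = mean_t(reference deaths in stratum k) / mean_t(reference
    population in stratum k). A stratum with zero mean population and zero
    deaths gets rate 0 with a warning; nonzero deaths on zero population is
    an error.
    """
    if ref.reference_deaths is None:
        raise ValueError("StratifiedPanel has no reference_deaths table")
    pop = (
        ref.population.groupby(["year", "sex", "age_group"])["population"]
        .sum()
        .groupby(["sex", "age_group"])
        .mean()
    )
    deaths = (
        ref.reference_deaths.groupby(["year", "sex", "age_group"])["deaths"]
        .sum()
        .groupby(["sex", "age_group"])
        .mean()
    )
    deaths = deaths.reindex(pop.index, fill_value=0.0)
    rates = pd.Series(0.0, index=pop.index, name="rate")
    zero_pop = pop == 0
    if (zero_pop & (deaths > 0)).any():
        bad = deaths.index[zero_pop & (deaths > 0)].tolist()
        raise ValueError(f"strata with deaths but zero mean population: {bad}")
    if zero_pop.any():
        warnings.warn(
            f"{int(zero_pop.sum())} empty strata assigned rate 0", stacklevel=2
        )
    rates[~zero_pop] = deaths[~zero_pop] / pop[~zero_pop]
    return rates


def compute_expected_deaths(rates: pd.Series, pop: StratifiedPanel) -> pd.DataFrame:
    """Expected deaths E_it = sum_k rate_k * population_itk.

    Returns a DataFrame indexed by region_id with one column per year.
    """
    df = pop.population.copy()
    key = list(zip(df["sex"], df["age_group"]))
    missing = sorted(set(key) - set(rates.index))
    if missing:
        raise ValueError(f"no reference rate for strata: {missing[:5]}")
    df["rate"] = rates.loc[key].to_numpy()
    df["expected"] = df["rate"] * df["population"]
    out = df.pivot_table(
        index="region_id", columns="year", values="expected", aggfunc="sum"
    )
    return out


def compute_smr(O, E):
    """Raw standardized mortality ratio O / E; E must be positive."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("SMR undefined where expected deaths are zero")
    return O / E


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between WGS84 lon/lat points."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(h))


def nearest_facility_distance(points: pd.DataFrame, facilities: pd.DataFrame, years) -> pd.DataFrame:
    """Distance (km) from each region's representative point to the nearest
    facility active in each year.

    Parameters
    ----------
    points : DataFrame with columns (region_id, lon, lat)
        One representative point per region (e.g. the municipal office).
    facilities : DataFrame with columns (facility_id, lon, lat,
        active_from_year, active_to_year)
        Facility sets may change over time (active range inclusive).
    years : iterable of int

    Returns a DataFrame indexed by region_id, one column per year.
    """
    out = pd.DataFrame(index=points["region_id"].to_numpy(), columns=list(years), dtype=float)
    out.index.name = "region_id"
    for year in years:
        active = facilities[
            (facilities["active_from_year"] <= year) & (facilities["active_to_year"] >= year)
        ]
        if active.empty:
            raise ValueError(f"no facilities active in year {year}")
        d = haversine_km(
            points["lon"].to_numpy()[:, None],
            points["lat"].to_numpy()[:, None],
            active["lon"].to_numpy()[None, :],
            active["lat"].to_numpy()[None, :],
        )
        out[year] = d.min(axis=1)
    return out


def fill_covariates_locf(X: pd.DataFrame) -> pd.DataFrame:
    """Fill missing survey years by carrying the last observation forward.

    ``X`` is wide: rows indexed by year (ascending), one column per
    covariate series. A covariate observed only once (a fixed socioeconomic
    indicator) is held constant over all later years. Missing the first year
    is an error: there is nothing to carry forward.
    """
    X = X.sort_index()
    first = X.iloc[0]
    if first.isna().any():
        bad = first.index[first.isna()].tolist()
        raise ValueError(f"covariates missing in their first year: {bad}")
    return X.ffill()


def zscore_columns(X: np.ndarray):
    """Z-score each covariate over the pooled region-year sample.

    Returns (standardized X, means, sds). The raw-scale SD is reported next
    to each fitted coefficient so relative risks read "per one SD".
    """
    X = np.asarray(X, dtype=float)
    flat = X.reshape(-1, X.shape[-1])
    means = flat.mean(axis=0)
    sds = flat.std(axis=0, ddof=0)
    if np.any(sds == 0):
        raise ValueError("cannot z-score a constant covariate column")
    return (X - means) / sds, means, sds
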