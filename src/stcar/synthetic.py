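"""Synthetic Hokkaido-like inputs with known ground truth.

Builds a queen-contiguous lattice of "municipalities" (optionally with
detached island cells wired back in by ferry edges), stratified populations,
age- and sex-graded reference death rates, partly time-varying covariates,
spatio-temporally autocorrelated log-relative-risk surfaces drawn exactly
from the CAR prior, and Poisson death counts — everything the pipeline
consumes, at a scale recognisably like a prefecture of ~188 municipalities
observed over 11 years with a handful of deaths per municipality-year.

The generator's outputs round-trip through the same CSV/GeoJSON dialects the
pipeline reads, and the generating parameters are returned (and can be
serialized) so recovery tests never have to re-derive the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from shapely.geometry import box

from .region_graph import RegionGraph, build_queen_adjacency, leroux_precision
from .standardization import (
    PanelData,
    StratifiedPanel,
    compute_expected_deaths,
    compute_reference_rates,
    default_age_groups,
    nearest_facility_distance,
    zscore_columns,
)

__all__ = ["CovariateRule", "SimulationSpec", "build_synthetic_regions",
           "simulate_car_effects", "simulate_panel", "write_inputs"]


@dataclass(frozen=True)
class CovariateRule:
    """How one synthetic covariate behaves.

    ``kind`` is "fixed" (constant over years, like census socioeconomic
    shares), "varying" (AR(1) drift over years, like facility counts), or
    "distance" (straight-line km to the nearest synthetic facility).
    ``loading`` on a shared regional factor induces the cross-covariate
    correlation that makes VIF screening non-trivial.
    """

    name: str
    kind: str = "varying"
    loading: float = 0.5
    beta: float = 0.0  # true per-SD log relative risk


def _default_covariates():
    # magnitudes chosen to resemble per-SD log-RRs reported for
    # healthcare-accessibility covariates in prefecture-scale mapping
    return (
        CovariateRule("distance_psc", kind="distance", beta=0.06),
        CovariateRule("emergency_hospitals", kind="varying", beta=-0.10),
        CovariateRule("general_hospitals", kind="varying", beta=0.12),
        CovariateRule("clinics", kind="varying", beta=0.0),
        CovariateRule("college_ratio", kind="fixed", beta=-0.04),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of a synthetic study area and model."""

    rows: int = 14
    cols: int = 14
    n_remove: int = 8          # cells deleted to break the perfect rectangle
    n_islands: int = 2         # detached cells reconnected by ferry edges
    years: tuple = tuple(range(2010, 2021))
    pop_range: tuple = (1_000, 100_000)   # log-uniform across regions
    crude_rate: float = 5.3e-4            # pooled deaths per person-year
    annual_pop_drift: float = -0.005      # population decline per year
    intercept: float = 0.0
    tau2: float = 0.3
    rho_s: float = 0.8
    rho_t: float = 0.7
    covariates: tuple = field(default_factory=_default_covariates)
    n_facilities: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("lattice dimensions must be positive")
        if not (0.0 < self.rho_s < 1.0 and 0.0 < self.rho_t < 1.0):
            raise ValueError("true rho values must lie in (0, 1)")
        if self.tau2 <= 0:
            raise ValueError("tau2 must be positive")
        if min(self.pop_range) <= 0:
            raise ValueError("populations must be positive")

    @property
    def beta(self) -> np.ndarray:
        return np.array([c.beta for c in self.covariates])


# lattice footprint, degrees: loosely prefecture-sized
_LON0, _LAT0, _CELL = 141.0, 42.0, 0.25


def _lattice_cells(spec: SimulationSpec, rng):
    """Choose lattice cells: keep most, detach islands, drop a few."""
    cells = [(r, c) for r in range(spec.rows) for c in range(spec.cols)]
    rng.shuffle(cells)
    islands = cells[: spec.n_islands]
    removed = set(cells[spec.n_islands: spec.n_islands + spec.n_remove])
    kept = [rc for rc in cells if rc not in removed]
    return sorted(kept), set(islands)


def build_synthetic_regions(spec: SimulationSpec):
    """Lattice polygons, adjacency graph and stratified populations.

    Island cells are translated away from the lattice (so they touch
    nothing) and reconnected to their nearest kept mainland cell through
    ferry ``extra_edges``. Populations are log-uniform across regions within
    ``spec.pop_range``, with a fixed age/sex structure shared by all regions
    and a deterministic annual drift.

    Returns (polygons, graph, StratifiedPanel, points) where ``points`` are
    the representative lon/lat coordinates used for distance covariates.
    """
    rng = np.random.default_rng(spec.seed)
    kept, islands = _lattice_cells(spec, rng)
    polygons, coords, extra_edges = [], [], []
    mainland = [rc for rc in kept if rc not in islands]
    for r, c in kept:
        rid = f"R{r:02d}{c:02d}"
        if (r, c) in islands:
            # push the island off the lattice so geometry sees no neighbours
            lon = _LON0 + (spec.cols + 3 + c) * _CELL
            lat = _LAT0 - 3 * _CELL + r * 0.01
            near = min(mainland, key=lambda rc2: abs(rc2[0] - r) + abs(rc2[1] - c))
            extra_edges.append((rid, f"R{near[0]:02d}{near[1]:02d}"))
        else:
            lon = _LON0 + c * _CELL
            lat = _LAT0 + r * _CELL
        polygons.append((rid, box(lon, lat, lon + _CELL, lat + _CELL)))
        coords.append((rid, lon + _CELL / 2, lat + _CELL / 2))
    graph = build_queen_adjacency(polygons, extra_edges=extra_edges)

    ages = default_age_groups()
    n_ages = len(ages)
    # fixed age pyramid, weighted toward older bands as in an ageing prefecture
    age_w = np.linspace(0.8, 1.6, n_ages)
    age_w /= age_w.sum()
    base_pop = np.exp(rng.uniform(np.log(spec.pop_range[0]),
                                  np.log(spec.pop_range[1]), len(kept)))
    rows = []
    for (rid, _, _), pop in zip(coords, base_pop):
        for yi, year in enumerate(spec.years):
            ypop = pop * (1.0 + spec.annual_pop_drift) ** yi
            for sex, frac in (("male", 0.48), ("female", 0.52)):
                for band, w in zip(ages, age_w):
                    rows.append((rid, year, sex, band, ypop * frac * w))
    population = pd.DataFrame(
        rows, columns=["region_id", "year", "sex", "age_group", "population"])

    # stratum rates rising exponentially with age, higher for men, scaled to
    # the target crude rate; reference deaths derive from them exactly
    age_idx = np.arange(n_ages)
    shape = np.exp(0.45 * age_idx)
    sex_factor = {"male": 1.3, "female": 0.77}
    pooled = population.groupby(["sex", "age_group"])["population"].sum()
    raw = pd.Series(
        {(s, a): shape[ages.index(a)] * sex_factor[s] for s, a in pooled.index})
    scale = spec.crude_rate * pooled.sum() / (raw * pooled).sum()
    rates = raw * scale
    ref_rows = []
    ref_by_year = population.groupby(["year", "sex", "age_group"])["population"].sum()
    for (year, sex, band), p in ref_by_year.items():
        ref_rows.append((year, sex, band, rates[(sex, band)] * p))
    reference_deaths = pd.DataFrame(
        ref_rows, columns=["year", "sex", "age_group", "deaths"])

    panel = StratifiedPanel(population=population,
                            reference_deaths=reference_deaths)
    points = pd.DataFrame(coords, columns=["region_id", "lon", "lat"])
    return polygons, graph, panel, points


def simulate_car_effects(graph: RegionGraph, T: int, tau2: float, rho_s: float,
                         rho_t: float, seed: int = 0) -> np.ndarray:
    """Exact draw of the spatio-temporal effect surface from the CAR prior.

    phi_1 ~ N(0, tau^2 Q^{-1}) and phi_t = rho_t phi_{t-1} + innovation with
    the same Leroux covariance, sampled through the Cholesky factor of Q
    (solve L' x = z gives x ~ N(0, Q^{-1})).
    """
    if not rho_s < 1.0:
        raise ValueError("rho_s must be below 1 for a proper prior")
    rng = np.random.default_rng(seed)
    Q = leroux_precision(graph, rho_s)
    L = cholesky(Q, lower=True)  # raises LinAlgError if Q is singular
    N = graph.n_regions

    def innovation():
        z = rng.standard_normal(N)
        return np.sqrt(tau2) * solve_triangular(L, z, trans="T", lower=True)

    phi = np.empty((N, T))
    phi[:, 0] = innovation()
    for t in range(1, T):
        phi[:, t] = rho_t * phi[:, t - 1] + innovation()
    return phi


def _covariate_matrix(spec: SimulationSpec, points: pd.DataFrame, rng):
    """Raw covariate panel (N, T, p) plus the synthetic facility table."""
    N, T = len(points), len(spec.years)
    shared = rng.standard_normal(N)  # regional factor inducing collinearity
    X = np.empty((N, T, len(spec.covariates)))
    facilities = None
    for j, rule in enumerate(spec.covariates):
        if rule.kind == "distance":
            # cap so some regions are always off-site, keeping distances
            # non-degenerate on tiny test lattices
            n_fac = max(1, min(spec.n_facilities, N // 3))
            pick = rng.choice(N, size=n_fac, replace=False)
            facilities = pd.DataFrame({
                "facility_id": [f"F{k}" for k in range(len(pick))],
                "lon": points["lon"].to_numpy()[pick],
                "lat": points["lat"].to_numpy()[pick],
                "active_from_year": min(spec.years),
                "active_to_year": max(spec.years),
            })
            dist = nearest_facility_distance(points, facilities, spec.years)
            X[:, :, j] = dist.loc[points["region_id"]].to_numpy()
            continue
        base = rule.loading * shared + np.sqrt(1 - rule.loading ** 2) * rng.standard_normal(N)
        if rule.kind == "fixed":
            X[:, :, j] = base[:, None]
        elif rule.kind == "varying":
            ar = np.empty((N, T))
            ar[:, 0] = rng.standard_normal(N)
            for t in range(1, T):
                ar[:, t] = 0.8 * ar[:, t - 1] + 0.6 * rng.standard_normal(N)
            X[:, :, j] = base[:, None] + 0.4 * ar
        else:
            raise ValueError(f"unknown covariate kind {rule.kind!r}")
    return X, facilities


def simulate_panel(spec: SimulationSpec):
    """Full generative chain: regions -> E -> covariates -> phi -> O.

    Expected deaths come from the standardization operations applied to the
    synthetic strata; covariates are z-scored over the pooled region-years
    before the true per-SD coefficients are applied, so the returned truth
    is on the same scale the fitting pipeline estimates.

    Returns (PanelData, truth dict, extras dict). ``truth`` holds every
    generating parameter including the effect surface; ``extras`` carries
    the polygons, graph, stratified panel, facility table and raw covariate
    SDs needed to exercise the I/O pipeline.
    """
    polygons, graph, strat, points = build_synthetic_regions(spec)
    rng = np.random.default_rng(spec.seed + 1)

    rates = compute_reference_rates(strat)
    E_df = compute_expected_deaths(rates, strat)
    region_ids = list(points["region_id"])
    E = E_df.loc[region_ids, list(spec.years)].to_numpy()

    X_raw, facilities = _covariate_matrix(spec, points, rng)
    X, x_means, x_sds = zscore_columns(X_raw)

    phi = simulate_car_effects(graph, len(spec.years), spec.tau2, spec.rho_s,
                               spec.rho_t, seed=spec.seed + 2)
    eta = spec.intercept + X @ spec.beta + phi
    O = rng.poisson(E * np.exp(eta))

    panel = PanelData(O=O, E=E, X=X, region_ids=region_ids,
                      years=list(spec.years),
                      covariate_names=[c.name for c in spec.covariates])
    truth = {
        "intercept": spec.intercept,
        "beta": spec.beta.copy(),
        "tau2": spec.tau2,
        "rho_s": spec.rho_s,
        "rho_t": spec.rho_t,
        "phi": phi,
        "covariate_means": x_means,
        "covariate_sds": x_sds,
        "reference_rates": rates,
        "seed": spec.seed,
    }
    extras = {"polygons": polygons, "graph": graph, "stratified": strat,
              "points": points, "facilities": facilities,
              "covariate_sds": x_sds}
    return panel, truth, extras


def write_inputs(outdir, spec: SimulationSpec, panel: PanelData, truth, extras) -> None:
    """Serialize the synthetic inputs in the dialects the pipeline reads.

    Writes stratified-population, deaths, facility and edge-list CSVs, the
    region polygons as GeoJSON, the panel itself, and the ground truth
    (JSON for scalars, CSV for the effect surface).
    """
    from pathlib import Path
    from shapely.geometry import mapping

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    extras["stratified"].population.to_csv(outdir / "population.csv", index=False)
    extras["stratified"].reference_deaths.to_csv(outdir / "reference_deaths.csv", index=False)
    if extras["facilities"] is not None:
        extras["facilities"].to_csv(outdir / "facilities.csv", index=False)
    extras["points"].to_csv(outdir / "points.csv", index=False)
    pd.DataFrame(extras["graph"].to_edge_list(),
                 columns=["region_a", "region_b"]).to_csv(outdir / "edges.csv", index=False)
    panel.to_frame().to_csv(outdir / "panel.csv", index=False)
    features = [{"type": "Feature", "properties": {"id": rid},
                 "geometry": mapping(geom)} for rid, geom in extras["polygons"]]
    with open(outdir / "regions.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    scalars = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in truth.items() if k not in ("phi", "reference_rates")}
    scalars["spec"] = {k: v for k, v in asdict(spec).items() if k != "covariates"}
    scalars["spec"]["covariates"] = [asdict(c) for c in spec.covariates]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(scalars, fh, indent=1)
    pd.DataFrame(truth["phi"], index=panel.region_ids,
                 columns=panel.years).to_csv(outdir / "truth_phi.csv")
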