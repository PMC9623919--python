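"""Posterior disease-mapping products.

Turns retained MCMC draws into the quantities a small-area mortality study
reports: the modeled (smoothed) SMR surface and its global trend, posterior
exceedance probabilities, the across-region IQR as a disparity measure,
between-year SMR differences, relative risks per covariate SD, and
sensitivity reruns under alternative variance priors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import run_mcmc

__all__ = ["SummaryOutputs", "modeled_smr", "exceedance_probability",
           "iqr_disparity", "rr_per_sd", "smr_difference", "sensitivity_rerun",
           "export_geojson"]


@dataclass
class SummaryOutputs:
    modeled_smr: pd.DataFrame          # region x year, posterior median mu/E
    global_trend: pd.Series            # per year
    exceedance: pd.DataFrame | None = None
    rr_table: pd.DataFrame | None = None
    disparity_iqr: pd.Series | None = None
    smr_diff: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def _smr_draws(samples, E) -> np.ndarray:
    """Pooled draws of mu_it / E_it, shape (draws, N, T)."""
    return samples.pooled("mu") / np.asarray(E, dtype=float)


def modeled_smr(samples, panel):
    """Posterior-median smoothed SMR per region-year plus the global trend.

    The modeled SMR is the posterior median of mu_it / E_it over the pooled
    retained draws. The global trend aggregates fitted deaths:
    trend_t = sum_i median-fit_it / sum_i E_it, weighting municipalities by
    their expected counts so tiny populations do not dominate. The unweighted
    per-year median across regions is returned as well.
    """
    ratios = _smr_draws(samples, panel.E)
    med = np.median(ratios, axis=0)
    fit_med = np.median(samples.pooled("mu"), axis=0)
    trend = fit_med.sum(axis=0) / panel.E.sum(axis=0)
    smr = pd.DataFrame(med, index=panel.region_ids, columns=panel.years)
    return SummaryOutputs(
        modeled_smr=smr,
        global_trend=pd.Series(trend, index=panel.years, name="global_smr"),
        extras={"median_across_regions": pd.Series(np.median(med, axis=0),
                                                   index=panel.years)},
    )


def exceedance_probability(samples, panel, threshold: float = 1.0) -> pd.DataFrame:
    """Fraction of pooled draws with modeled SMR above ``threshold``."""
    ratios = _smr_draws(samples, panel.E)
    pep = (ratios > threshold).mean(axis=0)
    return pd.DataFrame(pep, index=panel.region_ids, columns=panel.years)


def iqr_disparity(modeled: pd.DataFrame, as_percent: bool = False) -> pd.Series:
    """Across-region interquartile range of modeled SMR, per year.

    Quantiles use linear interpolation between order statistics. With
    ``as_percent`` the IQR is scaled by 100, matching disparity trends
    quoted in percent.
    """
    if modeled.shape[0] < 4:
        raise ValueError("IQR disparity needs at least 4 regions")
    q1 = modeled.quantile(0.25, axis=0, interpolation="linear")
    q3 = modeled.quantile(0.75, axis=0, interpolation="linear")
    iqr = (q3 - q1).rename("iqr")
    return iqr * 100.0 if as_percent else iqr


def rr_per_sd(samples, covariate_sds=None) -> pd.DataFrame:
    """Relative risks per one SD of each covariate.

    Because covariates are z-scored before fitting, exp(beta_j) is already
    the risk ratio for a one-SD increase. Reports the posterior median RR,
    its 95% credible interval, and the raw-scale SD each coefficient refers
    to.
    """
    beta = samples.pooled("beta")
    names = samples.covariate_names or [f"x{j}" for j in range(beta.shape[1])]
    med = np.median(beta, axis=0)
    lo, hi = np.percentile(beta, [2.5, 97.5], axis=0)
    table = pd.DataFrame({
        "variable": names,
        "rr": np.exp(med),
        "cr_low": np.exp(lo),
        "cr_high": np.exp(hi),
    })
    if covariate_sds is not None:
        table["sd"] = np.asarray(covariate_sds, dtype=float)
    return table


def smr_difference(modeled: pd.DataFrame, year_a, year_b):
    """Per-region change in modeled SMR from year_a to year_b, plus its mean."""
    for y in (year_a, year_b):
        if y not in modeled.columns:
            raise KeyError(f"year {y} not in modeled SMR table")
    diff = (modeled[year_b] - modeled[year_a]).rename(f"smr_diff_{year_a}_{year_b}")
    return diff, float(diff.mean())


def sensitivity_rerun(panel, graph, priors_base, config, alt_priors,
                      covariate_sds=None) -> dict:
    """Refit under alternative tau^2 priors and pair up the summaries.

    Returns {"base": {...}, "alt0": {...}, ...} where each entry carries the
    rr_table and modeled-SMR table from its own MCMC run. With an empty
    ``alt_priors`` only the base fit is returned.
    """
    out = {}
    labels = ["base"] + [f"alt{k}" for k in range(len(alt_priors))]
    for label, priors in zip(labels, [priors_base, *alt_priors]):
        samples = run_mcmc(panel, graph, priors, config)
        summ = modeled_smr(samples, panel)
        out[label] = {
            "priors": priors,
            "rr_table": rr_per_sd(samples, covariate_sds),
            "modeled_smr": summ.modeled_smr,
            "global_trend": summ.global_trend,
        }
    return out


def export_geojson(path, polygons, modeled: pd.DataFrame, exceedance: pd.DataFrame,
                   smr_diff: pd.Series, year) -> None:
    """Join mapping products onto region polygons as GeoJSON.

    Property names are fixed (smr_med, pep, smr_diff) so downstream
    choropleth tooling can rely on them.
    """
    from shapely.geometry import mapping

    features = []
    for rid, geom in polygons:
        features.append({
            "type": "Feature",
            "properties": {
                "region_id": rid,
                "smr_med": float(modeled.loc[rid, year]),
                "pep": float(exceedance.loc[rid, year]),
                "smr_diff": float(smr_diff.loc[rid]),
            },
            "geometry": mapping(geom),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
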