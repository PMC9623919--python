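"""Covariate screening: offset-Poisson GLM and VIF-based elimination.

Before the spatio-temporal model is fitted, candidate covariates are screened
with a non-spatial Poisson log-linear model

    O_it ~ Poisson(mu_it),   log mu_it = log E_it + a + x_it' beta,

and multicollinear covariates are removed stepwise: while any variance
inflation factor exceeds the threshold (default 5), the single worst
offender is dropped and VIFs are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GlmResult", "fit_poisson_glm", "compute_vif", "eliminate_high_vif"]

VIF_INFINITE = 1e6  # reported for numerically perfect collinearity


@dataclass
class GlmResult:
    """Offset-Poisson GLM fit in the layout of an exploratory-analysis table."""

    table: pd.DataFrame  # variable, coefficient, ci_low, ci_high, z_score, vif
    converged: bool
    n_obs: int
    deviance: float

    @property
    def coefficients(self) -> pd.Series:
        return self.table.set_index("variable")["coefficient"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def fit_poisson_glm(panel, covariate_names=None, tol: float = 1e-8, maxiter: int = 100) -> GlmResult:
    """Maximum-likelihood offset-Poisson fit with Wald 95% intervals.

    ``panel`` is a PanelData; ``covariate_names`` selects a subset of its
    covariates (default: all). The expected-death offset enters as
    ``log E_it``. Raises on rank deficiency (naming the collinear columns)
    and on IRLS non-convergence.
    """
    names = list(covariate_names) if covariate_names is not None else list(panel.covariate_names)
    idx = [panel.covariate_names.index(n) for n in names]
    X = panel.design_matrix()[:, idx]
    y = panel.O.ravel().astype(float)
    offset = np.log(panel.E.ravel())
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(f"design matrix rank deficient (rank {rank} < {design.shape[1]}); "
                         f"check covariates {names}")
    model = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset)
    res = model.fit(tol=tol, maxiter=maxiter)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge in {maxiter} iterations "
                           f"(final deviance {res.deviance:.6g})")
    ci = res.conf_int(alpha=0.05)
    vifs = [np.nan] + list(compute_vif(X)) if len(names) >= 2 else [np.nan] * (len(names) + 1)
    table = pd.DataFrame({
        "variable": ["intercept"] + names,
        "coefficient": res.params,
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
        "z_score": res.tvalues,
        "vif": vifs,
    })
    return GlmResult(table=table, converged=bool(res.converged),
                     n_obs=len(y), deviance=float(res.deviance))


def compute_vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors 1 / (1 - R^2_j).

    R^2_j comes from the ordinary least-squares regression of column j on
    all other columns plus an intercept. Perfectly collinear columns are
    reported as ``VIF_INFINITE``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariate columns")
    if np.any(X.std(axis=0) == 0):
        const = [j for j in range(X.shape[1]) if X[:, j].std() == 0]
        raise ValueError(f"constant columns have undefined VIF: {const}")
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vifs[j] = VIF_INFINITE if r2 >= 1.0 - 1.0 / VIF_INFINITE else 1.0 / (1.0 - r2)
    return vifs


def eliminate_high_vif(X: np.ndarray, names=None, threshold: float = 5.0):
    """Stepwise multicollinearity pruning.

    While any VIF exceeds ``threshold``, drop the single highest-VIF column
    (ties broken by earlier column index) and recompute. Returns
    ``(retained column indices, elimination log)`` where the log records
    each dropped column and the VIF that condemned it.
    """
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    keep = list(range(X.shape[1]))
    log = []
    while len(keep) >= 2:
        vifs = compute_vif(X[:, keep])
        worst = int(np.argmax(vifs))  # argmax takes the earliest on ties
        if vifs[worst] <= threshold:
            break
        dropped = keep.pop(worst)
        log.append({"dropped": names[dropped], "vif": float(vifs[worst]),
                    "remaining": [names[k] for k in keep]})
    return keep, log
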