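"""Bayesian spatio-temporal CAR Poisson model, fitted by Metropolis-within-Gibbs.

Model. For region i = 1..N and year t = 1..T,

    O_it ~ Poisson(lambda_it),
    log lambda_it = log E_it + a + x_it' beta + phi_it,

with the random-effect surface phi = (phi_1, ..., phi_T) following a
first-order autoregressive chain of Leroux-CAR fields:

    phi_1            ~ N(0, tau^2 Q(W, rho_s)^{-1}),
    phi_t | phi_{t-1} ~ N(rho_t phi_{t-1}, tau^2 Q(W, rho_s)^{-1}),

Q(W, rho_s) = rho_s (diag(W1) - W) + (1 - rho_s) I. rho_s and rho_t control
spatial and temporal autocorrelation (0 = independence, 1 = strong);
tau^2 is the process variance. Priors: tau^2 ~ Inverse-Gamma(1, 0.01),
rho_s, rho_t ~ Uniform(0, 1), and a vague Gaussian N(0, 1e5) on the
intercept and each regression coefficient.

Sampler. One sweep cycles
coefficients -> random effects -> tau^2 -> rho_t -> rho_s:

* a and beta: per-coordinate Gaussian random-walk Metropolis, scales adapted
  toward 44% acceptance during burn-in only.
* phi: element-wise random-walk Metropolis. Cells are grouped into
  conditionally independent colour classes (a proper colouring of the
  spatial graph crossed with year parity) so each class updates as one
  vectorised block — exactly equivalent to one-at-a-time updates because no
  two cells in a class interact through the joint Gaussian precision.
* tau^2: exact conjugate inverse-gamma Gibbs draw.
* rho_t: exact Gibbs draw from its Gaussian full conditional truncated
  to (0, 1).
* rho_s: random-walk Metropolis with the log-determinant of Q evaluated
  from the cached Laplacian spectrum; proposals outside (0, 1) are rejected,
  which is equivalent to the truncated uniform prior.

phi is not re-centred: the weak identifiability between the intercept and
the mean of phi is accepted and monitored through the potential scale
reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

from .region_graph import RegionGraph, leroux_precision, log_det_precision

__all__ = [
    "PriorSpec",
    "CARParams",
    "EffectState",
    "CoefficientState",
    "ModelState",
    "MCMCConfig",
    "PosteriorSamples",
    "ar1_diagonal_weights",
    "car_quadratic_form",
    "log_posterior_terms",
    "update_tau2",
    "update_rho_t",
    "update_rho_s",
    "update_phi",
    "update_coefficients",
    "run_mcmc",
    "SENSITIVITY_PRIORS",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: IG(shape, scale) on tau^2, U(0,1) on the rhos,
    N(0, beta_prior_variance) on the intercept and coefficients."""

    tau2_shape: float = 1.0
    tau2_scale: float = 0.01
    rho_lower: float = 0.0
    rho_upper: float = 1.0
    beta_prior_variance: float = 1e5

    def __post_init__(self):
        if self.tau2_shape <= 0 or self.tau2_scale <= 0:
            raise ValueError("inverse-gamma shape and scale must be positive")
        if self.beta_prior_variance <= 0:
            raise ValueError("beta prior variance must be positive")


#: the two alternative tau^2 priors used for sensitivity reruns
SENSITIVITY_PRIORS = (
    PriorSpec(tau2_shape=0.5, tau2_scale=0.005),
    PriorSpec(tau2_shape=1.0, tau2_scale=0.05),
)


@dataclass
class CARParams:
    rho_s: float
    rho_t: float
    tau2: float

    def __post_init__(self):
        if not (0.0 < self.rho_s < 1.0 and 0.0 < self.rho_t < 1.0):
            raise ValueError("rho_s and rho_t must lie strictly in (0, 1)")
        if self.tau2 <= 0:
            raise ValueError("tau2 must be positive")


@dataclass
class EffectState:
    phi: np.ndarray  # (N, T)

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.isfinite(self.phi).all():
            raise ValueError("phi must be finite")


@dataclass
class CoefficientState:
    intercept: float
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not (np.isfinite(self.intercept) and np.isfinite(self.beta).all()):
            raise ValueError("coefficients must be finite")


@dataclass
class ModelState:
    coef: CoefficientState
    effects: EffectState
    car: CARParams


@dataclass(frozen=True)
class MCMCConfig:
    """Chain bookkeeping. Retained draws per chain = (iterations - burn_in)/thin."""

    iterations: int
    burn_in: int
    thin: int = 1
    chains: int = 3
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1 or (self.iterations - self.burn_in) % self.thin != 0:
            raise ValueError("(iterations - burn_in) must be divisible by thin")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @property
    def retained_total(self) -> int:
        return self.chains * self.retained_per_chain


@dataclass
class PosteriorSamples:
    """Retained draws, shape (chains, draws, ...) per parameter."""

    intercept: np.ndarray
    beta: np.ndarray          # (chains, draws, p)
    tau2: np.ndarray
    rho_s: np.ndarray
    rho_t: np.ndarray
    phi: np.ndarray           # (chains, draws, N, T)
    mu: np.ndarray            # (chains, draws, N, T) fitted means E*exp(...)
    config: MCMCConfig
    covariate_names: list = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.intercept.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.intercept.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains (chain-major order)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def scalar_chains(self) -> dict:
        """Scalar-parameter chains for convergence diagnostics."""
        out = {"intercept": self.intercept, "tau2": self.tau2,
               "rho_s": self.rho_s, "rho_t": self.rho_t}
        names = self.covariate_names or [f"x{j}" for j in range(self.beta.shape[2])]
        for j, nm in enumerate(names):
            out[f"beta_{nm}"] = self.beta[:, :, j]
        return out


# ---------------------------------------------------------------------------
# Log-posterior pieces

def ar1_diagonal_weights(T: int, rho_t: float) -> np.ndarray:
    """Diagonal of the AR(1) precision chain in time.

    Year t's quadratic self-weight is 1 + rho_t^2 when a later year links to
    it and 1 for the final year; the joint precision over the stacked
    effects is kron(A, Q)/tau^2 with A tridiagonal (off-diagonal -rho_t).
    """
    att = np.ones(T)
    if T > 1:
        att[:-1] += rho_t ** 2
    return att


def car_quadratic_form(phi: np.ndarray, Q: np.ndarray, rho_t: float) -> float:
    """S(phi) = phi_1' Q phi_1 + sum_t (phi_t - rho_t phi_{t-1})' Q (phi_t - rho_t phi_{t-1})."""
    phi = np.asarray(phi, dtype=float)
    resid = phi.copy()
    if phi.shape[1] > 1:
        resid[:, 1:] -= rho_t * phi[:, :-1]
    return float(np.sum(resid * (Q @ resid)))


def log_posterior_terms(state: ModelState, panel, graph: RegionGraph,
                        priors: PriorSpec) -> dict:
    """Components of the joint log posterior at ``state``.

    Returns a dict with the Poisson log-likelihood (with all constants, so
    it is comparable across models), the Gaussian random-effect log density
    (the exact multivariate-normal log-pdf of the stacked effects), and the
    prior log densities; ``total`` sums them. ``panel`` may be None, giving
    the flat-likelihood (prior-only) posterior.
    """
    phi = state.effects.phi
    N, T = phi.shape
    car = state.car
    Q = leroux_precision(graph, car.rho_s)
    S = car_quadratic_form(phi, Q, car.rho_t)
    logdetQ = log_det_precision(graph, car.rho_s)
    # det of the joint precision kron(A, Q)/tau^2 is det(Q)^T / tau^(2NT)
    # because the AR(1) factor A has unit determinant.
    gaussian = (-0.5 * N * T * np.log(2 * np.pi)
                - 0.5 * N * T * np.log(car.tau2)
                + 0.5 * T * logdetQ
                - S / (2.0 * car.tau2))
    sh, sc = priors.tau2_shape, priors.tau2_scale
    tau2_prior = (sh * np.log(sc) - gammaln(sh)
                  - (sh + 1.0) * np.log(car.tau2) - sc / car.tau2)
    v = priors.beta_prior_variance
    coefs = np.concatenate([[state.coef.intercept], state.coef.beta])
    coef_prior = float(-0.5 * len(coefs) * np.log(2 * np.pi * v)
                       - 0.5 * np.sum(coefs ** 2) / v)
    if panel is None:
        poisson = 0.0
    else:
        eta = (state.coef.intercept
               + panel.X @ state.coef.beta
               + phi)
        lam = panel.E * np.exp(eta)
        poisson = float(np.sum(panel.O * (np.log(panel.E) + eta) - lam
                               - gammaln(panel.O + 1.0)))
    total = poisson + gaussian + tau2_prior + coef_prior
    return {"poisson": poisson, "gaussian_effects": float(gaussian),
            "tau2_prior": float(tau2_prior), "coef_prior": coef_prior,
            "total": float(total)}


# ---------------------------------------------------------------------------
# Individual updates (exposed for testing; the sampler below drives them)

def update_tau2(S: float, n_cells: int, priors: PriorSpec, rng) -> float:
    """Exact conjugate draw tau^2 ~ IG(shape + NT/2, scale + S/2)."""
    shape = priors.tau2_shape + 0.5 * n_cells
    scale = priors.tau2_scale + 0.5 * S
    return float(scale / rng.gamma(shape))


def _truncated_normal(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    if b - a < 1e-14:  # mass numerically outside the window: clamp to edge
        return lo + 1e-12 if mean < lo else hi - 1e-12
    u = rng.uniform(a, b)
    x = mean + sd * ndtri(u)
    return float(min(max(x, lo + 1e-12), hi - 1e-12))


def update_rho_t(phi: np.ndarray, Q: np.ndarray, tau2: float, rng) -> float:
    """Exact Gibbs draw of the temporal-autocorrelation parameter.

    The full conditional is Gaussian in rho_t with mean
    (sum_t phi_{t-1}' Q phi_t) / D and variance tau^2 / D, where
    D = sum_t phi_{t-1}' Q phi_{t-1}, truncated to (0, 1). Degenerate phi
    (D = 0) falls back to the Uniform(0, 1) prior.
    """
    T = phi.shape[1]
    if T < 2:
        return float(rng.uniform(0.0, 1.0))
    Qphi = Q @ phi
    D = float(np.sum(phi[:, :-1] * Qphi[:, :-1]))
    if D <= 0.0:
        return float(rng.uniform(0.0, 1.0))
    C = float(np.sum(phi[:, 1:] * Qphi[:, :-1]))
    return _truncated_normal(C / D, np.sqrt(tau2 / D), 0.0, 1.0, rng)


def update_rho_s(rho_s: float, phi: np.ndarray, graph: RegionGraph,
                 rho_t: float, tau2: float, scale: float, rng):
    """Random-walk Metropolis step for the spatial-smoothing parameter.

    Target: (T/2) log det Q(rho_s) - S(phi; rho_s, rho_t)/(2 tau^2) on
    (0, 1); proposals outside the interval are rejected outright.
    Returns (new rho_s, accepted flag).
    """
    T = phi.shape[1]
    prop = rho_s + scale * rng.standard_normal()
    if not 0.0 < prop < 1.0:
        return rho_s, False
    Q_cur = leroux_precision(graph, rho_s)
    Q_prop = leroux_precision(graph, prop)
    log_ratio = (0.5 * T * (log_det_precision(graph, prop)
                            - log_det_precision(graph, rho_s))
                 - (car_quadratic_form(phi, Q_prop, rho_t)
                    - car_quadratic_form(phi, Q_cur, rho_t)) / (2.0 * tau2))
    if np.log(rng.uniform()) < log_ratio:
        return float(prop), True
    return rho_s, False


def _spatial_coloring(W: np.ndarray) -> np.ndarray:
    """Greedy proper colouring of the spatial graph (colors as ints).

    Tries natural and highest-degree-first orders and keeps whichever uses
    fewer colours — fewer colour classes mean fewer vectorised blocks per
    sweep.
    """
    n = W.shape[0]
    neighbors = [np.nonzero(W[i])[0] for i in range(n)]

    def greedy(order):
        colors = -np.ones(n, dtype=int)
        for i in order:
            taken = {colors[j] for j in neighbors[i] if colors[j] >= 0}
            c = 0
            while c in taken:
                c += 1
            colors[i] = c
        return colors

    best = None
    for order in (range(n), np.argsort(-W.sum(axis=1))):
        colors = greedy(order)
        if best is None or colors.max() < best.max():
            best = colors
    return best


def phi_color_masks(graph: RegionGraph, T: int):
    """Conditionally independent blocks of phi cells.

    Cells (i, t) and (j, s) interact in the joint Gaussian precision iff
    kron(A, Q)_{(t,i),(s,j)} is nonzero: same year and spatially adjacent,
    or the same/adjacent region in an adjacent year. A proper colouring of
    the spatial graph crossed with year parity therefore separates the
    cells into blocks whose members never interact, so block proposals are
    exactly equivalent to one-at-a-time updates. Returns a list of
    (row_indices, col_indices) pairs (the block is their cross product).
    """
    colors = _spatial_coloring(graph.W)
    blocks = []
    for c in range(colors.max() + 1):
        rows = np.nonzero(colors == c)[0]
        for par in (0, 1) if T > 1 else (0,):
            cols = np.arange(par, T, 2)
            if rows.size and cols.size:
                blocks.append((rows, cols))
    return blocks


def update_phi(phi, Q, qdiag, rho_t, tau2, O, E_exp_eta, scales, masks, rng,
               flat_likelihood: bool = False):
    """One element-wise Metropolis sweep over all random-effect cells.

    ``E_exp_eta`` is E * exp(a + x'beta) so the current Poisson mean is
    E_exp_eta * exp(phi). Updates run block by block over the colour
    classes from :func:`phi_color_masks`, each block vectorised; returns
    (phi, accepted bool array of shape (N, T)). With ``flat_likelihood``
    the Poisson term is dropped, so the sweep targets the CAR prior itself
    (used for prior-recovery checks).
    """
    N, T = phi.shape
    att = ar1_diagonal_weights(T, rho_t)
    accepted = np.zeros((N, T), dtype=bool)
    phi = phi.copy()
    for rows, cols in masks:
        ix = np.ix_(rows, cols)
        M = Q[rows] @ phi  # (len(rows), T)
        # linear coefficient of the CAR quadratic form in each cell's value
        L = att[cols] * (M[:, cols] - qdiag[rows, None] * phi[ix])
        inner = cols > 0
        if inner.any():
            L[:, inner] -= rho_t * M[:, cols[inner] - 1]
        inner = cols < T - 1
        if inner.any():
            L[:, inner] -= rho_t * M[:, cols[inner] + 1]
        cur = phi[ix]
        prop = cur + scales[ix] * rng.standard_normal(cur.shape)
        quad = att[cols] * qdiag[rows, None]
        dS = quad * (prop ** 2 - cur ** 2) + 2.0 * L * (prop - cur)
        log_ratio = -dS / (2.0 * tau2)
        if not flat_likelihood:
            log_ratio += (O[ix] * (prop - cur)
                          - E_exp_eta[ix] * np.exp(cur) * np.expm1(prop - cur))
        acc = np.log(rng.uniform(size=cur.shape)) < log_ratio
        phi[ix] = np.where(acc, prop, cur)
        accepted[ix] = acc
    return phi, accepted


def translation_move(intercept, phi, rho_s, rho_t, tau2, prior_var, scale, rng):
    """Joint shift (a, phi) -> (a + d, phi - d) with symmetric Gaussian d.

    The Poisson likelihood depends on a and phi only through their sum, so
    this move costs nothing in likelihood terms and decorrelates the weakly
    identified intercept/effect-mean direction. Because Q 1 = (1 - rho_s) 1
    (the Laplacian annihilates constants), the change in the CAR quadratic
    form reduces to closed form in the per-year residual sums. The exact
    joint posterior is preserved (plain Metropolis on the joint state).
    Returns (intercept, phi, accepted).
    """
    N, T = phi.shape
    d = scale * rng.standard_normal()
    resid_sums = phi.sum(axis=0).copy()
    if T > 1:
        resid_sums[1:] -= rho_t * phi[:, :-1].sum(axis=0)
    shift = np.full(T, (1.0 - rho_t) * d)
    shift[0] = d
    one_Q_one = (1.0 - rho_s) * N
    # S(phi - d*1) - S(phi), using 1'Q r_t = (1 - rho_s) * sum(r_t)
    dS = float(np.sum(-2.0 * shift * (1.0 - rho_s) * resid_sums
                      + shift ** 2 * one_Q_one))
    log_ratio = (-dS / (2.0 * tau2)
                 - ((intercept + d) ** 2 - intercept ** 2) / (2.0 * prior_var))
    if np.log(rng.uniform()) < log_ratio:
        return intercept + d, phi - d, True
    return intercept, phi, False


def update_coefficients(intercept, beta, X, O, E, phi, prior_var, scales, rng):
    """Per-coordinate random-walk Metropolis on (a, beta_1..p).

    Returns (intercept, beta, accepted flags). The Gaussian prior is
    mean-zero with variance ``prior_var`` on every coordinate.
    """
    p = beta.size
    accepted = np.zeros(p + 1, dtype=bool)
    lam = E * np.exp(intercept + X @ beta + phi)
    O_sum = float(O.sum())
    # intercept: shifting a by d multiplies every mean by e^d
    d = scales[0] * rng.standard_normal()
    log_ratio = (d * O_sum - np.expm1(d) * float(lam.sum())
                 - ((intercept + d) ** 2 - intercept ** 2) / (2.0 * prior_var))
    if np.log(rng.uniform()) < log_ratio:
        intercept += d
        lam *= np.exp(d)
        accepted[0] = True
    for j in range(p):
        d = scales[j + 1] * rng.standard_normal()
        xj = X[:, :, j]
        log_ratio = (d * float(np.sum(O * xj))
                     - float(np.sum(lam * np.expm1(d * xj)))
                     - ((beta[j] + d) ** 2 - beta[j] ** 2) / (2.0 * prior_var))
        if np.log(rng.uniform()) < log_ratio:
            beta = beta.copy()
            beta[j] += d
            lam = lam * np.exp(d * xj)
            accepted[j + 1] = True
    return intercept, beta, accepted


# ---------------------------------------------------------------------------
# The driver

def _adapt(log_scale: np.ndarray, acc_count: np.ndarray, n_batch: int,
           batch_idx: int, target: float) -> None:
    """Batch Robbins-Monro adaptation of log proposal scales (in place)."""
    delta = min(0.1, 1.0 / np.sqrt(batch_idx + 1.0))
    rate = acc_count / n_batch
    log_scale += np.where(rate > target, delta, -delta)
    np.clip(log_scale, -10.0, 5.0, out=log_scale)


def run_mcmc(panel, graph: RegionGraph, priors: PriorSpec, config: MCMCConfig,
             fix_rho_s: float | None = None, fix_rho_t: float | None = None,
             fix_tau2: float | None = None, flat_likelihood: bool = False,
             store_phi: bool = True) -> PosteriorSamples:
    """Fit the spatio-temporal CAR Poisson model.

    Runs ``config.chains`` independent chains (seeded ``seed + chain``),
    each sweeping coefficients -> phi -> tau2 -> rho_t -> rho_s, retaining
    every ``thin``-th draw after burn-in. Proposal scales adapt toward 44%
    acceptance during burn-in only, preserving the ergodicity of the
    post-burn-in chain. ``fix_rho_s`` / ``fix_rho_t`` / ``fix_tau2`` pin a
    variance parameter (used for limit and prior-recovery checks);
    ``flat_likelihood`` drops the Poisson term so the chain samples the
    effect prior.
    """
    N, T = panel.n_regions, panel.n_years
    p = panel.n_covariates
    X, O, E = panel.X, panel.O.astype(float), panel.E
    n_keep = config.retained_per_chain
    masks = phi_color_masks(graph, T)

    out = {
        "intercept": np.empty((config.chains, n_keep)),
        "beta": np.empty((config.chains, n_keep, p)),
        "tau2": np.empty((config.chains, n_keep)),
        "rho_s": np.empty((config.chains, n_keep)),
        "rho_t": np.empty((config.chains, n_keep)),
        "phi": np.empty((config.chains, n_keep, N, T)) if store_phi else np.empty((config.chains, 0, N, T)),
        "mu": np.empty((config.chains, n_keep, N, T)),
    }
    acceptance = {}

    for chain in range(config.chains):
        rng = np.random.default_rng(config.seed + chain)
        intercept = float(np.log(O.sum() / E.sum())) if not flat_likelihood else 0.0
        beta = np.zeros(p)
        phi = np.zeros((N, T))
        tau2 = 0.01 if fix_tau2 is None else float(fix_tau2)
        rho_s = 0.5 if fix_rho_s is None else float(fix_rho_s)
        rho_t = 0.5 if fix_rho_t is None else float(fix_rho_t)
        Q = leroux_precision(graph, rho_s)
        qdiag = np.diag(Q).copy()

        log_s_coef = np.full(p + 1, np.log(0.1))
        log_s_phi = np.full((N, T), np.log(0.5))
        log_s_rho = np.log(0.05)
        log_s_trans = np.log(0.1)
        acc_coef = np.zeros(p + 1)
        acc_phi = np.zeros((N, T))
        acc_rho = 0.0
        acc_trans = 0.0
        batch = 0
        kept = 0
        total_acc_phi = np.zeros((N, T))
        total_acc_coef = np.zeros(p + 1)
        total_acc_rho = 0
        post_burn_sweeps = 0

        for it in range(1, config.iterations + 1):
            if not flat_likelihood:
                intercept, beta, acc = update_coefficients(
                    intercept, beta, X, O, E, phi,
                    priors.beta_prior_variance, np.exp(log_s_coef), rng)
                acc_coef += acc
                if it > config.burn_in:
                    total_acc_coef += acc
                intercept, phi, t_acc = translation_move(
                    intercept, phi, rho_s, rho_t, tau2,
                    priors.beta_prior_variance, np.exp(log_s_trans), rng)
                acc_trans += t_acc
            E_exp_eta = E * np.exp(intercept + X @ beta)
            phi, acc = update_phi(phi, Q, qdiag, rho_t, tau2, O, E_exp_eta,
                                  np.exp(log_s_phi), masks, rng,
                                  flat_likelihood=flat_likelihood)
            acc_phi += acc
            if fix_tau2 is None:
                S = car_quadratic_form(phi, Q, rho_t)
                tau2 = update_tau2(S, N * T, priors, rng)
            if fix_rho_t is None:
                rho_t = update_rho_t(phi, Q, tau2, rng)
            if fix_rho_s is None:
                rho_s, accepted = update_rho_s(rho_s, phi, graph, rho_t, tau2,
                                               np.exp(log_s_rho), rng)
                if accepted:
                    Q = leroux_precision(graph, rho_s)
                    qdiag = np.diag(Q).copy()
                    acc_rho += 1
                    if it > config.burn_in:
                        total_acc_rho += 1

            if it <= config.burn_in:
                if it % config.adapt_interval == 0:
                    _adapt(log_s_coef, acc_coef, config.adapt_interval, batch,
                           config.target_accept)
                    _adapt(log_s_phi, acc_phi, config.adapt_interval, batch,
                           config.target_accept)
                    if fix_rho_s is None:
                        arr = np.array([log_s_rho])
                        _adapt(arr, np.array([acc_rho]), config.adapt_interval,
                               batch, config.target_accept)
                        log_s_rho = float(arr[0])
                    arr = np.array([log_s_trans])
                    _adapt(arr, np.array([acc_trans]), config.adapt_interval,
                           batch, config.target_accept)
                    log_s_trans = float(arr[0])
                    acc_coef[:] = 0
                    acc_phi[:] = 0
                    acc_rho = 0
                    acc_trans = 0.0
                    batch += 1
            else:
                post_burn_sweeps += 1
                total_acc_phi += acc
                if (it - config.burn_in) % config.thin == 0:
                    out["intercept"][chain, kept] = intercept
                    out["beta"][chain, kept] = beta
                    out["tau2"][chain, kept] = tau2
                    out["rho_s"][chain, kept] = rho_s
                    out["rho_t"][chain, kept] = rho_t
                    if store_phi:
                        out["phi"][chain, kept] = phi
                    out["mu"][chain, kept] = E * np.exp(intercept + X @ beta + phi)
                    kept += 1
        denom = max(post_burn_sweeps, 1)
        acceptance[f"chain{chain}"] = {
            "phi_mean_rate": float(total_acc_phi.mean() / denom),
            "coef_rates": (total_acc_coef / denom).tolist(),
            "rho_s_rate": float(total_acc_rho / denom),
        }

    return PosteriorSamples(
        intercept=out["intercept"], beta=out["beta"], tau2=out["tau2"],
        rho_s=out["rho_s"], rho_t=out["rho_t"], phi=out["phi"], mu=out["mu"],
        config=config, covariate_names=list(panel.covariate_names),
        acceptance=acceptance,
    )
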