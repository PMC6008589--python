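"""Gaussian mixed-model equations and robust MAP predictors.

The model is y = W alpha + Z g + e with g ~ N(0, K sigma_g2) and residuals
that are Gaussian (GBLUP), scaled Student-t (TMAP) or Laplace (LMAP), each
with Var(e_i) = sigma_e2 / n_i where n_i is the replication count of record
i.  The robust predictors are posterior modes found by re-iterating
Henderson's mixed-model equations with per-observation weights:

* TMAP: weights d_i = n_i / (1 + n_i r_i^2 / (tau_e2 nu)), penalty
  lambda'' K^-1 with lambda'' = lambda' nu/(nu+1), lambda' = tau_e2/sigma_g2.
  The functional iteration is the EM algorithm for the normal/chi-square
  scale mixture, so the log-posterior ascends monotonically.
* LMAP: weights m_i = n_i / |r_i| (floored), penalty omega K^-1 with
  omega = sigma_e2 / (2 sqrt(2) sigma_g2).  The iteration is a
  majorize-minimize scheme for the L1-penalized objective
  J(g) = sum n_i |r_i| + (omega/2) g'K^-1 g, so J descends monotonically.

Gaussian weights are n_i exactly and the solution is BLUP/BLUE in one solve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .relmat import KinshipMatrix

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


@dataclass
class DispersionParams:
    """Variance components and every regularizer derived from them.

    nu is the t degrees of freedom (> 2 so the variance exists); tau_e2 is
    the t scale (nu-2)/nu * sigma_e2, chosen so Var(e) = sigma_e2 for every
    residual family.
    """

    sigma_g2: float
    sigma_e2: float
    nu: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_g2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variances must be positive")
        if self.nu is not None and self.nu <= 2:
            raise ValueError("t degrees of freedom must exceed 2")

    @property
    def lam(self) -> float:
        """Gaussian regularizer lambda = sigma_e2 / sigma_g2."""
        return self.sigma_e2 / self.sigma_g2

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def tau_e2(self) -> float:
        if self.nu is None:
            raise ValueError("tau_e2 requires nu")
        return (self.nu - 2.0) / self.nu * self.sigma_e2

    @property
    def lambda_prime(self) -> float:
        """t regularizer lambda' = tau_e2 / sigma_g2 = lambda (nu-2)/nu."""
        return self.tau_e2 / self.sigma_g2

    @property
    def lambda_dprime(self) -> float:
        """Iteration penalty lambda'' = lambda' nu / (nu + 1)."""
        if self.nu is None:
            raise ValueError("lambda_dprime requires nu")
        return self.lambda_prime * self.nu / (self.nu + 1.0)

    @property
    def omega(self) -> float:
        """Laplace regularizer omega = sigma_e2 / (2 sqrt(2) sigma_g2)."""
        return self.sigma_e2 / (2.0 * SQRT2 * self.sigma_g2)


@dataclass
class ModelData:
    """Phenotypes with designs and kinship.

    W is the optional fixed-effect design (full column rank); Z defaults to
    the identity (every individual phenotyped once); n_counts defaults to 1.
    """

    y: np.ndarray
    K: KinshipMatrix
    W: np.ndarray | None = None
    Z: np.ndarray | None = None
    n_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        r = self.K.n
        if self.Z is None:
            if n != r:
                raise ValueError("Z omitted but len(y) != K dimension")
            self.Z = np.eye(n)
        else:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.shape != (n, r):
                raise ValueError("Z shape inconsistent with y and K")
        if self.W is not None:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.ndim == 1:
                self.W = self.W[:, None]
            if self.W.shape[0] != n:
                raise ValueError("W row count != len(y)")
            if np.linalg.matrix_rank(self.W) < self.W.shape[1]:
                raise ValueError("W is rank deficient")
        if self.n_counts is None:
            self.n_counts = np.ones(n)
        else:
            self.n_counts = np.asarray(self.n_counts, dtype=float).ravel()
            if self.n_counts.size != n or np.any(self.n_counts <= 0):
                raise ValueError("n_counts must be positive, length n")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def r(self) -> int:
        return self.K.n

    @property
    def identity_design(self) -> bool:
        return self.W is None and self.Z.shape[0] == self.Z.shape[1] and np.array_equal(
            self.Z, np.eye(self.Z.shape[0])
        )


@dataclass
class FitResult:
    """Solution of one (possibly reweighted) mixed-model system."""

    alpha: np.ndarray
    g: np.ndarray
    weights: np.ndarray
    method: str
    n_iter: int = 1
    converged: bool = True
    objective_trace: list[float] = field(default_factory=list)

    @property
    def mu(self) -> np.ndarray | None:
        return None  # populated via fitted_values(data)

    def fitted_values(self, data: ModelData) -> np.ndarray:
        mu = data.Z @ self.g
        if data.W is not None and self.alpha.size:
            mu = mu + data.W @ self.alpha
        return mu


@dataclass
class PosteriorCovariance:
    matrix: np.ndarray
    scale_note: str
    psd_flag: bool


def solve_weighted_mme(
    data: ModelData,
    weights: np.ndarray,
    regularizer: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One solve of the weighted mixed-model equations.

    Returns (alpha, g) solving the symmetric system

        [W'OW   W'OZ ] [alpha]   [W'Oy]
        [Z'OW   Z'OZ + c K^-1] [g] = [Z'Oy]

    with O = Diag(weights) and c the penalty multiplying K^-1.  No explicit
    inverse of the coefficient matrix is formed.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if regularizer <= 0:
        raise ValueError("regularizer must be positive")
    Z, W, y = data.Z, data.W, data.y
    Kinv = data.K.inverse()
    ZO = Z.T * w  # r x n
    Cgg = ZO @ Z + regularizer * Kinv
    rhs_g = ZO @ y
    if W is None:
        try:
            cf = cho_factor(Cgg, lower=True)
        except LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular genetic block of the mixed-model equations"
            ) from err
        return np.zeros(0), cho_solve(cf, rhs_g)
    WO = W.T * w
    C = np.block([[WO @ W, WO @ Z], [ZO @ W, Cgg]])
    rhs = np.concatenate([WO @ y, rhs_g])
    try:
        cf = cho_factor(C, lower=True)
    except LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular mixed-model coefficient matrix (fixed-effect block?)"
        ) from err
    sol = cho_solve(cf, rhs)
    f = W.shape[1]
    return sol[:f], sol[f:]


def fit_gblup(data: ModelData, params: DispersionParams) -> FitResult:
    """Gaussian BLUP/BLUE: weights n_i, penalty lambda.

    For Z = I, no W and n_i = 1 this is g = (I + lambda K^-1)^-1 y; with
    replication it is g = (N + lambda K^-1)^-1 N y.
    """
    alpha, g = solve_weighted_mme(data, data.n_counts, params.lam)
    return FitResult(
        alpha=alpha, g=g, weights=data.n_counts.copy(), method="GBLUP"
    )


def tmap_weights(
    residuals: np.ndarray,
    n_counts: np.ndarray,
    tau_e2: float,
    nu: float,
) -> np.ndarray:
    """t-model attenuation weights d_i = n_i / (1 + n_i r_i^2/(tau_e2 nu))."""
    if tau_e2 <= 0:
        raise ValueError("tau_e2 must be positive")
    if nu <= 2:
        raise ValueError("nu must exceed 2")
    r = np.asarray(residuals, dtype=float)
    n = np.asarray(n_counts, dtype=float)
    return n / (1.0 + n * r * r / (tau_e2 * nu))


def lmap_weights(
    residuals: np.ndarray,
    n_counts: np.ndarray,
    floor_eps: float,
) -> np.ndarray:
    """Laplace weights m_i = n_i / max(|r_i|, floor_eps)."""
    if floor_eps <= 0:
        raise ValueError("floor_eps must be positive")
    r = np.abs(np.asarray(residuals, dtype=float))
    n = np.asarray(n_counts, dtype=float)
    return n / np.maximum(r, floor_eps)


def _t_log_posterior(data: ModelData, params: DispersionParams,
                     alpha: np.ndarray, g: np.ndarray) -> float:
    """Unnormalized log conditional posterior under t residuals."""
    mu = data.Z @ g
    if data.W is not None and alpha.size:
        mu = mu + data.W @ alpha
    r = data.y - mu
    tau2, nu = params.tau_e2, params.nu
    loglik = -0.5 * (nu + 1.0) * np.sum(
        np.log1p(data.n_counts * r * r / (tau2 * nu))
    )
    penalty = -0.5 / params.sigma_g2 * float(g @ data.K.inverse() @ g)
    return float(loglik + penalty)


def _l1_objective(data: ModelData, params: DispersionParams,
                  alpha: np.ndarray, g: np.ndarray) -> float:
    """L1-penalized objective J minimized by the LMAP iteration."""
    mu = data.Z @ g
    if data.W is not None and alpha.size:
        mu = mu + data.W @ alpha
    r = data.y - mu
    return float(
        np.sum(data.n_counts * np.abs(r))
        + 0.5 * params.omega * float(g @ data.K.inverse() @ g)
    )


def _init_solution(data: ModelData, params: DispersionParams,
                   init) -> tuple[np.ndarray, np.ndarray]:
    if init is not None:
        alpha, g = init
        return np.asarray(alpha, dtype=float), np.asarray(g, dtype=float)
    fit = fit_gblup(data, params)
    return fit.alpha, fit.g


def fit_tmap(
    data: ModelData,
    params: DispersionParams,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """TMAP by functional (EM) iteration of the reweighted MME.

    Starting values default to the Gaussian solution.  Convergence when
    max|dg| / (1 + max|g|) < tol.  The objective trace (t log-posterior) is
    non-decreasing up to round-off.
    """
    if params.nu is None:
        raise ValueError("TMAP requires nu in params")
    alpha, g = _init_solution(data, params, init)
    trace = [_t_log_posterior(data, params, alpha, g)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = data.Z @ g
        if data.W is not None and alpha.size:
            mu = mu + data.W @ alpha
        d = tmap_weights(data.y - mu, data.n_counts, params.tau_e2, params.nu)
        alpha_new, g_new = solve_weighted_mme(data, d, params.lambda_dprime)
        delta = np.max(np.abs(g_new - g)) / (1.0 + np.max(np.abs(g_new)))
        alpha, g = alpha_new, g_new
        trace.append(_t_log_posterior(data, params, alpha, g))
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("TMAP did not converge in %d iterations", max_iter)
    mu = data.Z @ g
    if data.W is not None and alpha.size:
        mu = mu + data.W @ alpha
    d = tmap_weights(data.y - mu, data.n_counts, params.tau_e2, params.nu)
    return FitResult(alpha=alpha, g=g, weights=d, method="TMAP",
                     n_iter=it, converged=converged, objective_trace=trace)


def fit_tmap_newton(
    data: ModelData,
    params: DispersionParams,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """TMAP by Newton-Raphson on the t log-posterior.

    Uses the negative-Hessian blocks built from Q = D - 2DSD with
    s_i = r_i^2 / (tau_e2 nu), step-halving until the objective does not
    decrease.  Rounds with an indefinite Hessian fall back to one functional
    step.  Convergence when the (scaled) gradient norm drops below tol.
    """
    if params.nu is None:
        raise ValueError("TMAP requires nu in params")
    alpha, g = _init_solution(data, params, init)
    Kinv = data.K.inverse()
    tau2, nu = params.tau_e2, params.nu
    lam2 = params.lambda_dprime
    trace = [_t_log_posterior(data, params, alpha, g)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = data.Z @ g
        if data.W is not None and alpha.size:
            mu = mu + data.W @ alpha
        r = data.y - mu
        d = tmap_weights(r, data.n_counts, tau2, nu)
        s = r * r / (tau2 * nu)
        q = d - 2.0 * d * d * s  # diag of Q = D - 2DSD
        # gradient of L scaled by tau2 nu / (nu + 1)
        grad_g = data.Z.T @ (d * r) - lam2 * (Kinv @ g)
        if data.W is not None:
            grad_a = data.W.T @ (d * r)
            grad = np.concatenate([grad_a, grad_g])
        else:
            grad = grad_g
        gnorm = np.max(np.abs(grad)) / (1.0 + np.max(np.abs(g)))
        if gnorm < tol:
            converged = True
            break
        ZQ = data.Z.T * q
        Hgg = ZQ @ data.Z + lam2 * Kinv
        try:
            if data.W is not None:
                WQ = data.W.T * q
                H = np.block([[WQ @ data.W, WQ @ data.Z], [ZQ @ data.W, Hgg]])
                cf = cho_factor(H, lower=True)
                step = cho_solve(cf, grad)
                f = data.W.shape[1]
                da, dg = step[:f], step[f:]
            else:
                cf = cho_factor(Hgg, lower=True)
                da, dg = np.zeros(0), cho_solve(cf, grad)
        except LinAlgError:
            logger.info("indefinite Hessian at iter %d: functional step", it)
            alpha, g = solve_weighted_mme(data, d, lam2)
            trace.append(_t_log_posterior(data, params, alpha, g))
            continue
        # step-halving on the (maximized) objective
        obj0 = trace[-1]
        t = 1.0
        for _ in range(30):
            a_try = alpha + t * da if alpha.size else alpha
            g_try = g + t * dg
            obj = _t_log_posterior(data, params, a_try, g_try)
            if obj >= obj0 - 1e-12 * (1.0 + abs(obj0)):
                break
            t *= 0.5
        alpha, g = (alpha + t * da if alpha.size else alpha), g + t * dg
        trace.append(_t_log_posterior(data, params, alpha, g))
    if not converged:
        logger.warning("TMAP-NR did not converge in %d iterations", max_iter)
    mu = data.Z @ g
    if data.W is not None and alpha.size:
        mu = mu + data.W @ alpha
    d = tmap_weights(data.y - mu, data.n_counts, tau2, nu)
    return FitResult(alpha=alpha, g=g, weights=d, method="TMAP",
                     n_iter=it, converged=converged, objective_trace=trace)


def fit_lmap(
    data: ModelData,
    params: DispersionParams,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    floor_eps: float | None = None,
    obj_tol: float = 1e-9,
) -> FitResult:
    """LMAP by majorize-minimize iteration of the reweighted MME.

    floor_eps defaults to 1e-8 * SD(y) (the Laplace weight n_i/|r_i| is
    unbounded at a zero residual).  The objective trace (J) is
    non-increasing up to the floor-induced tolerance.

    The L1 solution typically interpolates a few records, and at such kinks
    the reweighted iteration contracts sublinearly: the step criterion
    max|dg|/(1+max|g|) < tol alone can be unattainable.  Convergence is
    therefore also declared when the relative decrease of J over one round
    falls below obj_tol — further movement of g is then below the
    resolution the residual floor induces.
    """
    if floor_eps is None:
        sd = float(np.std(data.y))
        floor_eps = 1e-8 * (sd if sd > 0 else 1.0)
    alpha, g = _init_solution(data, params, init)
    trace = [_l1_objective(data, params, alpha, g)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = data.Z @ g
        if data.W is not None and alpha.size:
            mu = mu + data.W @ alpha
        m = lmap_weights(data.y - mu, data.n_counts, floor_eps)
        alpha_new, g_new = solve_weighted_mme(data, m, params.omega)
        delta = np.max(np.abs(g_new - g)) / (1.0 + np.max(np.abs(g_new)))
        alpha, g = alpha_new, g_new
        trace.append(_l1_objective(data, params, alpha, g))
        obj_delta = abs(trace[-2] - trace[-1]) / (1.0 + abs(trace[-1]))
        if delta < tol or obj_delta < obj_tol:
            converged = True
            break
    if not converged:
        logger.warning("LMAP did not converge in %d iterations", max_iter)
    mu = data.Z @ g
    if data.W is not None and alpha.size:
        mu = mu + data.W @ alpha
    m = lmap_weights(data.y - mu, data.n_counts, floor_eps)
    return FitResult(alpha=alpha, g=g, weights=m, method="LMAP",
                     n_iter=it, converged=converged, objective_trace=trace)


def posterior_covariance(
    fit: FitResult, data: ModelData, params: DispersionParams
) -> PosteriorCovariance:
    """Approximate posterior covariance of (alpha, g) at the converged fit.

    Gaussian: exact, sigma_e2 * [MME blocks with N and lambda K^-1]^-1.
    TMAP: tau_e2 nu/(nu+1) * [blocks with Q = D - 2DSD, lambda'' K^-1]^-1
    (may be indefinite in the tails; psd_flag reports the eigenvalue check).
    LMAP: sigma_e2/(2 sqrt 2) * [blocks with M, omega K^-1]^-1; the absolute
    scale inherits the Laplace parameterization ambiguity (see scale_note).
    """
    if not fit.converged:
        raise ValueError("posterior covariance requires a converged fit")
    Kinv = data.K.inverse()
    r = data.y - fit.fitted_values(data)
    if fit.method == "GBLUP":
        w = data.n_counts
        penalty = params.lam
        scale = params.sigma_e2
        note = "sigma_e2 * inv(MME); exact under Gaussian residuals"
    elif fit.method == "TMAP":
        d = fit.weights
        s = r * r / (params.tau_e2 * params.nu)
        w = d - 2.0 * d * d * s
        penalty = params.lambda_dprime
        scale = params.tau_e2 * params.nu / (params.nu + 1.0)
        note = "tau_e2*nu/(nu+1) * inv(Q-blocks); Gaussian approximation"
    elif fit.method == "LMAP":
        w = fit.weights
        penalty = params.omega
        scale = params.sigma_e2 / (2.0 * SQRT2)
        note = ("sigma_e2/(2 sqrt 2) * inv(M-blocks); absolute scale "
                "inherits the Laplace parameterization ambiguity")
    else:
        raise ValueError(f"unknown method {fit.method!r}")
    ZW = data.Z.T * w
    Hgg = ZW @ data.Z + penalty * Kinv
    if data.W is not None:
        WW = data.W.T * w
        H = np.block([[WW @ data.W, WW @ data.Z], [ZW @ data.W, Hgg]])
    else:
        H = Hgg
    H = 0.5 * (H + H.T)
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular curvature matrix") from err
    V = scale * 0.5 * (Hinv + Hinv.T)
    eigmin = float(np.min(np.linalg.eigvalsh(H)))
    return PosteriorCovariance(
        matrix=V, scale_note=note, psd_flag=bool(eigmin >= -1e-10)
    )


def effective_shrinkage(fit: FitResult, params: DispersionParams) -> np.ndarray:
    """Per-observation effective shrinkage (regularization x attenuation).

    GBLUP: constant lambda / n_i; TMAP: lambda'' / d_i; LMAP: omega / m_i.
    """
    if fit.method == "GBLUP":
        return params.lam / fit.weights
    if fit.method == "TMAP":
        return params.lambda_dprime / fit.weights
    if fit.method == "LMAP":
        return params.omega / fit.weights
    raise ValueError(f"unknown method {fit.method!r}")
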