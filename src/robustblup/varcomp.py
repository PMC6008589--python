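"""Variance-component estimation and regularization-parameter derivation.

MINQUE solves, non-iteratively, a 2x2 system of traces built from a guessed
variance ratio.  For the zero-means model y = g + e with Var(y) =
K sigma_g2 + I sigma_e2, put lambda_guess = (1 - h2_guess)/h2_guess and
V* = K / lambda_guess + I; then

    [tr(K V*^-1 K V*^-1)  tr(K V*^-2)] [sigma_g2]   [y' V*^-1 K V*^-1 y]
    [tr(K V*^-2)          tr(V*^-2)  ] [sigma_e2] = [y' V*^-2 y        ]

The estimator is unbiased at any guess; everything is computed in the
eigenbasis of K, so a single symmetric eigendecomposition serves a whole
grid of guesses.  Spectral maximum likelihood profiles sigma_g2 out and
optimizes the Gaussian log-likelihood over the variance ratio in the same
eigenbasis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .mixedmodels import DispersionParams
from .relmat import KinshipMatrix

logger = logging.getLogger(__name__)


@dataclass
class VarianceEstimate:
    sigma_g2_hat: float
    sigma_e2_hat: float
    guess_h2: float | None = None
    negative_flag: bool = False
    fallback_applied: str = "none"
    boundary_flag: bool = False

    @property
    def h2_hat(self) -> float:
        return self.sigma_g2_hat / (self.sigma_g2_hat + self.sigma_e2_hat)


@dataclass
class HeritabilityGrid:
    """Grids of heritability and t degrees-of-freedom values."""

    h2_values: np.ndarray
    nu_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.h2_values = np.asarray(self.h2_values, dtype=float)
        if np.any(self.h2_values <= 0) or np.any(self.h2_values >= 1):
            raise ValueError("h2 grid must lie in (0, 1)")
        if np.any(np.diff(self.h2_values) <= 0):
            raise ValueError("h2 grid must be strictly increasing")
        if self.nu_values is not None:
            self.nu_values = np.asarray(self.nu_values, dtype=float)
            if np.any(self.nu_values <= 2):
                raise ValueError("nu grid must exceed 2")
            if np.any(np.diff(self.nu_values) <= 0):
                raise ValueError("nu grid must be strictly increasing")

    @classmethod
    def regular(cls, start: float = 0.05, stop: float = 0.95,
                step: float = 0.05,
                nu_values: np.ndarray | None = None) -> "HeritabilityGrid":
        """Evenly spaced heritability grid, endpoints included."""
        n = int(round((stop - start) / step)) + 1
        return cls(h2_values=start + step * np.arange(n), nu_values=nu_values)


def kinship_eigen(K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of K, cached on the matrix."""
    if "_eig" not in K.meta:
        vals, vecs = np.linalg.eigh(K.values)
        K.meta["_eig"] = (vals, vecs)
    return K.meta["_eig"]


def minque_estimate(
    y: np.ndarray,
    K: KinshipMatrix,
    guess_h2: float,
) -> VarianceEstimate:
    """One-shot MINQUE of (sigma_g2, sigma_e2) for centered phenotypes.

    Raises on a (near-)singular trace system, which happens when K and I are
    confounded (e.g. K = I) and the two components are not identifiable.
    """
    if not (0.0 < guess_h2 < 1.0):
        raise ValueError("guess_h2 must be in (0, 1)")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != K.n:
        raise ValueError("y length does not match K")
    lam_guess = (1.0 - guess_h2) / guess_h2
    evals, evecs = kinship_eigen(K)
    w = evals / lam_guess + 1.0  # eigenvalues of V*
    z = evecs.T @ y
    iw2 = 1.0 / (w * w)
    c11 = float(np.sum(evals * evals * iw2))
    c12 = float(np.sum(evals * iw2))
    c22 = float(np.sum(iw2))
    q1 = float(np.sum(evals * z * z * iw2))
    q2 = float(np.sum(z * z * iw2))
    C = np.array([[c11, c12], [c12, c22]])
    det = c11 * c22 - c12 * c12
    if abs(det) < 1e-10 * max(c11 * c22, 1.0):
        raise np.linalg.LinAlgError(
            "MINQUE trace system singular: genetic and residual components "
            "are not identifiable for this K (is K proportional to I?)"
        )
    sg2, se2 = np.linalg.solve(C, np.array([q1, q2]))
    return VarianceEstimate(
        sigma_g2_hat=float(sg2),
        sigma_e2_hat=float(se2),
        guess_h2=guess_h2,
        negative_flag=bool(sg2 <= 0 or se2 <= 0),
    )


def ml_estimate(
    y: np.ndarray,
    K: KinshipMatrix,
    h2_bounds: tuple[float, float] = (1e-6, 1.0 - 1e-6),
) -> VarianceEstimate:
    """Spectral maximum likelihood for y ~ N(0, K sigma_g2 + I sigma_e2).

    Profiles the overall scale out and minimizes the negative log-likelihood
    over h2 by bounded 1-D optimization in the eigenbasis of K.  A solution
    at the h2 bounds is returned with boundary_flag set.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != K.n:
        raise ValueError("y length does not match K")
    n = y.size
    evals, evecs = kinship_eigen(K)
    z2 = (evecs.T @ y) ** 2

    def negloglik(h2: float) -> float:
        lam = (1.0 - h2) / h2
        v = evals + lam  # V / sigma_g2 eigenvalues
        sg2 = float(np.mean(z2 / v))
        if sg2 <= 0:
            return np.inf
        return n * np.log(sg2) + float(np.sum(np.log(v)))

    res = minimize_scalar(negloglik, bounds=h2_bounds, method="bounded",
                          options={"xatol": 1e-10})
    h2 = float(res.x)
    lam = (1.0 - h2) / h2
    sg2 = float(np.mean(z2 / (evals + lam)))
    se2 = sg2 * lam
    boundary = bool(h2 - h2_bounds[0] < 1e-4 or h2_bounds[1] - h2 < 1e-4)
    return VarianceEstimate(
        sigma_g2_hat=sg2, sigma_e2_hat=se2, guess_h2=None,
        negative_flag=False, boundary_flag=boundary,
    )


def apply_negative_fallback(
    est: VarianceEstimate,
    y: np.ndarray,
    K: KinshipMatrix,
    policy: str = "ml",
) -> VarianceEstimate:
    """Replace non-positive MINQUE components.

    policy 'ml': replace the offending component(s) by the full-data
    spectral ML estimate.  policy 'clamp': clamp to 1e-6 * var(y).
    """
    if not est.negative_flag:
        return est
    if policy == "ml":
        ml = ml_estimate(y, K)
        sg2 = est.sigma_g2_hat if est.sigma_g2_hat > 0 else ml.sigma_g2_hat
        se2 = est.sigma_e2_hat if est.sigma_e2_hat > 0 else ml.sigma_e2_hat
    elif policy == "clamp":
        floor = 1e-6 * float(np.var(y))
        sg2 = max(est.sigma_g2_hat, floor)
        se2 = max(est.sigma_e2_hat, floor)
    else:
        raise ValueError(f"unknown fallback policy {policy!r}")
    logger.info("negative MINQUE estimate replaced via %s policy", policy)
    return VarianceEstimate(
        sigma_g2_hat=float(sg2), sigma_e2_hat=float(se2),
        guess_h2=est.guess_h2, negative_flag=True, fallback_applied=policy,
    )


def derive_regularizers(
    sigma_g2: float,
    sigma_e2: float,
    nu: float | None = None,
    sigma_y2: float | None = None,
) -> DispersionParams:
    """Bundle variance components into DispersionParams.

    All regularizers (lambda, lambda', lambda'', omega, tau_e2, h2) are
    derived lazily from the components; sigma_y2, if given, only sanity
    checks that the components roughly sum to the phenotypic variance.
    """
    params = DispersionParams(sigma_g2=sigma_g2, sigma_e2=sigma_e2, nu=nu)
    if sigma_y2 is not None:
        total = sigma_g2 + sigma_e2
        if not np.isclose(total, sigma_y2, rtol=0.5):
            logger.warning(
                "sigma_g2 + sigma_e2 = %.4g far from declared sigma_y2 %.4g",
                total, sigma_y2,
            )
    return params
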