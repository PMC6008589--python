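"""Predictive evaluation: GCV, leave-one-out, bootstrap, train/test.

For the zero-means model all three predictors share the form
g_hat = C^-1 y with C = I + sP: in GBLUP s = lambda, P = K^-1; in TMAP
s = lambda'', P = (KD)^-1; in LMAP s = omega, P = (KM)^-1 (weights frozen
at their converged full-data values).  That form yields the leave-one-out
shortcut

    g_hat_{i,LOO} = (g_hat_i - c_ii y_i) / (1 - c_ii),

with c_ii the i-th diagonal of C^-1; for GBLUP at fixed lambda the shortcut
agrees with refitting n times exactly.  Generalized cross-validation for
GBLUP uses the smoother H(lambda) = (I + lambda K^-1)^-1:

    GCV(lambda) = (1/n) y'(I - H)^2 y / (1 - mean diag H)^2,

evaluated for a whole lambda grid from one eigendecomposition of K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedmodels import (
    DispersionParams,
    FitResult,
    ModelData,
    fit_gblup,
    fit_lmap,
    fit_tmap,
)
from .relmat import KinshipMatrix
from .varcomp import (
    HeritabilityGrid,
    apply_negative_fallback,
    derive_regularizers,
    kinship_eigen,
    minque_estimate,
    ml_estimate,
)

logger = logging.getLogger(__name__)


@dataclass
class MetricSet:
    """Predictive metrics: PMSE, PCOR, regression intercept/slope, MNDCG."""

    pmse: float
    pcor: float
    alpha: float
    beta: float
    mndcg: dict[int, float] | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"pmse": self.pmse, "pcor": self.pcor,
               "alpha": self.alpha, "beta": self.beta}
        if self.mndcg:
            out.update({f"mndcg@{k}": v for k, v in self.mndcg.items()})
        return out


@dataclass
class LooResult:
    g_loo: np.ndarray
    c_diag: np.ndarray
    mode: str  # shortcut | brute_force
    metrics: MetricSet
    s: float | None = None
    excluded_folds: int = 0


@dataclass
class BootstrapResult:
    n_samples: int
    per_sample_metrics: dict[str, pd.DataFrame]
    seed: int
    paired: bool = True
    missing_pcor: dict[str, int] = field(default_factory=dict)
    indices: np.ndarray | None = None  # (B, n) resampled row indices


def prediction_metrics(targets: np.ndarray, predictions: np.ndarray,
                       k_list: list[int] | None = None) -> MetricSet:
    """PMSE, Pearson correlation and the regression of target on prediction.

    An empirically unbiased predictor gives intercept 0 and slope 1.
    Constant predictions leave pcor/alpha/beta as NaN (pmse still valid).
    """
    t = np.asarray(targets, dtype=float).ravel()
    p = np.asarray(predictions, dtype=float).ravel()
    if t.size != p.size or t.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    pmse = float(np.mean((t - p) ** 2))
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        return MetricSet(pmse=pmse, pcor=np.nan, alpha=np.nan, beta=np.nan,
                         mndcg=_mndcg_map(t, p, k_list))
    pcor = float(np.corrcoef(p, t)[0, 1])
    beta = float(np.cov(t, p, ddof=1)[0, 1] / np.var(p, ddof=1))
    alpha = float(np.mean(t) - beta * np.mean(p))
    return MetricSet(pmse=pmse, pcor=pcor, alpha=alpha, beta=beta,
                     mndcg=_mndcg_map(t, p, k_list))


def _mndcg_map(t, p, k_list):
    if not k_list:
        return None
    return {k: mndcg_at_k(t, p, k) for k in k_list}


def mndcg_at_k(targets: np.ndarray, predictions: np.ndarray, k: int,
               shift: float | None = None) -> float:
    """Mean normalized discounted cumulative gain over positions 1..k.

    Gains are the targets shifted to positivity (default shift:
    -min(targets) + 1; predictions are positivity-shifted separately,
    which never alters their ranking, so the criterion is invariant to
    monotone transforms of the predictions); the discount is
    log2(position + 1) and each NDCG@j is normalized by the ideal
    (target-sorted) ordering.  Ties in predictions are broken by original
    index.
    """
    t = np.asarray(targets, dtype=float).ravel()
    p = np.asarray(predictions, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > t.size:
        raise ValueError("k exceeds number of items")
    if shift is None:
        shift = -float(t.min()) + 1.0
    gains = t + shift
    if np.any(gains <= 0):
        raise ValueError("shifted targets must be positive")
    # stable sort descending by prediction; ties keep original index order
    order_pred = np.argsort(-p, kind="stable")
    order_ideal = np.argsort(-gains, kind="stable")
    disc = 1.0 / np.log2(np.arange(1, k + 1) + 1.0)
    dcg = np.cumsum(gains[order_pred[:k]] * disc)
    idcg = np.cumsum(gains[order_ideal[:k]] * disc)
    return float(np.mean(dcg / idcg))


def gcv_curve(y: np.ndarray, K: KinshipMatrix,
              lambda_grid: np.ndarray) -> np.ndarray:
    """GCV(lambda) for the zero-means GBLUP smoother, all lambdas at once."""
    lam = np.asarray(lambda_grid, dtype=float).ravel()
    if np.any(lam <= 0):
        raise ValueError("lambda grid must be positive")
    y = np.asarray(y, dtype=float).ravel()
    evals, evecs = kinship_eigen(K)
    z2 = (evecs.T @ y) ** 2
    n = y.size
    out = np.empty(lam.size)
    for j, l in enumerate(lam):
        h = evals / (evals + l)  # eigenvalues of H(lambda)
        hbar = float(np.mean(h))
        if hbar >= 1.0 - 1e-12:
            raise ZeroDivisionError("mean leverage is 1: GCV undefined")
        num = float(np.sum((1.0 - h) ** 2 * z2)) / n
        out[j] = num / (1.0 - hbar) ** 2
    return out


def _shortcut_cdiag(fit: FitResult, data: ModelData,
                    params: DispersionParams) -> tuple[np.ndarray, float]:
    """Diagonal of C^-1 for the frozen-weight predictor C^-1 y."""
    Kinv = data.K.inverse()
    if fit.method == "GBLUP":
        # with replication the predictor is (N + lam K^-1)^-1 N y
        # = (I + lam N^-1 K^-1)^-1 y, so P = N^-1 K^-1
        s = params.lam
        P = Kinv / data.n_counts[:, None]
    elif fit.method == "TMAP":
        s = params.lambda_dprime
        P = Kinv / fit.weights[:, None]  # (KD)^-1 = D^-1 K^-1 row-scaled
    elif fit.method == "LMAP":
        s = params.omega
        P = Kinv / fit.weights[:, None]
    else:
        raise ValueError(f"unknown method {fit.method!r}")
    C = np.eye(data.n) + s * P
    c_diag = np.diag(np.linalg.inv(C)).copy()
    return c_diag, s


def loo_shortcut(fit: FitResult, data: ModelData,
                 params: DispersionParams,
                 k_list: list[int] | None = None) -> LooResult:
    """Leave-one-out predictions without refitting (weights frozen).

    Requires the zero-means model (Z = I, no W).  Exact for GBLUP at fixed
    lambda; an approximation for TMAP/LMAP whose weights would adapt on
    refit.
    """
    if not data.identity_design:
        raise ValueError("LOO shortcut requires the zero-means model")
    if not fit.converged:
        raise ValueError("LOO shortcut requires a converged fit")
    c_diag, s = _shortcut_cdiag(fit, data, params)
    if np.any(np.abs(1.0 - c_diag) < 1e-12):
        raise ZeroDivisionError("a leverage c_ii equals 1: LOO degenerate")
    g_loo = (fit.g - c_diag * data.y) / (1.0 - c_diag)
    metrics = prediction_metrics(data.y, g_loo, k_list=k_list)
    return LooResult(g_loo=g_loo, c_diag=c_diag, mode="shortcut",
                     metrics=metrics, s=s)


def predict_unobserved(K: KinshipMatrix, train_idx: np.ndarray,
                       test_idx: np.ndarray, g_train: np.ndarray) -> np.ndarray:
    """Conditional-expectation prediction for individuals without records:
    g_test = K_test,train K_train,train^-1 g_train."""
    Ktt = K.values[np.ix_(train_idx, train_idx)]
    Kxt = K.values[np.ix_(test_idx, train_idx)]
    return Kxt @ np.linalg.solve(Ktt, g_train)


def _fit_method(method: str, data: ModelData, params: DispersionParams,
                **kw) -> FitResult:
    if method == "gblup":
        return fit_gblup(data, params)
    if method == "tmap":
        return fit_tmap(data, params, **kw)
    if method == "lmap":
        return fit_lmap(data, params, **kw)
    raise ValueError(f"unknown method {method!r}")


def loo_brute_force(
    data: ModelData,
    method: str,
    params: DispersionParams,
    refit_varcomp: bool = False,
    guess_h2: float | None = None,
    fallback_policy: str = "ml",
    k_list: list[int] | None = None,
) -> LooResult:
    """Leave-one-out by n refits, predicting the held-out individual from
    the kinship cross-covariances.

    With refit_varcomp, variance components are re-estimated by MINQUE on
    each training fold (guess = full-data ML heritability unless given),
    negative estimates replaced per the fallback policy.
    """
    if not data.identity_design:
        raise ValueError("brute-force LOO implemented for zero-means model")
    n = data.n
    y = data.y
    g_loo = np.empty(n)
    excluded = 0
    if refit_varcomp and guess_h2 is None:
        guess_h2 = ml_estimate(y, data.K).h2_hat
        guess_h2 = min(max(guess_h2, 1e-3), 1 - 1e-3)
    for i in range(n):
        keep = np.r_[0:i, i + 1:n]
        K_i = data.K.subset(keep)
        d_i = ModelData(y=y[keep], K=K_i, n_counts=data.n_counts[keep])
        p_i = params
        if refit_varcomp:
            est = minque_estimate(y[keep], K_i, guess_h2)
            est = apply_negative_fallback(est, y[keep], K_i,
                                          policy=fallback_policy)
            p_i = derive_regularizers(est.sigma_g2_hat, est.sigma_e2_hat,
                                      nu=params.nu)
        fit_i = _fit_method(method, d_i, p_i)
        if not fit_i.converged:
            excluded += 1
            logger.warning("LOO fold %d did not converge", i)
        g_loo[i] = predict_unobserved(data.K, keep, np.array([i]), fit_i.g)[0]
    metrics = prediction_metrics(y, g_loo, k_list=k_list)
    return LooResult(g_loo=g_loo, c_diag=np.full(n, np.nan),
                     mode="brute_force", metrics=metrics,
                     excluded_folds=excluded)


def bootstrap_metrics(
    targets: np.ndarray,
    predictions_by_method: dict[str, np.ndarray],
    B: int,
    seed: int,
    k_list: list[int] | None = None,
) -> BootstrapResult:
    """Paired bootstrap of predictive metrics.

    Rows (target, prediction) are resampled with replacement B times; every
    method sees the same index draws, so win fractions are paired.
    Resamples with constant predictions record pcor as NaN and are counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    t = np.asarray(targets, dtype=float).ravel()
    n = t.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    tables: dict[str, pd.DataFrame] = {}
    missing: dict[str, int] = {}
    for method, pred in predictions_by_method.items():
        p = np.asarray(pred, dtype=float).ravel()
        rows = []
        n_missing = 0
        for b in range(B):
            ms = prediction_metrics(t[idx[b]], p[idx[b]], k_list=k_list)
            if np.isnan(ms.pcor):
                n_missing += 1
            rows.append(ms.as_dict())
        tables[method] = pd.DataFrame(rows)
        missing[method] = n_missing
    return BootstrapResult(n_samples=B, per_sample_metrics=tables,
                           seed=seed, paired=True, missing_pcor=missing,
                           indices=idx)


def paired_win_fraction(
    bootstrap: BootstrapResult,
    method_a: str,
    method_b: str,
    metric: str,
    direction: str,
) -> tuple[float, int]:
    """Fraction of paired bootstrap samples where a strictly beats b.

    direction 'min' (smaller wins, e.g. pmse) or 'max' (larger wins, e.g.
    pcor).  Ties count as non-wins; the tie count is returned alongside.
    """
    if not bootstrap.paired:
        raise ValueError("win fractions require a paired bootstrap")
    a = bootstrap.per_sample_metrics[method_a][metric].to_numpy()
    b = bootstrap.per_sample_metrics[method_b][metric].to_numpy()
    if direction == "min":
        wins = a < b
    elif direction == "max":
        wins = a > b
    else:
        raise ValueError("direction must be 'min' or 'max'")
    ties = int(np.sum(a == b))
    return float(np.mean(wins)), ties


def train_test_replicates(
    data: ModelData,
    grid: HeritabilityGrid,
    methods: list[str],
    n_rep: int,
    train_fraction: float,
    seed: int,
    fallback_policy: str = "ml",
    max_redraws: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated random train/test evaluation over a regularization grid.

    Per replicate: draw a random split; estimate (sigma_g2, sigma_e2) on the
    training set by MINQUE at each grid heritability (with tau_e2 and omega
    derived); fit each method on the training individuals; predict the test
    individuals through the kinship cross-covariances; score PMSE, PCOR,
    alpha, beta.  Replicate streams are spawned from (seed, replicate) so
    the set of replicates is order-independent.

    Returns (tidy metric table, winner-frequency table).  Winners (max PCOR
    and min PMSE per replicate x grid entry) break exact ties by method
    order.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not data.identity_design:
        raise ValueError("train/test protocol implemented for zero-means model")
    n = data.n
    n_train = int(round(train_fraction * n))
    nu_grid = (grid.nu_values if grid.nu_values is not None else [4.0])
    rows = []
    for rep in range(n_rep):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            K_tr = data.K.subset(train)
            try:
                K_tr.cholesky()
                break
            except np.linalg.LinAlgError:
                logger.warning("singular training K at rep %d: redraw", rep)
        y_tr = data.y[train]
        d_tr = ModelData(y=y_tr, K=K_tr, n_counts=data.n_counts[train])
        y_te = data.y[test]
        for h2_guess in grid.h2_values:
            est = minque_estimate(y_tr, K_tr, float(h2_guess))
            est = apply_negative_fallback(est, y_tr, K_tr,
                                          policy=fallback_policy)
            for method in methods:
                nus = nu_grid if method == "tmap" else [None]
                for nu in nus:
                    params = derive_regularizers(
                        est.sigma_g2_hat, est.sigma_e2_hat, nu=nu
                    )
                    fit = _fit_method(method, d_tr, params)
                    g_te = predict_unobserved(data.K, train, test, fit.g)
                    ms = prediction_metrics(y_te, g_te)
                    tag = f"{method}{int(nu)}" if nu is not None else method
                    for metric, value in ms.as_dict().items():
                        rows.append({
                            "replicate": rep, "grid_h2": float(h2_guess),
                            "nu": np.nan if nu is None else float(nu),
                            "method": tag, "metric": metric, "value": value,
                        })
    table = pd.DataFrame(rows)
    winners = _winner_frequencies(table)
    return table, winners


def _winner_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Per grid entry, frequency each method wins (max pcor / min pmse)."""
    rows = []
    for (h2, metric), sub in table[table.metric.isin(["pcor", "pmse"])].groupby(
        ["grid_h2", "metric"]
    ):
        wide = sub.pivot_table(index="replicate", columns="method",
                               values="value")
        methods = list(wide.columns)
        vals = wide.to_numpy()
        best = (np.nanargmax(vals, axis=1) if metric == "pcor"
                else np.nanargmin(vals, axis=1))
        counts = np.bincount(best, minlength=len(methods))
        for j, method in enumerate(methods):
            rows.append({
                "grid_h2": h2, "metric": metric, "method": method,
                "win_fraction": counts[j] / len(wide),
            })
    return pd.DataFrame(rows)
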