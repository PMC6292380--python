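"""Covariate-conditional estimation of the null proportion pi0(x).

The estimator regresses the exceedance indicators ``Y_i = 1(P_i > lambda)``
on feature-level covariates: for each threshold lambda the conditional mean
``E(Y_i | x_i)`` is estimated by logistic (or linear) regression and scaled
by ``1 / (1 - lambda)``; the per-threshold estimates are then smoothed over a
grid of thresholds with a penalized cubic smoothing spline (3 effective
degrees of freedom), the final estimate being the smoothed value at the
largest threshold.  With an intercept-only design and the linear method this
reduces exactly to the classical threshold estimator
``pi0_hat = (m - R) / ((1 - lambda) m)``.

Bootstrap percentile confidence intervals resample features (p-value and
covariate row jointly), re-run the full smoothed pipeline, and predict at the
original covariate rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "PValueSet",
    "DesignMatrix",
    "LambdaGrid",
    "Pi0LambdaProfile",
    "Pi0Fit",
    "BootstrapConfig",
    "exceedance_indicators",
    "fit_pi0_lambda",
    "smooth_lambda_profile",
    "estimate_pi0",
    "storey_pi0",
    "bootstrap_pi0",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PValueSet:
    """A vector of m p-values with feature identifiers."""

    p: np.ndarray
    feature_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1:
            raise ValueError("p-values must form a one-dimensional vector")
        if p.size < 2:
            raise ValueError(f"need at least 2 p-values, got {p.size}")
        if not np.all(np.isfinite(p)):
            bad = np.flatnonzero(~np.isfinite(p))
            raise ValueError(f"non-finite p-values at rows {bad[:10].tolist()}")
        if p.min() < 0.0 or p.max() > 1.0:
            bad = np.flatnonzero((p < 0) | (p > 1))
            raise ValueError(f"p-values outside [0, 1] at rows {bad[:10].tolist()}")
        object.__setattr__(self, "p", p)
        if self.feature_id is None:
            object.__setattr__(
                self, "feature_id", np.array([f"feature_{i}" for i in range(p.size)])
            )
        else:
            fid = np.asarray(self.feature_id)
            if fid.shape != p.shape:
                raise ValueError("feature_id must match p in length")
            object.__setattr__(self, "feature_id", fid)

    def __len__(self) -> int:
        return self.p.size


def _numerical_rank(Z: np.ndarray) -> int:
    s = np.linalg.svd(Z, compute_uv=False)
    if s.size == 0:
        return 0
    tol = max(Z.shape) * np.finfo(float).eps * s[0]
    return int(np.sum(s > tol))


@dataclass(frozen=True)
class DesignMatrix:
    """An m x p regression design with an all-ones intercept first column."""

    Z: np.ndarray
    column_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        if Z.ndim != 2:
            raise ValueError("design matrix must be two-dimensional")
        if not np.all(np.isfinite(Z)):
            raise ValueError("design matrix contains non-finite entries")
        if not np.allclose(Z[:, 0], 1.0):
            raise ValueError("first design column must be the all-ones intercept")
        object.__setattr__(self, "Z", Z)
        names = self.column_names or tuple(f"z{j}" for j in range(Z.shape[1]))
        if len(names) != Z.shape[1]:
            raise ValueError("column_names length must match the number of columns")
        object.__setattr__(self, "column_names", tuple(names))

    @property
    def rank(self) -> int:
        return _numerical_rank(self.Z)

    @property
    def shape(self) -> tuple[int, int]:
        return self.Z.shape

    @classmethod
    def intercept_only(cls, m: int) -> "DesignMatrix":
        return cls(np.ones((m, 1)), ("intercept",))


@dataclass(frozen=True)
class LambdaGrid:
    """Strictly increasing thresholds in (0, 1); default 0.05, 0.10, ..., 0.95."""

    values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1, 20) * 0.05, 2)
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("lambda grid must be a non-empty vector")
        if v.min() <= 0.0 or v.max() >= 1.0:
            raise ValueError("lambda thresholds must lie strictly inside (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("lambda thresholds must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Pi0LambdaProfile:
    """Per-feature pi0 estimates across the lambda grid (m x n_lambda)."""

    estimates: np.ndarray
    method: str


@dataclass(frozen=True)
class Pi0Fit:
    """Smoothed pi0(x_i) estimates, the lambda profile, and optional CIs."""

    pi0: np.ndarray
    profile: Pi0LambdaProfile
    lambda_grid: LambdaGrid
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    alpha: float | None = None


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 100
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _as_pvalues(p) -> np.ndarray:
    if isinstance(p, PValueSet):
        return p.p
    return PValueSet(np.asarray(p, dtype=float)).p


def _as_design(Z) -> np.ndarray:
    if isinstance(Z, DesignMatrix):
        return Z.Z
    return DesignMatrix(np.asarray(Z, dtype=float)).Z


def _check_lambda(lam: float) -> float:
    lam = float(lam)
    if not 0.0 < lam < 1.0:
        raise ValueError(f"threshold lambda must lie in (0, 1), got {lam}")
    return lam


def exceedance_indicators(p, lam: float) -> np.ndarray:
    """Indicators Y_i = 1(P_i > lambda), with a strict inequality."""
    lam = _check_lambda(lam)
    return (_as_pvalues(p) > lam).astype(float)


def _fit_logistic_irls(
    Z: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray | None:
    """Maximum-likelihood logistic fit via Newton/IRLS with step-halving.

    Returns the coefficient vector, or None when the iteration fails to
    converge (e.g. perfect separation at an extreme threshold).
    """
    m, k = Z.shape
    beta = np.zeros(k)
    ybar = y.mean()
    beta[0] = np.log((ybar + 1e-8) / (1.0 - ybar + 1e-8))

    def negloglik(b: np.ndarray) -> float:
        eta = Z @ b
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    nll = negloglik(beta)
    for _ in range(max_iter):
        eta = Z @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        grad = Z.T @ (y - mu)
        hess = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None
        # step-halving line search on the deviance
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_nll = negloglik(cand)
            if cand_nll <= nll + 1e-12:
                break
            scale *= 0.5
        else:
            return None
        converged = np.max(np.abs(cand - beta)) < tol * (1.0 + np.max(np.abs(beta)))
        beta, nll = cand, cand_nll
        if converged:
            return beta
        if np.max(np.abs(beta)) > 1e3:  # diverging: separation
            return None
    return None


def _linear_fitted(Z: np.ndarray, y: np.ndarray, Z_pred: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return Z_pred @ beta


def fit_pi0_lambda(
    Y: np.ndarray,
    Z,
    lam: float,
    method: str = "logistic",
    Z_pred=None,
) -> np.ndarray:
    """Per-feature pi0 estimate at one threshold: E_hat(Y|x) / (1 - lambda).

    ``Z_pred`` lets a model fitted on one design be evaluated at other
    covariate rows (used by the bootstrap); it defaults to the fitting design.
    The result is thresholded into [0, 1].
    """
    lam = _check_lambda(lam)
    Y = np.asarray(Y, dtype=float)
    Z = _as_design(Z)
    Zp = Z if Z_pred is None else _as_design(Z_pred)
    if Z.shape[0] != Y.size:
        raise ValueError("design rows must match the indicator vector length")
    if method not in ("logistic", "linear"):
        raise ValueError(f"unknown method {method!r}")

    if Y.min() == Y.max():
        # all-zero or all-one indicators: the MLE of E(Y|x) is the constant
        fitted = np.full(Zp.shape[0], Y[0])
    elif method == "logistic":
        beta = _fit_logistic_irls(Z, Y)
        if beta is None:
            logger.warning(
                "logistic fit failed to converge at lambda=%.3g; "
                "falling back to the linear fit",
                lam,
            )
            fitted = _linear_fitted(Z, Y, Zp)
        else:
            fitted = expit(Zp @ beta)
    else:
        fitted = _linear_fitted(Z, Y, Zp)

    return np.clip(fitted / (1.0 - lam), 0.0, 1.0)


@lru_cache(maxsize=32)
def _smoother_weights(grid: tuple[float, ...], df: float) -> np.ndarray:
    """Evaluation weights of the df-constrained cubic smoothing spline.

    The smoother is linear in the profile, so the fitted value at the largest
    threshold is ``w @ profile`` for a weight vector depending only on the
    grid and the effective degrees of freedom (trace of the hat matrix).
    """
    x = np.asarray(grid, dtype=float)
    n = x.size

    def hat_matrix(log_pen: float) -> np.ndarray:
        S = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            S[:, j] = make_smoothing_spline(x, e, lam=10.0**log_pen)(x)
        return S

    def df_gap(log_pen: float) -> float:
        return float(np.trace(hat_matrix(log_pen))) - df

    log_pen = brentq(df_gap, -12.0, 12.0, xtol=1e-10)
    S = hat_matrix(log_pen)
    return S[-1].copy()


def smooth_lambda_profile(profile, grid: LambdaGrid | np.ndarray, df: float = 3) -> np.ndarray:
    """Smooth each feature's lambda profile; return the value at the largest
    threshold, clipped into [0, 1]."""
    est = profile.estimates if isinstance(profile, Pi0LambdaProfile) else np.asarray(profile, float)
    lams = grid.values if isinstance(grid, LambdaGrid) else LambdaGrid(np.asarray(grid, float)).values
    if est.ndim == 1:
        est = est[None, :]
    if est.shape[1] != lams.size:
        raise ValueError("profile width must match the lambda grid length")
    if lams.size < df + 1:
        raise ValueError(
            f"lambda grid of length {lams.size} cannot support {df} effective df"
        )
    w = _smoother_weights(tuple(lams.tolist()), float(df))
    return np.clip(est @ w, 0.0, 1.0)


def estimate_pi0(
    p,
    Z=None,
    grid: LambdaGrid | None = None,
    method: str = "logistic",
    smooth_df: float = 3,
) -> Pi0Fit:
    """Full pi0(x) pipeline: indicators -> per-lambda regression -> smoothing.

    Parameters
    ----------
    p : PValueSet or array-like
        The m p-values.
    Z : DesignMatrix, array-like or None
        Covariate design; ``None`` means intercept-only (no covariates),
        which with ``method='linear'`` is the classical smoothed threshold
        estimator.
    grid : LambdaGrid, optional
        Thresholds; defaults to 0.05, 0.10, ..., 0.95.
    method : {'logistic', 'linear'}
        Regression model for E(Y | x).
    """
    pv = _as_pvalues(p)
    Zm = np.ones((pv.size, 1)) if Z is None else _as_design(Z)
    if Zm.shape[0] != pv.size:
        raise ValueError("design rows must match the number of p-values")
    if _numerical_rank(Zm) >= pv.size:
        raise ValueError("regression needs more features than design rank")
    grid = grid if grid is not None else LambdaGrid()

    prof = np.empty((pv.size, len(grid)))
    for j, lam in enumerate(grid.values):
        Y = exceedance_indicators(pv, lam)
        try:
            prof[:, j] = fit_pi0_lambda(Y, Zm, lam, method=method)
        except Exception as err:  # pragma: no cover - defensive context
            raise RuntimeError(f"pi0 regression failed at lambda={lam:g}") from err
    profile = Pi0LambdaProfile(estimates=prof, method=method)
    pi0 = smooth_lambda_profile(profile, grid, df=smooth_df)
    return Pi0Fit(pi0=pi0, profile=profile, lambda_grid=grid)


def storey_pi0(p, lam: float = 0.5) -> float:
    """Scalar threshold estimator (m - R) / ((1 - lambda) m), floored at 1/m
    and capped at 1."""
    lam = _check_lambda(lam)
    pv = _as_pvalues(p)
    m = pv.size
    raw = np.sum(pv > lam) / ((1.0 - lam) * m)
    if raw <= 0.0:
        logger.warning("threshold pi0 estimate was 0; flooring at 1/m")
        return 1.0 / m
    return float(min(raw, 1.0))


def bootstrap_pi0(
    p,
    Z=None,
    grid: LambdaGrid | None = None,
    method: str = "logistic",
    cfg: BootstrapConfig | None = None,
    min_success: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap bounds for pi0(x_i).

    Features are resampled with replacement — the p-value and its covariate
    row travel together — the full smoothed pipeline is re-run per resample,
    and estimates are predicted at the ORIGINAL covariate rows.  Resamples
    whose fit fails are skipped; fewer than ``min_success * B`` successes is
    an error.
    """
    cfg = cfg or BootstrapConfig()
    pv = _as_pvalues(p)
    m = pv.size
    Zm = np.ones((m, 1)) if Z is None else _as_design(Z)
    grid = grid if grid is not None else LambdaGrid()
    # fail fast if the original data cannot be fit
    estimate_pi0(pv, Zm, grid, method=method)

    rng = np.random.default_rng(cfg.seed)
    boot = np.empty((cfg.B, m))
    ok = 0
    for b in range(cfg.B):
        idx = rng.integers(0, m, size=m)
        pb, Zb = pv[idx], Zm[idx]
        try:
            prof = np.empty((m, len(grid)))
            for j, lam in enumerate(grid.values):
                Y = (pb > lam).astype(float)
                prof[:, j] = fit_pi0_lambda(Y, Zb, lam, method=method, Z_pred=Zm)
            boot[ok] = smooth_lambda_profile(prof, grid)
            ok += 1
        except Exception as err:
            logger.warning("bootstrap resample %d failed: %s", b, err)
    if ok < min_success * cfg.B:
        raise RuntimeError(
            f"only {ok}/{cfg.B} bootstrap resamples succeeded "
            f"(need at least {min_success:.0%})"
        )
    boot = boot[:ok]
    lo = np.clip(np.quantile(boot, cfg.alpha / 2.0, axis=0), 0.0, 1.0)
    hi = np.clip(np.quantile(boot, 1.0 - cfg.alpha / 2.0, axis=0), 0.0, 1.0)
    return lo, hi
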