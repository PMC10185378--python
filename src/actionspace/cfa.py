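"""Confirmatory factor analysis by normal-theory maximum likelihood.

A confirmatory spec assigns every item to exactly one factor (free loading,
free uniqueness), with unit factor variances and free factor correlations.
The fit minimises the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over loadings, log-uniquenesses and a hyperspherical parametrisation of the
factor correlation matrix; the test statistic is chi2 = n * F at the optimum
(sample covariance with ML divisor n, likelihood over n observations, the
conventions the printed AIC values depend on).  CFI is computed against the
independence (diagonal-covariance) baseline, RMSEA with a noncentral-chi2
90% interval and a close-fit test at RMSEA0 = .05.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError, ValidationError

__all__ = ["CfaSpec", "CfaFit", "build_cfa_spec", "fit_cfa",
           "independence_baseline", "sample_cov"]


def sample_cov(data: np.ndarray) -> np.ndarray:
    """Sample covariance with the ML divisor n."""
    x = np.asarray(data, dtype=float)
    return np.cov(x, rowvar=False, ddof=0)


@dataclass
class CfaSpec:
    """Simple-structure confirmatory model: item -> factor assignment."""

    items: list[str]
    assignment: dict[str, int]        # item -> 0-based factor index
    k: int

    def __post_init__(self) -> None:
        missing = [i for i in self.items if i not in self.assignment]
        if missing:
            raise ValidationError(f"unassigned item(s): {missing}")
        used = set(self.assignment.values())
        if used - set(range(self.k)):
            raise ValidationError("assignment references unknown factor index")

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def n_free(self) -> int:
        return 2 * self.p + self.k * (self.k - 1) // 2

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free

    def loading_pattern(self) -> np.ndarray:
        pat = np.zeros((self.p, self.k), dtype=bool)
        for i, item in enumerate(self.items):
            pat[i, self.assignment[item]] = True
        return pat


def build_cfa_spec(efa, use: str = "structure") -> CfaSpec:
    """Convert an EFA solution to a confirmatory spec by assigning every item
    to its largest-|loading| factor (ties broken toward the lower index)."""
    loadings = efa.structure if use == "structure" else efa.pattern
    assignment = {}
    for i, item in enumerate(efa.items):
        row = np.abs(np.asarray(loadings)[i])
        # np.argmax already prefers the lower index on exact ties
        assignment[item] = int(np.argmax(row))
    return CfaSpec(items=list(efa.items), assignment=assignment, k=efa.k)


@dataclass
class CfaFit:
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    rmsea_pclose: float
    loglik: float
    aic: float
    converged: bool
    n: int
    n_free: int
    loadings: np.ndarray = field(repr=False)
    uniquenesses: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    baseline_chi2: float = np.nan
    baseline_df: int = 0

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "p_value": self.p_value,
            "cfi": self.cfi, "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci), "rmsea_pclose": self.rmsea_pclose,
            "loglik": self.loglik, "aic": self.aic, "converged": self.converged,
            "n": self.n, "n_free": self.n_free,
            "loadings": np.asarray(self.loadings).tolist(),
            "uniquenesses": np.asarray(self.uniquenesses).tolist(),
            "phi": np.asarray(self.phi).tolist(),
            "baseline_chi2": self.baseline_chi2, "baseline_df": self.baseline_df,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# -- hyperspherical parametrisation of a correlation matrix -----------------

def _angles_to_chol(theta: np.ndarray, k: int) -> np.ndarray:
    """Lower-triangular Cholesky factor of a unit-diagonal correlation matrix
    from k(k-1)/2 angles in (0, pi)."""
    L = np.zeros((k, k))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, k):
        prod = 1.0
        for j in range(i):
            L[i, j] = prod * np.cos(theta[idx])
            prod *= np.sin(theta[idx])
            idx += 1
        L[i, i] = prod
    return L


def _pack(loadings, log_psi, theta):
    return np.concatenate([loadings, log_psi, theta])


def _unpack(x: np.ndarray, p: int, k: int):
    lam = x[:p]
    log_psi = x[p:2 * p]
    theta = x[2 * p:]
    return lam, log_psi, theta


def _implied_cov(lam, psi, phi, rows, cols, p):
    Lam = np.zeros((p, phi.shape[0]))
    Lam[rows, cols] = lam
    return Lam @ phi @ Lam.T + np.diag(psi)


def _fml(sigma: np.ndarray, S: np.ndarray, logdet_s: float, p: int) -> float:
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.log(np.diag(c)).sum()
    tr = np.trace(np.linalg.solve(sigma, S))
    return logdet + tr - logdet_s - p


def independence_baseline(S: np.ndarray, n: int) -> tuple[float, int]:
    """Closed-form independence (diagonal Sigma) model fit."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegenerateDataError("sample covariance not positive definite")
    chi2 = n * (np.log(np.diag(S)).sum() - logdet_s)
    return float(max(chi2, 0.0)), p * (p - 1) // 2


def _rmsea_ci(chi2: float, df: int, n: int, conf: float = 0.90):
    """Noncentral-chi2 RMSEA interval: solve for the noncentrality parameters
    at which the observed statistic sits at the (1+conf)/2 and (1-conf)/2
    quantiles."""
    lo_tail, hi_tail = (1 + conf) / 2, (1 - conf) / 2

    def bound(target):
        if stats.chi2.cdf(chi2, df) < target:   # ncp 0 already too big
            return 0.0
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - target
        hi = max(chi2 * 2, df + 10.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e7:
                break
        try:
            return optimize.brentq(f, 1e-10, hi)
        except ValueError:
            return 0.0

    nc_lo = bound(lo_tail)
    nc_hi = bound(hi_tail)
    lo = np.sqrt(nc_lo / (df * n)) if nc_lo > 0 else 0.0
    hi = np.sqrt(nc_hi / (df * n)) if nc_hi > 0 else 0.0
    return float(lo), float(hi)


def fit_cfa(S: np.ndarray, n: int, spec: CfaSpec, starts: int = 5,
            tol: float = 1e-9, seed: int | None = 0,
            rmsea0: float = 0.05) -> CfaFit:
    """Fit the confirmatory model to a sample covariance matrix.

    Jittered restarts are attempted when the optimizer fails or lands on a
    non-finite optimum; ``converged=False`` fits are returned (not raised) so
    that simulation harnesses can apply their own discard policy.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p != spec.p:
        raise ValidationError(f"S is {p}x{p} but spec has {spec.p} items")
    if n <= p:
        raise ValidationError("need n > p observations")
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegenerateDataError("sample covariance not positive definite")
    k = spec.k
    rows = np.arange(p)
    cols = np.array([spec.assignment[i] for i in spec.items])
    n_angles = k * (k - 1) // 2
    diag_s = np.diag(S)

    def objective(x):
        lam, log_psi, theta = _unpack(x, p, k)
        psi = np.exp(log_psi)
        L = _angles_to_chol(theta, k)
        phi = L @ L.T
        return _fml(_implied_cov(lam, psi, phi, rows, cols, p), S, logdet_s, p)

    rng = np.random.default_rng(seed)
    x0_base = _pack(np.sqrt(0.5 * diag_s), np.log(0.5 * diag_s),
                    np.full(n_angles, np.pi / 2))
    bounds = ([(None, None)] * p
              + [(np.log(1e-8 * diag_s.mean()), None)] * p
              + [(0.05, np.pi - 0.05)] * n_angles)
    best = None
    for attempt in range(max(1, starts)):
        x0 = x0_base if attempt == 0 else x0_base + np.concatenate([
            rng.normal(0, 0.3 * np.sqrt(diag_s)),
            rng.normal(0, 0.3, p),
            rng.normal(0, 0.3, n_angles),
        ])
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 2000, "ftol": tol})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and best.success and attempt >= 0:
            break
    converged = bool(best is not None and best.success and np.isfinite(best.fun))
    if best is None:
        raise DegenerateDataError("CFA optimisation produced no finite value")

    lam, log_psi, theta = _unpack(best.x, p, k)
    psi = np.exp(log_psi)
    L = _angles_to_chol(theta, k)
    phi = L @ L.T
    Lam = np.zeros((p, k))
    Lam[rows, cols] = lam
    sigma_hat = _implied_cov(lam, psi, phi, rows, cols, p)

    fmin = float(best.fun)
    chi2 = max(n * fmin, 0.0)
    df = spec.df
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + logdet_s + fmin + p)
    aic = -2.0 * loglik + 2.0 * spec.n_free
    base_chi2, base_df = independence_baseline(S, n)
    d_model = max(chi2 - df, 0.0)
    d_base = max(base_chi2 - base_df, 0.0)
    cfi = 1.0 if d_base == 0 else float(np.clip(1.0 - d_model / d_base, 0.0, 1.0))
    if df > 0:
        rmsea = float(np.sqrt(d_model / (df * n)))
        ci = _rmsea_ci(chi2, df, n)
        pclose = float(stats.ncx2.sf(chi2, df, n * df * rmsea0 ** 2))
    else:
        rmsea, ci, pclose = 0.0, (0.0, 0.0), 1.0
    return CfaFit(
        chi2=float(chi2), df=df, p_value=p_value, cfi=cfi, rmsea=rmsea,
        rmsea_ci=ci, rmsea_pclose=pclose, loglik=float(loglik), aic=float(aic),
        converged=converged, n=n, n_free=spec.n_free,
        loadings=Lam, uniquenesses=psi, phi=phi,
        baseline_chi2=base_chi2, baseline_df=base_df,
    )
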