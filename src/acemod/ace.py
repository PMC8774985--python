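"""Unmoderated univariate ACE/AE/CE/E twin models by maximum likelihood.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C) and non-shared environmental (E)
components by exploiting the different additive-genetic correlation of
monozygotic (r=1) and dizygotic (r=0.5) co-twins.  With path coefficients
a, c, e and grand mean mu, each pair's phenotype vector is bivariate normal
with

    Var   = a^2 + c^2 + e^2
    Cov_z = r_z a^2 + c^2,   r_MZ = 1,  r_DZ = 0.5

and the deviance (-2 ln L) is the sum of per-pair bivariate-normal
log-densities.  Fitting is unconstrained quasi-Newton on the path
coefficients with a multi-start grid; signs are canonicalized to
non-negative afterwards (the likelihood is sign-invariant).  Confidence
intervals are profile-likelihood based: a bound is the parameter value at
which the profile deviance rises 3.8415 (the 0.95 quantile of chi-square
with 1 df) above its minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "ACEParams",
    "VarianceDecomposition",
    "FitResult",
    "MODEL_SPECS",
    "expected_cov_ace",
    "neg2_loglik",
    "fit_model",
    "standardize",
    "profile_ci",
    "lrt",
]

LOG_2PI = math.log(2.0 * math.pi)
_CHI2_95_1DF = float(chi2.ppf(0.95, 1))  # 3.8415

#: Free path coefficients per model specification (mu is always free).
MODEL_SPECS: dict[str, tuple[str, ...]] = {
    "ACE": ("a", "c", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}


@dataclass(frozen=True)
class ACEParams:
    """Path coefficients and grand mean of the unmoderated model."""

    a: float = 0.0
    c: float = 0.0
    e: float = 1.0
    mu: float = 0.0

    def canonical(self) -> "ACEParams":
        """Non-negative path coefficients (likelihood is sign-invariant)."""
        return ACEParams(abs(self.a), abs(self.c), abs(self.e), self.mu)

    @property
    def total_variance(self) -> float:
        return self.a ** 2 + self.c ** 2 + self.e ** 2


@dataclass(frozen=True)
class VarianceDecomposition:
    """Standardized variance shares A + C + E = 1."""

    A: float
    C: float
    E: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    spec: str
    params: ACEParams
    neg2lnL: float
    ep: int
    df: int
    n_pairs: int
    converged: bool
    grad_norm: float
    n_starts: int = 1
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    boundary_flags: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def expected_cov_ace(params: ACEParams, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 covariance matrix of a twin pair."""
    r = 1.0 if zygosity.upper() == "MZ" else 0.5
    a2, c2, e2 = params.a ** 2, params.c ** 2, params.e ** 2
    v = a2 + c2 + e2
    cov = r * a2 + c2
    return np.array([[v, cov], [cov, v]])


def _deviance_arrays(
    a: float, c: float, e: float, mu: float,
    y1: np.ndarray, y2: np.ndarray, is_mz: np.ndarray,
) -> float:
    """Vectorized deviance; +inf if any pair covariance is singular/non-PD."""
    a2, c2, e2 = a * a, c * c, e * e
    v = a2 + c2 + e2
    out = 0.0
    for mz in (True, False):
        mask = is_mz if mz else ~is_mz
        n = int(mask.sum())
        if n == 0:
            continue
        cov = (1.0 if mz else 0.5) * a2 + c2
        det = v * v - cov * cov
        if det <= 0.0 or v <= 0.0:
            return math.inf
        d1 = y1[mask] - mu
        d2 = y2[mask] - mu
        quad = (v * (d1 @ d1 + d2 @ d2) - 2.0 * cov * (d1 @ d2)) / det
        out += n * (2.0 * LOG_2PI + math.log(det)) + quad
    return out


def neg2_loglik(
    params: ACEParams,
    y1: np.ndarray, y2: np.ndarray, is_mz: np.ndarray,
) -> float:
    """Deviance -2 ln L of the cohort under ``params``.

    Pairs enter through the bivariate-normal density with the model-implied
    covariance for their zygosity.  A singular implied covariance returns
    +inf (so optimizers back away) rather than raising.
    """
    return _deviance_arrays(params.a, params.c, params.e, params.mu,
                            np.asarray(y1, float), np.asarray(y2, float),
                            np.asarray(is_mz, bool))


# ---------------------------------------------------------------------------
# Optimization machinery (shared with the moderation module)
# ---------------------------------------------------------------------------

def _num_grad(f: Callable[[np.ndarray], float], x: np.ndarray,
              rel_h: float = 1e-5) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_h * (1.0 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def _num_hess(f: Callable[[np.ndarray], float], x: np.ndarray,
              rel_h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    hs = rel_h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += hs[i]; xpp[j] += hs[j]
            xpm = x.copy(); xpm[i] += hs[i]; xpm[j] -= hs[j]
            xmp = x.copy(); xmp[i] -= hs[i]; xmp[j] += hs[j]
            xmm = x.copy(); xmm[i] -= hs[i]; xmm[j] -= hs[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * hs[i] * hs[j])
    return H


def minimize_deviance(
    fun: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    *,
    ftol: float = 1e-12,
    newton_polish: int = 4,
) -> tuple[np.ndarray, float, float, bool]:
    """Multi-start quasi-Newton minimization with a Newton polish.

    Returns (x_best, f_best, grad_norm, converged).  The polish takes a few
    damped Newton steps with a finite-difference Hessian to drive the
    gradient norm down to the noise floor of the deviance evaluation.
    """
    best_x, best_f = None, math.inf
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(fun, np.asarray(x0, float), method="L-BFGS-B",
                                options={"ftol": ftol, "gtol": 1e-9, "maxiter": 500})
        if not np.isfinite(res.fun):
            continue
        any_ok = any_ok or bool(res.success)
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.asarray(res.x, float)
    if best_x is None:
        raise RuntimeError("no start of the optimizer reached a finite deviance")
    x, fx = best_x, best_f
    for _ in range(newton_polish):
        g = _num_grad(fun, x)
        gn = float(np.linalg.norm(g))
        if gn < 1e-7 * (1.0 + abs(fx) / 1e4):
            break
        H = _num_hess(fun, x)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(x.size), -g)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        for _ in range(20):
            f_new = fun(x + lam * step)
            if f_new <= fx + 1e-12:
                x, fx = x + lam * step, f_new
                break
            lam *= 0.5
        else:
            break
    gn = float(np.linalg.norm(_num_grad(fun, x)))
    converged = bool(any_ok and gn < 1e-6 * (1.0 + abs(fx) / 1e4))
    return x, float(fx), gn, converged


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _default_starts(free: tuple[str, ...], sd: float, mu0: float,
                    n_starts: int | None) -> list[np.ndarray]:
    grid = (0.2, 0.6, 1.0)
    paths = [p for p in free]
    if n_starts == 1:
        # single moment-flavoured start
        return [np.array([0.6 * sd] * len(paths) + [mu0])]
    starts = []
    for g in grid:
        starts.append(np.array([g * sd] * len(paths) + [mu0]))
    # one asymmetric start to escape symmetric saddles
    starts.append(np.array([(0.3 + 0.2 * i) * sd for i in range(len(paths))] + [mu0]))
    return starts


def fit_model(
    y1: np.ndarray, y2: np.ndarray, is_mz: np.ndarray,
    spec: str = "ACE",
    *,
    n_starts: int | None = None,
) -> FitResult:
    """Fit an ACE / AE / CE / E model by maximum likelihood.

    ``n_starts=1`` uses a single moment-based start (useful inside
    simulation loops); the default multi-start grid scans path coefficients
    over {0.2, 0.6, 1.0} x sample SD.
    """
    spec = spec.upper()
    if spec not in MODEL_SPECS:
        raise ValueError(f"unknown model spec {spec!r}")
    y1 = np.asarray(y1, float); y2 = np.asarray(y2, float)
    is_mz = np.asarray(is_mz, bool)
    if int(is_mz.sum()) < 2 or int((~is_mz).sum()) < 2:
        raise ValueError("need at least 2 MZ and 2 DZ pairs")
    ystack = np.concatenate([y1, y2])
    if np.std(ystack) == 0:
        raise ValueError("phenotype is degenerate (zero variance)")
    free = MODEL_SPECS[spec]
    sd = float(np.std(ystack, ddof=1))
    mu0 = float(np.mean(ystack))

    def unpack(x: np.ndarray) -> ACEParams:
        kw = {"a": 0.0, "c": 0.0, "e": 0.0}
        for nm, v in zip(free, x[:-1]):
            kw[nm] = float(v)
        return ACEParams(mu=float(x[-1]), **kw)

    def fun(x: np.ndarray) -> float:
        p = unpack(x)
        return _deviance_arrays(p.a, p.c, p.e, p.mu, y1, y2, is_mz)

    starts = _default_starts(free, sd, mu0, n_starts)
    x, fx, gn, conv = minimize_deviance(fun, starts)
    params = unpack(x).canonical()
    ep = len(free) + 1
    n_pairs = y1.size
    return FitResult(
        spec=spec, params=params, neg2lnL=fx, ep=ep,
        df=2 * n_pairs - ep, n_pairs=n_pairs,
        converged=conv, grad_norm=gn, n_starts=len(starts),
    )


def standardize(fit: FitResult) -> VarianceDecomposition:
    """Variance shares A = a^2/V, C = c^2/V, E = e^2/V (V = a^2+c^2+e^2)."""
    p = fit.params
    v = p.total_variance
    return VarianceDecomposition(A=p.a ** 2 / v, C=p.c ** 2 / v, E=p.e ** 2 / v)


def lrt(reduced: FitResult, full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced against a nested fuller model.

    Returns (chi2_statistic, delta_df, p_value); the statistic is clipped at
    0 against optimizer noise.
    """
    stat = max(reduced.neg2lnL - full.neg2lnL, 0.0)
    ddf = full.ep - reduced.ep
    if ddf < 1:
        raise ValueError("models are not nested in the right direction")
    return stat, ddf, float(chi2.sf(stat, ddf))


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profile_deviance_std(
    target: str, t: float, fit: FitResult,
    y1: np.ndarray, y2: np.ndarray, is_mz: np.ndarray,
) -> float:
    """Min deviance with the standardized share of ``target`` fixed at t.

    Reparameterizes by total variance v (and, for ACE, the split of the
    remaining share) so the constraint is built in.
    """
    free = MODEL_SPECS[fit.spec]
    others = [p for p in free if p != target.lower()]
    p0 = fit.params
    v0 = max(p0.total_variance, 1e-6)

    if len(others) == 0:  # single-path model: share is fixed at 1
        return math.inf

    def make_params(x: np.ndarray) -> ACEParams:
        logv, mu = x[0], x[-1]
        v = math.exp(logv)
        rest = 1.0 - t
        kw = {"a": 0.0, "c": 0.0, "e": 0.0}
        kw[target.lower()] = math.sqrt(max(t, 0.0) * v)
        if len(others) == 1:
            kw[others[0]] = math.sqrt(max(rest, 0.0) * v)
        else:  # split rest between the two remaining paths via a logistic knob
            w = 1.0 / (1.0 + math.exp(-x[1]))
            kw[others[0]] = math.sqrt(rest * w * v)
            kw[others[1]] = math.sqrt(rest * (1.0 - w) * v)
        return ACEParams(mu=mu, **kw)

    def fun(x: np.ndarray) -> float:
        p = make_params(x)
        return _deviance_arrays(p.a, p.c, p.e, p.mu, y1, y2, is_mz)

    if len(others) == 1:
        x0 = np.array([math.log(v0), p0.mu])
    else:
        o2 = p0.a ** 2 + p0.c ** 2 + p0.e ** 2
        s1 = getattr(p0, others[0]) ** 2 / o2
        w0 = min(max(s1 / max(1.0 - t, 1e-9), 1e-6), 1 - 1e-6)
        x0 = np.array([math.log(v0), math.log(w0 / (1 - w0)), p0.mu])
    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(res.fun)


def _profile_deviance_raw(
    target: str, t: float, fit: FitResult,
    y1: np.ndarray, y2: np.ndarray, is_mz: np.ndarray,
) -> float:
    free = MODEL_SPECS[fit.spec]
    others = [p for p in free if p != target] + (["mu"] if target != "mu" else [])
    if target != "mu" and target not in free:
        raise ValueError(f"parameter {target!r} not free in spec {fit.spec}")

    def fun(x: np.ndarray) -> float:
        kw = {"a": 0.0, "c": 0.0, "e": 0.0, "mu": 0.0}
        kw[target] = t
        for nm, v in zip(others, x):
            kw[nm] = float(v)
        return _deviance_arrays(kw["a"], kw["c"], kw["e"], kw["mu"], y1, y2, is_mz)

    x0 = np.array([getattr(fit.params, nm) for nm in others])
    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(res.fun)


def profile_ci(
    fit: FitResult,
    y1: np.ndarray, y2: np.ndarray, is_mz: np.ndarray,
    parameter: str,
    level: float = 0.95,
) -> tuple[tuple[float, float], dict[str, str]]:
    """Profile-likelihood CI for a raw path/mean or a standardized share.

    ``parameter`` in {'a','c','e','mu'} profiles the raw coefficient;
    upper-case {'A','C','E'} profiles the standardized variance share on
    [0, 1].  A bound that runs into the admissible boundary is reported at
    the boundary with a flag.
    """
    y1 = np.asarray(y1, float); y2 = np.asarray(y2, float)
    is_mz = np.asarray(is_mz, bool)
    crit = float(chi2.ppf(level, 1))
    dev0 = fit.neg2lnL
    flags: dict[str, str] = {}

    standardized = parameter in ("A", "C", "E")
    if standardized:
        if parameter.lower() not in MODEL_SPECS[fit.spec]:
            raise ValueError(f"component {parameter} not in spec {fit.spec}")
        centre = getattr(standardize(fit), parameter)
        lo_bound, hi_bound = 0.0, 1.0
        prof = lambda t: _profile_deviance_std(parameter, t, fit, y1, y2, is_mz)
    else:
        centre = getattr(fit.params, parameter)
        lo_bound, hi_bound = -math.inf, math.inf
        if parameter != "mu":
            lo_bound = 0.0  # canonical sign: profile over the non-negative branch
        prof = lambda t: _profile_deviance_raw(parameter, t, fit, y1, y2, is_mz)

    def height(t: float) -> float:
        return prof(t) - dev0 - crit

    # crude curvature-based step for bracketing
    h = 0.05 * (1.0 + abs(centre))
    bounds = []
    for direction in (-1.0, 1.0):
        t = centre
        step = direction * h
        bracket = None
        limit = lo_bound if direction < 0 else hi_bound
        for _ in range(60):
            t_next = t + step
            if direction < 0 and t_next <= limit:
                t_next = limit
            if direction > 0 and t_next >= limit:
                t_next = limit
            if height(t_next) > 0:
                bracket = (min(t, t_next), max(t, t_next))
                break
            t = t_next
            if t == limit:
                break
            step *= 1.6
        if bracket is None:
            name = "lower" if direction < 0 else "upper"
            flags[name] = "boundary"
            bounds.append(limit)
        else:
            root = optimize.brentq(height, bracket[0], bracket[1], xtol=1e-6)
            bounds.append(float(root))
    lo, hi = min(bounds), max(bounds)
    return (lo, hi), flags
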