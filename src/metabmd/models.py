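"""Continuous benchmark-dose engine.

Fits the seven parametric dose-response models used for continuous endpoints
(Linear, Power, Hill, Exponential 2-5) under a constant-variance normal
likelihood, computes the benchmark dose (BMD) at a standard-deviation-based
benchmark response (BMR), profile-likelihood lower/upper confidence limits
(BMDL/BMDU), a likelihood-ratio lack-of-fit p-value, and AIC-based best-model
selection with the Hill-k flagging rule.

Model mean functions (d >= 0):

======  ==========================================  ==================
family  mu(d)                                       mean parameters
======  ==========================================  ==================
linear  b0 + b1*d                                   2
power   g + beta*d**delta          (delta >= 1)     3
hill    g + v*d**n/(k**n + d**n)   (n >= 1, k > 0)  4
exp2    a*exp(s*b*d)               (a, b > 0)       2
exp3    a*exp(s*(b*d)**c)          (c >= 1)         3
exp4    a*(c - (c-1)*exp(-b*d))    (c > 0)          3
exp5    a*(c - (c-1)*exp(-(b*d)**g))  (g >= 1)      4
======  ==========================================  ==================

s = +/-1 is the adverse direction, inferred from the data rather than fixed
in advance (metabolite intensities rise or fall with dose).  Observations are
modeled as y_i ~ Normal(mu(d_i), sigma^2) with a single shared sigma; the
sigma MLE is RSS/n so fitting reduces to nonlinear least squares on the mean.

Fitting uses variable projection: the conditionally linear parameters of each
family are solved exactly by least squares at every trial value of the
nonlinear shape parameters, which are themselves optimized over a
deterministic coarse grid followed by local refinement.  This replaces ad hoc
multi-start heuristics with an exhaustive deterministic search of the shape
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

FAMILIES = ("linear", "power", "hill", "exp2", "exp3", "exp4", "exp5")

#: number of mean parameters per family (sigma is counted separately in AIC)
N_MEAN_PARAMS = {
    "linear": 2, "power": 3, "hill": 4, "exp2": 2, "exp3": 3, "exp4": 3, "exp5": 4,
}

_MAX_EXPONENT = 18.0  # upper cap on power/Hill/exp shape exponents
_LOG_EPS = 1e-300


# ----------------------------------------------------------------------
# mean functions
# ----------------------------------------------------------------------
def mean_function(family: str, params: dict[str, float], d: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return _mean_function(family, params, np.asarray(d, dtype=float))


def _mean_function(family: str, params: dict[str, float], d: np.ndarray) -> np.ndarray:
    p = params
    if family == "linear":
        return p["b0"] + p["b1"] * d
    if family == "power":
        return p["g"] + p["beta"] * np.power(d, p["delta"])
    if family == "hill":
        with np.errstate(divide="ignore", invalid="ignore"):
            dn = np.power(d, p["n"])
            out = p["g"] + p["v"] * dn / (p["k"] ** p["n"] + dn)
        return np.where(d == 0, p["g"], out)
    if family == "exp2":
        return p["a"] * np.exp(np.clip(p["s"] * p["b"] * d, -700, 700))
    if family == "exp3":
        with np.errstate(over="ignore"):
            arg = p["s"] * np.power(p["b"] * d, p["c"])
        return p["a"] * np.exp(np.clip(arg, -700, 700))
    if family == "exp4":
        return p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-p["b"] * d))
    if family == "exp5":
        return p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-np.power(p["b"] * d, p["g"])))
    raise ValueError(f"unknown family {family!r}")


def control_mean(family: str, params: dict[str, float]) -> float:
    """mu(0): b0 / g for the polynomial-style families, a for the exponentials."""
    if family == "linear":
        return params["b0"]
    if family in ("power", "hill"):
        return params["g"]
    return params["a"]


# ----------------------------------------------------------------------
# fit result
# ----------------------------------------------------------------------
@dataclass
class ModelFit:
    """A single parametric dose-response fit for one feature."""

    family: str
    params: dict[str, float]
    sigma: float
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_mean_params: int
    bmr_factor: float | None = None
    bmd: float | None = None
    bmdl: float | None = None
    bmdu: float | None = None
    bmdl_reason: str | None = None
    bmdu_reason: str | None = None
    fit_p_value: float | None = None
    hill_k_flag: bool = False
    direction: int = 0

    def mu(self, d) -> np.ndarray:
        return mean_function(self.family, self.params, d)


# ----------------------------------------------------------------------
# variable-projection fitting
# ----------------------------------------------------------------------
def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _fit_linear(d, y):
    X = np.column_stack([np.ones_like(d), d])
    coef, rss = _lstsq_rss(X, y)
    return {"b0": float(coef[0]), "b1": float(coef[1])}, rss


def _fit_power(d, y, max_iter):
    dmax = d.max()
    ds = d / dmax  # scale doses to [0,1] for conditioning

    def rss_of(delta):
        X = np.column_stack([np.ones_like(ds), np.power(ds, delta)])
        _, rss = _lstsq_rss(X, y)
        return rss

    grid = np.concatenate([np.linspace(1.0, 4.0, 13), np.linspace(4.5, _MAX_EXPONENT, 10)])
    vals = [rss_of(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(rss_of, bounds=(lo, hi), method="bounded",
                                   options={"maxiter": max_iter, "xatol": 1e-6})
    delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    X = np.column_stack([np.ones_like(ds), np.power(ds, delta)])
    coef, rss = _lstsq_rss(X, y)
    # undo dose scaling: beta_s * (d/dmax)^delta = (beta_s/dmax^delta) * d^delta
    return {"g": float(coef[0]), "beta": float(coef[1] / dmax**delta),
            "delta": delta}, rss


def _fit_hill(d, y, max_iter):
    dmax = d.max()
    nz = np.unique(d[d > 0])

    def solve(n, k):
        dn = np.power(d, n)
        frac = np.where(d == 0, 0.0, dn / (k**n + dn))
        X = np.column_stack([np.ones_like(d), frac])
        coef, rss = _lstsq_rss(X, y)
        return coef, rss

    k_grid = np.geomspace(nz.min() / 10.0, dmax * 5.0, 12)
    n_grid = np.array([1.0, 1.5, 2.0, 3.0, 5.0, 8.0])
    best = None
    for n in n_grid:
        for k in k_grid:
            _, rss = solve(n, k)
            if best is None or rss < best[0]:
                best = (rss, n, k)
    _, n0, k0 = best

    def obj(z):
        n = 1.0 + math.exp(min(z[0], 5.0))
        if n > _MAX_EXPONENT:
            return np.inf
        k = math.exp(z[1])
        _, rss = solve(n, k)
        return rss

    z0 = [math.log(max(n0 - 1.0, 1e-6)), math.log(k0)]
    res = optimize.minimize(obj, z0, method="Nelder-Mead",
                            options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-12})
    z = res.x if res.fun <= best[0] else np.array(z0)
    n = min(1.0 + math.exp(min(z[0], 5.0)), _MAX_EXPONENT)
    k = math.exp(z[1])
    coef, rss = solve(n, k)
    return {"g": float(coef[0]), "v": float(coef[1]), "n": float(n),
            "k": float(k)}, rss


def _fit_exp2(d, y, max_iter):
    dmax = d.max()

    def solve(w):
        # mu = a * exp(w d); least squares through the origin
        e = np.exp(np.clip(w * d, -700, 700))
        denom = float(e @ e)
        if not np.isfinite(denom) or denom == 0:
            return 0.0, float(y @ y)
        a = float(y @ e) / denom
        r = y - a * e
        return a, float(r @ r)

    grid = np.concatenate([-np.geomspace(1e-3, 30.0, 20)[::-1], [0.0],
                           np.geomspace(1e-3, 30.0, 20)]) / dmax
    vals = [solve(w)[1] for w in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda w: solve(w)[1], bounds=(lo, hi),
                                   method="bounded",
                                   options={"maxiter": max_iter, "xatol": 1e-12})
    w = float(res.x) if res.fun <= vals[i] else float(grid[i])
    a, rss = solve(w)
    if a <= 0:  # intensity data; keep a > 0 by falling back to the flat model
        a, rss = solve(0.0)
        w = 0.0
    s = 1.0 if w >= 0 else -1.0
    return {"a": float(a), "b": abs(w), "s": s}, rss


def _fit_exp3(d, y, max_iter):
    dmax = d.max()

    def solve(c, w):
        e = np.exp(np.clip(w * np.power(d, c), -700, 700))
        denom = float(e @ e)
        if not np.isfinite(denom) or denom == 0:
            return 0.0, float(y @ y)
        a = float(y @ e) / denom
        r = y - a * e
        return a, float(r @ r)

    c_grid = np.array([1.0, 1.5, 2.0, 3.0, 5.0, 8.0])
    w_grid = np.concatenate([-np.geomspace(1e-3, 30.0, 12)[::-1],
                             np.geomspace(1e-3, 30.0, 12)])
    best = None
    for c in c_grid:
        for wd in w_grid:
            w = wd / dmax**c
            _, rss = solve(c, w)
            if best is None or rss < best[0]:
                best = (rss, c, w)
    _, c0, w0 = best

    def obj(z):
        c = 1.0 + math.exp(min(z[0], 5.0))
        if c > _MAX_EXPONENT:
            return np.inf
        _, rss = solve(c, z[1])
        return rss

    z0 = [math.log(max(c0 - 1.0, 1e-6)), w0]
    res = optimize.minimize(obj, z0, method="Nelder-Mead",
                            options={"maxiter": max_iter, "fatol": 1e-12})
    if res.fun <= best[0]:
        c = min(1.0 + math.exp(min(res.x[0], 5.0)), _MAX_EXPONENT)
        w = float(res.x[1])
    else:
        c, w = c0, w0
    a, rss = solve(c, w)
    if a <= 0:
        a = float(np.mean(y))
        rss = float(((y - a) ** 2).sum())
        c, w = 1.0, 0.0
    s = 1.0 if w >= 0 else -1.0
    b = abs(w) ** (1.0 / c) if w != 0 else 0.0
    return {"a": float(a), "b": float(b), "c": float(c), "s": s}, rss


def _exp4_solve(d, y, b):
    # mu = A + B*exp(-b d) with A = a*c, B = -a*(c-1); a = A + B, c = A/(A+B)
    e = np.exp(-np.clip(b * d, 0, 700))
    X = np.column_stack([np.ones_like(d), e])
    coef, rss = _lstsq_rss(X, y)
    A, B = float(coef[0]), float(coef[1])
    a = A + B
    if a <= 0 or A <= 0:  # violates a > 0, c > 0
        return None, 1e300
    c = A / a
    return {"a": a, "b": b, "c": c}, rss


def _fit_exp4(d, y, max_iter):
    dmax = d.max()
    grid = np.geomspace(0.03, 100.0, 25) / dmax

    def rss_of(logb):
        _, rss = _exp4_solve(d, y, math.exp(logb))
        return rss

    vals = [rss_of(math.log(b)) for b in grid]
    i = int(np.argmin(vals))
    if vals[i] >= 1e300:
        p, rss = _flat_params(y)
        return {"a": p, "b": 0.0, "c": 1.0}, rss
    lo = math.log(grid[max(i - 1, 0)])
    hi = math.log(grid[min(i + 1, len(grid) - 1)])
    res = optimize.minimize_scalar(rss_of, bounds=(lo, hi), method="bounded",
                                   options={"maxiter": max_iter, "xatol": 1e-10})
    logb = float(res.x) if res.fun <= vals[i] else math.log(grid[i])
    params, rss = _exp4_solve(d, y, math.exp(logb))
    if params is None:
        p, rss = _flat_params(y)
        return {"a": p, "b": 0.0, "c": 1.0}, rss
    return params, rss


def _exp5_solve(d, y, b, g):
    e = np.exp(-np.clip(np.power(b * d, g), 0, 700))
    X = np.column_stack([np.ones_like(d), e])
    coef, rss = _lstsq_rss(X, y)
    A, B = float(coef[0]), float(coef[1])
    a = A + B
    if a <= 0 or A <= 0:
        return None, 1e300
    return {"a": a, "b": b, "c": A / a, "g": g}, rss


def _fit_exp5(d, y, max_iter):
    dmax = d.max()
    b_grid = np.geomspace(0.03, 100.0, 15) / dmax
    g_grid = np.array([1.0, 1.5, 2.0, 3.0, 5.0, 8.0])
    best = None
    for g in g_grid:
        for b in b_grid:
            _, rss = _exp5_solve(d, y, b, g)
            if best is None or rss < best[0]:
                best = (rss, b, g)
    if best[0] >= 1e300:
        p, rss = _flat_params(y)
        return {"a": p, "b": 0.0, "c": 1.0, "g": 1.0}, rss
    _, b0, g0 = best

    def obj(z):
        g = 1.0 + math.exp(min(z[1], 5.0))
        if g > _MAX_EXPONENT:
            return np.inf
        _, rss = _exp5_solve(d, y, math.exp(z[0]), g)
        return rss

    z0 = [math.log(b0), math.log(max(g0 - 1.0, 1e-6))]
    res = optimize.minimize(obj, z0, method="Nelder-Mead",
                            options={"maxiter": max_iter, "fatol": 1e-12})
    if res.fun <= best[0]:
        b = math.exp(res.x[0])
        g = min(1.0 + math.exp(min(res.x[1], 5.0)), _MAX_EXPONENT)
    else:
        b, g = b0, g0
    params, rss = _exp5_solve(d, y, b, g)
    if params is None:
        p, rss = _flat_params(y)
        return {"a": p, "b": 0.0, "c": 1.0, "g": 1.0}, rss
    return params, rss


def _flat_params(y):
    m = float(np.mean(y))
    return m, float(((y - m) ** 2).sum())


_FITTERS = {
    "linear": lambda d, y, it: _fit_linear(d, y),
    "power": _fit_power,
    "hill": _fit_hill,
    "exp2": _fit_exp2,
    "exp3": _fit_exp3,
    "exp4": _fit_exp4,
    "exp5": _fit_exp5,
}


def _loglik_from_rss(rss: float, n: int) -> float:
    sigma2 = max(rss / n, _LOG_EPS)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + rss / (n * sigma2))


def fit_model(values, doses, family: str, max_iter: int = 250) -> ModelFit:
    """Maximum-likelihood fit of one model family to one feature.

    Parameters
    ----------
    values, doses
        Per-sample intensity and dose vectors (study samples only, no
        missing values).
    family
        One of :data:`FAMILIES`.
    max_iter
        Iteration budget for the shape-parameter refinement stage.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(doses, dtype=float)
    if y.shape != d.shape:
        raise ValueError("values and doses must align")
    if np.isnan(y).any():
        raise ValueError("values must be imputed before model fitting")
    n_doses = len(np.unique(d))
    p_mean = N_MEAN_PARAMS[family]
    if 0.0 not in d or n_doses < 4:
        raise ValueError("need observations at >= 4 distinct doses including 0")
    if n_doses < p_mean:
        raise ValueError(
            f"{family}: fewer distinct doses ({n_doses}) than mean parameters ({p_mean})"
        )
    n = y.size
    try:
        params, rss = _FITTERS[family](d, y, max_iter)
        converged = np.isfinite(rss)
    except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
        params, rss, converged = {}, float("nan"), False
    if not converged:
        return ModelFit(family=family, params=params, sigma=float("nan"),
                        loglik=float("-inf"), aic=float("inf"), converged=False,
                        n_obs=n, n_mean_params=p_mean)
    sigma = math.sqrt(rss / n)
    ll = _loglik_from_rss(rss, n)
    aic = 2.0 * (p_mean + 1) - 2.0 * ll
    mu_lo = control_mean(family, params)
    mu_hi = float(mean_function(family, params, np.array([d.max()]))[0])
    direction = int(np.sign(mu_hi - mu_lo))
    return ModelFit(family=family, params=params, sigma=sigma, loglik=ll,
                    aic=aic, converged=True, n_obs=n, n_mean_params=p_mean,
                    direction=direction)


# ----------------------------------------------------------------------
# BMD
# ----------------------------------------------------------------------
def bmd_from_params(family: str, params: dict[str, float], sigma: float,
                    bmr_factor: float, max_dose: float,
                    bracket_factor: float = 10.0) -> float | None:
    """Smallest d > 0 with |mu(d) - mu(0)| = bmr_factor * sigma.

    Closed form for the linear family; bracketed root finding on
    [0, bracket_factor * max_dose] otherwise.  Returns None when the curve
    never departs the baseline by the benchmark response within the bracket.
    """
    if bmr_factor <= 0:
        raise ValueError("bmr_factor must be > 0")
    target = bmr_factor * sigma
    if family == "linear":
        b1 = params["b1"]
        if b1 == 0:
            return None
        return target / abs(b1)
    mu0 = control_mean(family, params)

    def depart(dd):
        return abs(float(mean_function(family, params, np.array([dd]))[0]) - mu0)

    hi = bracket_factor * max_dose
    if target == 0.0:
        return 0.0 if depart(hi) > 0 else None
    if depart(hi) < target:
        return None

    f = lambda dd: depart(dd) - target
    try:
        root = optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12, maxiter=200)
    except ValueError:
        return None
    return float(root)


def compute_bmd(fit: ModelFit, bmr_factor: float, max_dose: float) -> ModelFit:
    """Attach the BMD at the given SD-multiple BMR to a converged fit."""
    if not fit.converged:
        fit.bmr_factor = bmr_factor
        fit.bmd = None
        return fit
    fit.bmr_factor = bmr_factor
    fit.bmd = bmd_from_params(fit.family, fit.params, fit.sigma, bmr_factor,
                              max_dose)
    return fit


# ----------------------------------------------------------------------
# profile-likelihood confidence limits
# ----------------------------------------------------------------------
def _pack(family: str, p: dict[str, float]) -> np.ndarray:
    if family == "linear":
        return np.array([p["b0"], p["b1"]])
    if family == "power":
        return np.array([p["g"], p["beta"], math.log(max(p["delta"] - 1.0, 1e-9))])
    if family == "hill":
        return np.array([p["g"], p["v"], math.log(max(p["n"] - 1.0, 1e-9)),
                         math.log(p["k"])])
    if family == "exp2":
        return np.array([math.log(max(p["a"], 1e-12)), p["s"] * p["b"]])
    if family == "exp3":
        return np.array([math.log(max(p["a"], 1e-12)),
                         math.log(max(p["c"] - 1.0, 1e-9)),
                         p["s"] * p["b"] ** p["c"]])
    if family == "exp4":
        return np.array([math.log(max(p["a"], 1e-12)),
                         math.log(max(p["b"], 1e-12)),
                         math.log(max(p["c"], 1e-12))])
    if family == "exp5":
        return np.array([math.log(max(p["a"], 1e-12)),
                         math.log(max(p["b"], 1e-12)),
                         math.log(max(p["c"], 1e-12)),
                         math.log(max(p["g"] - 1.0, 1e-9))])
    raise ValueError(family)


def _unpack(family: str, z: np.ndarray) -> dict[str, float]:
    if family == "linear":
        return {"b0": z[0], "b1": z[1]}
    if family == "power":
        return {"g": z[0], "beta": z[1],
                "delta": min(1.0 + math.exp(min(z[2], 5.0)), _MAX_EXPONENT)}
    if family == "hill":
        return {"g": z[0], "v": z[1],
                "n": min(1.0 + math.exp(min(z[2], 5.0)), _MAX_EXPONENT),
                "k": math.exp(np.clip(z[3], -300, 300))}
    if family == "exp2":
        w = z[1]
        return {"a": math.exp(np.clip(z[0], -300, 300)), "b": abs(w),
                "s": 1.0 if w >= 0 else -1.0}
    if family == "exp3":
        c = min(1.0 + math.exp(min(z[1], 5.0)), _MAX_EXPONENT)
        w = z[2]
        b = abs(w) ** (1.0 / c) if w != 0 else 0.0
        return {"a": math.exp(np.clip(z[0], -300, 300)), "b": b, "c": c,
                "s": 1.0 if w >= 0 else -1.0}
    if family == "exp4":
        return {"a": math.exp(np.clip(z[0], -300, 300)),
                "b": math.exp(np.clip(z[1], -300, 300)),
                "c": math.exp(np.clip(z[2], -300, 300))}
    if family == "exp5":
        return {"a": math.exp(np.clip(z[0], -300, 300)),
                "b": math.exp(np.clip(z[1], -300, 300)),
                "c": math.exp(np.clip(z[2], -300, 300)),
                "g": min(1.0 + math.exp(min(z[3], 5.0)), _MAX_EXPONENT)}
    raise ValueError(family)


def _profile_loglik(family: str, z0: np.ndarray, bmd: float, bmr_factor: float,
                    d: np.ndarray, y: np.ndarray,
                    max_iter: int = 400) -> tuple[float, np.ndarray]:
    """Max log-likelihood over mean parameters with the BMD pinned at ``bmd``.

    The BMD definition |mu(bmd) - mu(0)| = bmr * sigma pins sigma to
    |mu(bmd) - mu(0)| / bmr, so the profile is an unconstrained optimization
    over the mean parameters alone.
    """
    n = y.size
    d_bmd = np.array([bmd])

    def negll(z):
        p = _unpack(family, z)
        try:
            mu = mean_function(family, p, d)
            mu_b = float(mean_function(family, p, d_bmd)[0])
        except (OverflowError, FloatingPointError):
            return 1e300
        if not np.all(np.isfinite(mu)) or not np.isfinite(mu_b):
            return 1e300
        sigma = abs(mu_b - control_mean(family, p)) / bmr_factor
        if sigma <= 0:
            return 1e300
        rss = float(((y - mu) ** 2).sum())
        return 0.5 * n * math.log(2.0 * math.pi * sigma * sigma) + rss / (2.0 * sigma * sigma)

    res = optimize.minimize(negll, z0, method="Nelder-Mead",
                            options={"maxiter": max_iter, "xatol": 1e-9,
                                     "fatol": 1e-9, "adaptive": True})
    if not res.success:
        # restart once from the stall point (Nelder-Mead can collapse early)
        res2 = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                 options={"maxiter": max_iter, "xatol": 1e-10,
                                          "fatol": 1e-10})
        if res2.fun < res.fun:
            res = res2
    return -res.fun, res.x


def profile_bmdl_bmdu(fit: ModelFit, values, doses, confidence: float = 0.95,
                      max_dose: float | None = None,
                      sides: tuple[str, ...] = ("lower", "upper")) -> ModelFit:
    """Profile-likelihood BMDL and BMDU at a one-sided confidence level.

    The likelihood is reparameterized so the BMD is explicit (sigma is
    eliminated through the BMR equation); the bound is where the profile
    log-likelihood drops by half the chi-square(1) quantile at 2c-1 — the
    standard correspondence between a one-sided bound at level c and a
    two-sided likelihood-ratio interval.
    """
    if fit.bmd is None or not fit.converged or fit.bmr_factor is None:
        raise ValueError("fit must be converged with a defined BMD")
    y = np.asarray(values, dtype=float)
    d = np.asarray(doses, dtype=float)
    if max_dose is None:
        max_dose = float(d.max())
    cut = stats.chi2.ppf(2.0 * confidence - 1.0, 1)
    z_hat = _pack(fit.family, fit.params)
    ll_hat = fit.loglik
    bmd = fit.bmd
    cache: dict[float, tuple[float, np.ndarray]] = {}

    def g(b, z_start):
        if b in cache:
            ll, _ = cache[b]
        else:
            ll, z = _profile_loglik(fit.family, z_start, b, fit.bmr_factor, d, y)
            ll = min(ll, ll_hat)  # profile cannot exceed the global optimum
            cache[b] = (ll, z)
        return 2.0 * (ll_hat - ll) - cut

    def search(side: str):
        # geometric expansion away from the MLE until the profile crosses the
        # cutoff, then bisection on the bracket
        z_start = z_hat
        prev = bmd
        if side == "lower":
            candidates = bmd * 0.5 ** np.arange(1, 40)
            edge = bmd * 1e-10
        else:
            hi_edge = max(10.0 * max_dose, bmd * 8.0)
            candidates = bmd * 2.0 ** np.arange(1, 40)
            candidates = candidates[candidates <= hi_edge]
            candidates = np.append(candidates, hi_edge)
            edge = hi_edge
        for b in candidates:
            val = g(float(b), z_start)
            z_start = cache[float(b)][1]
            if val > 0:
                lo, hi = (float(b), prev) if side == "lower" else (prev, float(b))
                try:
                    root = optimize.brentq(lambda x: g(x, cache_nearest(x)),
                                           lo, hi, xtol=max(bmd * 1e-4, 1e-12),
                                           rtol=1e-5, maxiter=60)
                except ValueError:
                    return None, "bracketing failed"
                return float(root), None
            prev = float(b)
            if (side == "lower" and b <= edge) or (side == "upper" and b >= edge):
                break
        return None, "profile flat to bracket edge"

    def cache_nearest(x):
        keys = np.array(list(cache.keys()))
        return cache[float(keys[np.argmin(np.abs(np.log(keys) - np.log(x)))])][1]

    if "lower" in sides:
        bmdl, reason_l = search("lower")
        fit.bmdl = min(bmdl, bmd) if bmdl is not None else None
        fit.bmdl_reason = reason_l
    if "upper" in sides:
        bmdu, reason_u = search("upper")
        fit.bmdu = max(bmdu, bmd) if bmdu is not None else None
        fit.bmdu_reason = reason_u
    return fit


# ----------------------------------------------------------------------
# goodness of fit and model selection
# ----------------------------------------------------------------------
def fit_p_value(fit: ModelFit, values, doses) -> ModelFit:
    """Lack-of-fit p-value against the saturated dose-group-means model.

    Both models share a single constant variance.  The deviance between the
    fitted mean function and the saturated means is referred to an F
    distribution with (number of dose groups - number of mean parameters,
    n - number of dose groups) degrees of freedom — the exact small-sample
    form of the likelihood-ratio lack-of-fit test (the two are monotone
    transformations of each other; the F calibration is exact under the
    normal model where the chi-square form is anticonservative at the
    replicate counts of a typical in-vivo study).  df <= 0 leaves p
    undefined (None); a p of 1 means the model reproduces the group means.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(doses, dtype=float)
    groups = np.unique(d)
    g = len(groups)
    df1 = g - fit.n_mean_params
    n = y.size
    df2 = n - g
    if df1 <= 0 or df2 <= 0:
        fit.fit_p_value = None
        return fit
    rss_sat = 0.0
    for gdose in groups:
        sub = y[d == gdose]
        rss_sat += float(((sub - sub.mean()) ** 2).sum())
    mu = fit.mu(d)
    rss_model = float(((y - mu) ** 2).sum())
    if rss_sat <= 0:
        fit.fit_p_value = 1.0 if rss_model <= 1e-12 else 0.0
        return fit
    f_stat = max(rss_model - rss_sat, 0.0) / df1 / (rss_sat / df2)
    fit.fit_p_value = float(stats.f.sf(f_stat, df1, df2))
    return fit


def apply_hill_flag(fit: ModelFit, lowest_nonzero_dose: float) -> ModelFit:
    """Flag Hill fits whose half-max dose k is below lowest nonzero dose / 3."""
    fit.hill_k_flag = (fit.family == "hill"
                       and fit.params.get("k", math.inf) < lowest_nonzero_dose / 3.0)
    return fit


def select_best_model(fits: list[ModelFit], lowest_nonzero_dose: float,
                      p_screen: float = 0.05) -> ModelFit | None:
    """Lowest-AIC fit among viable candidates.

    Discards non-converged fits, fits with undefined BMD, fits failing the
    lack-of-fit screen at ``p_screen``, and flagged Hill fits (half-max dose
    below a third of the lowest tested dose).  Returns None when no fit
    survives.  Ties on AIC break deterministically by family order.
    """
    viable = []
    for f in fits:
        if not f.converged or f.bmd is None or f.bmd <= 0:
            continue
        if f.fit_p_value is None or f.fit_p_value <= p_screen:
            continue
        apply_hill_flag(f, lowest_nonzero_dose)
        if f.hill_k_flag:
            continue
        viable.append(f)
    if not viable:
        return None
    return min(viable, key=lambda f: (f.aic, FAMILIES.index(f.family)))


def fit_all_models(values, doses, max_iter: int = 250,
                   families: tuple[str, ...] = FAMILIES) -> list[ModelFit]:
    """Fit every model family to one feature; non-viable families skipped."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_model(values, doses, fam, max_iter=max_iter))
        except ValueError:
            continue
    return fits
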