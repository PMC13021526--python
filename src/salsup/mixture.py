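"""Ex-Gaussian RT distributions and two-component capture mixtures.

The reaction-time model treats every distractor-present search trial as coming
from one of two latent populations: trials where attention went straight to the
target (the *no-capture* curve, estimated from distractor-absent trials) and
trials where attention was first captured by the distractor (the *capture*
curve).  The observed RT density for a condition is the convex combination

    f_cond(t) = (1 - p) * f_baseline(t) + p * f_capture(t)

with capture probability ``p`` constrained to [0.2, 0.8] so the baseline curve
always retains influence.  Three nested variants are compared:

* ``capture``        — one shared capture curve, separate p for the
                       high-probability (HP) and low-probability (LP)
                       distractor conditions (5 free parameters);
* ``disengagement``  — separate capture curves per condition, one shared p
                       (7 free parameters);
* ``combined``       — both curves and both probabilities free (8 parameters).

Curves are exponentially modified Gaussians parameterized by skew ``K``
(dimensionless, tau/sigma), midpoint ``loc`` (ms) and spread ``scale`` (ms) —
the same (K, loc, scale) convention as :data:`scipy.stats.exponnorm`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger("salsup.mixture")

__all__ = [
    "ExGaussParams",
    "MixtureFit",
    "ModelComparison",
    "exgauss_logpdf",
    "exgauss_pdf",
    "exgauss_cdf",
    "exgauss_median",
    "exgauss_rvs",
    "fit_exgauss",
    "fit_baseline",
    "BaselineFit",
    "fit_mixture",
    "information_criteria",
    "compare_models",
    "per_participant_comparison",
    "CAPTURE_BOUNDS",
]

ModelKind = Literal["capture", "disengagement", "combined"]

#: Floor/ceiling on the capture probability; keeps the baseline curve
#: continuously influential in every fitted mixture.
CAPTURE_BOUNDS: tuple[float, float] = (0.2, 0.8)

_SQRT2 = math.sqrt(2.0)
_MODEL_NPARAMS: dict[str, int] = {"capture": 5, "disengagement": 7, "combined": 8}


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of an exponentially modified Gaussian RT curve.

    ``K`` is the skew (ratio of the exponential time constant to the Gaussian
    spread), ``loc`` the Gaussian midpoint in ms and ``scale`` the Gaussian
    spread in ms.  Equivalent to the classic (mu, sigma, tau) form via
    mu = loc, sigma = scale, tau = K * scale.
    """

    K: float
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.K > 0 and np.isfinite(self.K)):
            raise ValueError(f"K must be positive and finite, got {self.K}")
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if not np.isfinite(self.loc):
            raise ValueError(f"loc must be finite, got {self.loc}")

    @property
    def tau(self) -> float:
        """Exponential time constant in ms."""
        return self.K * self.scale

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.K, self.loc, self.scale)

    def to_dict(self) -> dict[str, float]:
        return {"K": self.K, "loc": self.loc, "scale": self.scale}


# ---------------------------------------------------------------------------
# Density, CDF, median, sampling
# ---------------------------------------------------------------------------

def exgauss_logpdf(rt, params: ExGaussParams):
    """Log-density of the ex-Gaussian at ``rt`` (ms).

    Computed in log space throughout.  Where the erfc factor underflows
    (deep left tail of the exponential component) the scaled complementary
    error function ``erfcx`` is used: log erfc(t) = log erfcx(t) - t**2.
    Never returns NaN for finite input.
    """
    rt = np.asarray(rt, dtype=float)
    K, loc, scale = params.K, params.loc, params.scale
    y = (rt - loc) / scale
    t = (1.0 / K - y) / _SQRT2  # = -(y - 1/K)/sqrt(2)
    # log erfc(t): direct branch fine for t < 0 (erfc in (1, 2));
    # erfcx branch stable for arbitrarily large positive t.
    pos = t >= 0.0
    log_erfc = np.empty_like(y)
    tp = np.where(pos, t, 0.0)
    log_erfc = np.where(
        pos,
        np.log(special.erfcx(tp)) - tp * tp,
        np.log(special.erfc(np.where(pos, 0.0, t))),
    )
    return -np.log(2.0 * K * scale) + 1.0 / (2.0 * K * K) - y / K + log_erfc


def exgauss_pdf(rt, params: ExGaussParams):
    """Density of the ex-Gaussian at ``rt`` (ms); integrates to one."""
    return np.exp(exgauss_logpdf(rt, params))


def exgauss_cdf(rt, params: ExGaussParams):
    """CDF of the ex-Gaussian, evaluated stably via log-space Gaussian tails."""
    rt = np.asarray(rt, dtype=float)
    K, loc, scale = params.K, params.loc, params.scale
    u = (rt - loc) / scale
    # F(x) = Phi(u) - exp(1/(2K^2) - u/K) * Phi(u - 1/K), second term in logs
    log_term = 1.0 / (2.0 * K * K) - u / K + special.log_ndtr(u - 1.0 / K)
    val = special.ndtr(u) - np.exp(log_term)
    return np.clip(val, 0.0, 1.0)


def exgauss_median(params: ExGaussParams) -> float:
    """Median RT (ms): the root of CDF(m) = 1/2, located to ±0.01 ms."""
    mean = params.loc + params.tau
    spread = params.scale + params.tau
    lo, hi = mean - 50.0 * spread, mean + 50.0 * spread
    return float(
        optimize.brentq(lambda m: exgauss_cdf(m, params) - 0.5, lo, hi, xtol=1e-3)
    )


def exgauss_rvs(
    params: ExGaussParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` RTs: loc + scale * (Z + K * E), Z ~ N(0,1), E ~ Exp(1)."""
    z = rng.standard_normal(size)
    e = rng.standard_exponential(size)
    return params.loc + params.scale * (z + params.K * e)


# ---------------------------------------------------------------------------
# Baseline (no-distractor) fitting and the distribution-family comparison
# ---------------------------------------------------------------------------

def _moment_start(rts: np.ndarray) -> tuple[float, float, float]:
    """Classic moment-based ex-Gaussian start (tau from the skewness)."""
    m, s = float(np.mean(rts)), float(np.std(rts, ddof=1))
    g = float(stats.skew(rts))
    g = min(max(g, 0.05), 2.0)
    tau = s * (g / 2.0) ** (1.0 / 3.0)
    sigma2 = s * s * max(1.0 - (g / 2.0) ** (2.0 / 3.0), 0.05)
    sigma = math.sqrt(sigma2)
    mu = m - tau
    return tau / sigma, mu, sigma  # (K, loc, scale)


def _exgauss_nll(theta: np.ndarray, rts: np.ndarray) -> float:
    k, loc, log_scale = theta
    if not np.isfinite(theta).all():
        return 1e12
    try:
        p = ExGaussParams(math.exp(k), loc, math.exp(log_scale))
    except (ValueError, OverflowError):
        return 1e12
    ll = exgauss_logpdf(rts, p)
    val = -float(np.sum(ll))
    return val if np.isfinite(val) else 1e12


def fit_exgauss(
    rts: Sequence[float], n_starts: int = 8, seed: int = 0
) -> tuple[ExGaussParams, float]:
    """Maximum-likelihood ex-Gaussian fit with seeded multi-start.

    Returns the fitted parameters and the attained negative log-likelihood.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 5:
        raise ValueError("need at least 5 RTs to fit an ex-Gaussian")
    rng = np.random.default_rng(seed)
    K0, loc0, scale0 = _moment_start(rts)
    best: tuple[float, np.ndarray] | None = None
    for i in range(n_starts):
        if i == 0:
            x0 = np.array([math.log(K0), loc0, math.log(scale0)])
        else:
            x0 = np.array(
                [
                    math.log(K0) + rng.normal(0, 0.5),
                    loc0 + rng.normal(0, 0.5 * scale0),
                    math.log(scale0) + rng.normal(0, 0.4),
                ]
            )
        res = optimize.minimize(
            _exgauss_nll, x0, args=(rts,), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x)
    nll, x = best
    return ExGaussParams(math.exp(x[0]), x[1], math.exp(x[2])), nll


@dataclass
class BaselineFit:
    """Result of fitting candidate RT distribution families to no-distractor trials."""

    params: ExGaussParams
    nll: float
    family_table: pd.DataFrame  # columns: family, nll, n_params, bic, converged
    n_obs: int

    @property
    def winner(self) -> str:
        ok = self.family_table[self.family_table["converged"]]
        return str(ok.loc[ok["bic"].idxmin(), "family"])


_SCIPY_FAMILIES: dict[str, stats.rv_continuous] = {
    "lognormal": stats.lognorm,
    "weibull": stats.weibull_min,
    "chi_squared": stats.chi2,
    "inverse_gamma": stats.invgamma,
}


def fit_baseline(rts: Sequence[float], n_starts: int = 8, seed: int = 0) -> BaselineFit:
    """Fit the no-distractor RT distribution and compare candidate families.

    Five families are fitted by maximum likelihood (log-normal, Weibull,
    chi-squared, inverse-gamma via their scipy three-parameter forms; the
    ex-Gaussian via the in-package seeded multi-start optimizer) and ranked
    by BIC.  The returned ex-Gaussian is the mixture baseline regardless of
    which family wins; the table records the comparison.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 50:
        raise ValueError(f"need at least 50 no-distractor RTs, got {rts.size}")
    n = rts.size
    rows = []
    exg_params, exg_nll = fit_exgauss(rts, n_starts=n_starts, seed=seed)
    rows.append(("ex_gaussian", exg_nll, 3, True))
    lo = float(rts.min())
    for name, dist in _SCIPY_FAMILIES.items():
        try:
            # anchor loc below the sample minimum; these families have
            # left-bounded support
            shape, loc, scale = dist.fit(rts, loc=lo - 50.0)
            nll = -float(np.sum(dist.logpdf(rts, shape, loc, scale)))
            ok = np.isfinite(nll)
        except Exception:  # optimizer failure on a family: mark unfit
            nll, ok = np.inf, False
        rows.append((name, nll, 3, ok))
    table = pd.DataFrame(rows, columns=["family", "nll", "n_params", "converged"])
    table["bic"] = table["n_params"] * math.log(n) + 2.0 * table["nll"]
    table = table[["family", "nll", "n_params", "bic", "converged"]]
    return BaselineFit(params=exg_params, nll=exg_nll, family_table=table, n_obs=n)


# ---------------------------------------------------------------------------
# Mixture fitting
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """A fitted two-component capture mixture for the HP and LP conditions."""

    model_kind: ModelKind
    baseline: ExGaussParams
    capture_curve_hp: ExGaussParams
    capture_curve_lp: ExGaussParams
    p_capture_hp: float
    p_capture_lp: float
    n_params: int
    objective: Literal["mle", "binned"]
    objective_value: float  # NLL (mle) or SSE (binned)
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    boundary_pinned: bool = False

    def condition_logpdf(self, rt, condition: Literal["hp", "lp"]):
        """Log mixture density for one condition at ``rt`` (ms)."""
        p = self.p_capture_hp if condition == "hp" else self.p_capture_lp
        curve = self.capture_curve_hp if condition == "hp" else self.capture_curve_lp
        lb = exgauss_logpdf(rt, self.baseline)
        lc = exgauss_logpdf(rt, curve)
        return np.logaddexp(np.log1p(-p) + lb, math.log(p) + lc)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "baseline": self.baseline.to_dict(),
            "capture_curve_hp": self.capture_curve_hp.to_dict(),
            "capture_curve_lp": self.capture_curve_lp.to_dict(),
            "p_capture_hp": self.p_capture_hp,
            "p_capture_lp": self.p_capture_lp,
            "n_params": self.n_params,
            "objective": self.objective,
            "objective_value": self.objective_value,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary_pinned": self.boundary_pinned,
        }


def _p_from_raw(a: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return lo + (hi - lo) * special.expit(a)


def _raw_from_p(p: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    frac = np.clip((p - lo) / (hi - lo), 1e-6, 1 - 1e-6)
    return float(special.logit(frac))


def _unpack(theta: np.ndarray, model_kind: str, bounds: tuple[float, float]):
    """theta -> (curve_hp, curve_lp, p_hp, p_lp); shared pieces aliased."""
    if model_kind == "capture":
        k, loc, ls, a_hp, a_lp = theta
        curve = (math.exp(k), loc, math.exp(ls))
        return curve, curve, _p_from_raw(a_hp, bounds), _p_from_raw(a_lp, bounds)
    if model_kind == "disengagement":
        k1, l1, s1, k2, l2, s2, a = theta
        p = _p_from_raw(a, bounds)
        return (math.exp(k1), l1, math.exp(s1)), (math.exp(k2), l2, math.exp(s2)), p, p
    if model_kind == "combined":
        k1, l1, s1, k2, l2, s2, a_hp, a_lp = theta
        return (
            (math.exp(k1), l1, math.exp(s1)),
            (math.exp(k2), l2, math.exp(s2)),
            _p_from_raw(a_hp, bounds),
            _p_from_raw(a_lp, bounds),
        )
    raise ValueError(f"unknown model_kind {model_kind!r}")


def _curve_logpdf(rt: np.ndarray, curve: tuple[float, float, float]) -> np.ndarray:
    K, loc, scale = curve
    y = (rt - loc) / scale
    t = (1.0 / K - y) / _SQRT2
    pos = t >= 0.0
    tp = np.where(pos, t, 0.0)
    log_erfc = np.where(
        pos,
        np.log(special.erfcx(tp)) - tp * tp,
        np.log(special.erfc(np.where(pos, 0.0, t))),
    )
    return -math.log(2.0 * K * scale) + 1.0 / (2.0 * K * K) - y / K + log_erfc


class _MixtureObjective:
    """Negative log-likelihood (or binned SSE) of the two-condition mixture.

    The baseline log-density for each data point is precomputed once since the
    baseline curve is fixed throughout the optimization.
    """

    def __init__(
        self,
        hp_rts: np.ndarray,
        lp_rts: np.ndarray,
        baseline: ExGaussParams,
        model_kind: str,
        objective: str,
        bounds: tuple[float, float],
        bin_range: tuple[float, float] = (300.0, 2000.0),
        n_bins: int = 50,
    ) -> None:
        self.model_kind = model_kind
        self.kind = objective
        self.bounds = bounds
        self.baseline = baseline
        if objective == "mle":
            self.hp = hp_rts
            self.lp = lp_rts
            self.base_hp = exgauss_logpdf(hp_rts, baseline)
            self.base_lp = exgauss_logpdf(lp_rts, baseline)
            self.n_obs = hp_rts.size + lp_rts.size
        else:  # binned least squares on normalized histograms
            edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
            self.centers = 0.5 * (edges[:-1] + edges[1:])
            self.dens_hp = np.histogram(hp_rts, bins=edges, density=True)[0]
            self.dens_lp = np.histogram(lp_rts, bins=edges, density=True)[0]
            self.base_c = exgauss_logpdf(self.centers, baseline)
            self.n_obs = 2 * n_bins

    def __call__(self, theta: np.ndarray) -> float:
        if not np.isfinite(theta).all() or np.abs(theta[1]) > 1e6:
            return 1e12
        try:
            curve_hp, curve_lp, p_hp, p_lp = _unpack(theta, self.model_kind, self.bounds)
        except (OverflowError, ValueError):
            return 1e12
        if min(curve_hp[0], curve_lp[0]) < 1e-4 or min(curve_hp[2], curve_lp[2]) < 1e-6:
            return 1e12
        if self.kind == "mle":
            ll_hp = np.logaddexp(
                math.log1p(-p_hp) + self.base_hp,
                math.log(p_hp) + _curve_logpdf(self.hp, curve_hp),
            )
            ll_lp = np.logaddexp(
                math.log1p(-p_lp) + self.base_lp,
                math.log(p_lp) + _curve_logpdf(self.lp, curve_lp),
            )
            val = -(float(np.sum(ll_hp)) + float(np.sum(ll_lp)))
        else:
            model_hp = np.exp(
                np.logaddexp(
                    math.log1p(-p_hp) + self.base_c,
                    math.log(p_hp) + _curve_logpdf(self.centers, curve_hp),
                )
            )
            model_lp = np.exp(
                np.logaddexp(
                    math.log1p(-p_lp) + self.base_c,
                    math.log(p_lp) + _curve_logpdf(self.centers, curve_lp),
                )
            )
            val = float(
                np.sum((model_hp - self.dens_hp) ** 2)
                + np.sum((model_lp - self.dens_lp) ** 2)
            )
        return val if np.isfinite(val) else 1e12

    def loglik(self, objective_value: float) -> float:
        """Log-likelihood implied by the objective (Gaussian-error form in binned mode)."""
        if self.kind == "mle":
            return -objective_value
        n = self.n_obs
        sigma2 = max(objective_value / n, 1e-300)
        return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _mixture_starts(
    hp_rts: np.ndarray,
    lp_rts: np.ndarray,
    baseline: ExGaussParams,
    model_kind: str,
    n_starts: int,
    seed: int,
    bounds: tuple[float, float],
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)

    def tail_start(rts: np.ndarray) -> np.ndarray:
        # the capture component sits in the slow tail: moment-start on the
        # upper half of the condition's RTs
        upper = rts[rts > np.median(rts)]
        K0, loc0, scale0 = _moment_start(upper if upper.size >= 20 else rts)
        return np.array([math.log(K0), loc0, math.log(scale0)])

    pooled = np.concatenate([hp_rts, lp_rts])
    base = tail_start(pooled)
    base_hp = tail_start(hp_rts)
    base_lp = tail_start(lp_rts)
    scale0 = math.exp(base[2])
    a0 = _raw_from_p(0.5, bounds)

    def jitter() -> np.ndarray:
        return np.array(
            [rng.normal(0, 0.5), rng.normal(0, 0.6 * scale0), rng.normal(0, 0.4)]
        )

    starts = []
    for i in range(n_starts):
        cold = i > 0
        curve = base + (jitter() if cold else 0.0)
        a_jit = rng.normal(0, 1.2) if cold else 0.0
        if model_kind == "capture":
            starts.append(np.concatenate([curve, [a0 + a_jit, a0 - a_jit]]))
        else:
            # per-condition moment starts seed the two-curve models
            c_hp = (base_hp if not cold else base_hp + jitter())
            c_lp = (base_lp if not cold else base_lp + jitter())
            if model_kind == "disengagement":
                starts.append(np.concatenate([c_hp, c_lp, [a0 + a_jit]]))
            else:
                starts.append(np.concatenate([c_hp, c_lp, [a0 + a_jit, a0 - a_jit]]))
    return starts


def fit_mixture(
    hp_rts: Sequence[float],
    lp_rts: Sequence[float],
    baseline: ExGaussParams,
    model_kind: ModelKind,
    objective: Literal["mle", "binned"] = "mle",
    n_starts: int = 16,
    seed: int = 0,
    capture_bounds: tuple[float, float] = CAPTURE_BOUNDS,
    extra_starts: Sequence[np.ndarray] = (),
    min_trials: int = 30,
) -> MixtureFit:
    """Fit one mixture model to the HP and LP condition RTs.

    The baseline curve is held fixed (it comes from :func:`fit_baseline` on
    no-distractor trials).  Capture probabilities are constrained to
    ``capture_bounds`` through a scaled logistic transform; curve skew and
    spread are optimized on the log scale.  ``n_starts`` seeded restarts of a
    bounded quasi-Newton search are run and the best optimum kept, so the fit
    is deterministic given (data, seed).
    """
    hp_rts = np.asarray(hp_rts, dtype=float)
    lp_rts = np.asarray(lp_rts, dtype=float)
    for name, arr in (("hp", hp_rts), ("lp", lp_rts)):
        if arr.size < min_trials:
            logger.warning("condition %s has only %d trials (< %d)", name, arr.size, min_trials)
        if arr.size < 5:
            raise ValueError(f"condition {name!r} has too few trials ({arr.size})")
    obj = _MixtureObjective(hp_rts, lp_rts, baseline, model_kind, objective, capture_bounds)
    starts = _mixture_starts(
        hp_rts, lp_rts, baseline, model_kind, n_starts, seed, capture_bounds
    ) + [np.asarray(s, dtype=float) for s in extra_starts]
    best_val, best_x, any_ok = np.inf, None, False
    since_improvement = 0
    for i, x0 in enumerate(starts):
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B",
            options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun < 1e11:
            any_ok = any_ok or res.success
            if res.fun < best_val - 1e-6 * max(abs(best_val), 1.0):
                best_val, best_x = float(res.fun), res.x
                since_improvement = 0
                continue
            if res.fun < best_val:
                best_val, best_x = float(res.fun), res.x
        since_improvement += 1
        # deterministic early stop: once several consecutive restarts land on
        # (or above) the incumbent optimum, further restarts are redundant
        if i >= 5 and since_improvement >= 4 and i < len(starts) - len(extra_starts):
            remaining = [np.asarray(s, dtype=float) for s in extra_starts]
            for xw in remaining:
                res = optimize.minimize(
                    obj, xw, method="L-BFGS-B",
                    options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8},
                )
                if np.isfinite(res.fun) and res.fun < best_val:
                    best_val, best_x = float(res.fun), res.x
                    any_ok = any_ok or res.success
            break
    if best_x is None:
        raise RuntimeError(
            f"all optimization starts failed for model {model_kind!r} "
            f"(n_hp={hp_rts.size}, n_lp={lp_rts.size})"
        )
    curve_hp, curve_lp, p_hp, p_lp = _unpack(best_x, model_kind, capture_bounds)
    k = _MODEL_NPARAMS[model_kind]
    loglik = obj.loglik(best_val)
    aic, bic = information_criteria(loglik, k, obj.n_obs)
    lo, hi = capture_bounds
    pinned = min(p_hp - lo, hi - p_hp, p_lp - lo, hi - p_lp) < 1e-3
    if pinned:
        logger.info("capture probability pinned at a bound for model %s", model_kind)
    return MixtureFit(
        model_kind=model_kind,
        baseline=baseline,
        capture_curve_hp=ExGaussParams(*curve_hp),
        capture_curve_lp=ExGaussParams(*curve_lp),
        p_capture_hp=float(p_hp),
        p_capture_lp=float(p_lp),
        n_params=k,
        objective=objective,
        objective_value=best_val,
        loglik=loglik,
        aic=aic,
        bic=bic,
        n_obs=obj.n_obs,
        converged=bool(any_ok),
        boundary_pinned=bool(pinned),
    )


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = 2k - 2 lnL;  BIC = k ln(n) - 2 lnL."""
    if n_obs < 2:
        raise ValueError("information criteria need n_obs >= 2")
    aic = 2.0 * n_params - 2.0 * loglik
    bic = n_params * math.log(n_obs) - 2.0 * loglik
    return aic, bic


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Three-way capture/disengagement/combined comparison on one dataset."""

    fits: dict[str, MixtureFit]
    winner_aic: str
    winner_bic: str
    baseline_median: float
    capture_median: float
    capture_cost: float  # median(capture curve of capture model) - median(baseline)

    @property
    def criteria(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.fits),
                "aic": [f.aic for f in self.fits.values()],
                "bic": [f.bic for f in self.fits.values()],
                "loglik": [f.loglik for f in self.fits.values()],
                "n_params": [f.n_params for f in self.fits.values()],
            }
        )

    def pairwise_deltas(self, criterion: str = "bic") -> dict[str, float]:
        vals = {m: getattr(f, criterion) for m, f in self.fits.items()}
        out = {}
        names = list(vals)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                out[f"{a}_minus_{b}"] = vals[a] - vals[b]
        return out

    def to_dict(self) -> dict:
        return {
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
            "winner_aic": self.winner_aic,
            "winner_bic": self.winner_bic,
            "baseline_median": self.baseline_median,
            "capture_median": self.capture_median,
            "capture_cost": self.capture_cost,
        }


def compare_models(
    hp_rts: Sequence[float],
    lp_rts: Sequence[float],
    baseline: ExGaussParams,
    objective: Literal["mle", "binned"] = "mle",
    n_starts: int = 16,
    seed: int = 0,
    capture_bounds: tuple[float, float] = CAPTURE_BOUNDS,
) -> ModelComparison:
    """Fit all three mixture models and rank them by AIC and BIC.

    Warm starts tie the nested fits together: disengagement is seeded from the
    capture optimum, combined from both restricted optima (so its likelihood
    can never fall below either), and disengagement is refined once more from
    the combined optimum projected back onto a shared capture probability.
    """

    def curve_theta(curve: ExGaussParams) -> list[float]:
        return [math.log(curve.K), curve.loc, math.log(curve.scale)]

    cap = fit_mixture(hp_rts, lp_rts, baseline, "capture", objective, n_starts, seed,
                      capture_bounds)
    warm_from_cap = np.array(
        curve_theta(cap.capture_curve_hp) * 2
        + [_raw_from_p(0.5 * (cap.p_capture_hp + cap.p_capture_lp), capture_bounds)]
    )
    dis = fit_mixture(hp_rts, lp_rts, baseline, "disengagement", objective, n_starts,
                      seed, capture_bounds, extra_starts=[warm_from_cap])
    warm_cap = np.array(
        curve_theta(cap.capture_curve_hp) * 2
        + [_raw_from_p(cap.p_capture_hp, capture_bounds),
           _raw_from_p(cap.p_capture_lp, capture_bounds)]
    )
    warm_dis = np.array(
        curve_theta(dis.capture_curve_hp) + curve_theta(dis.capture_curve_lp)
        + [_raw_from_p(dis.p_capture_hp, capture_bounds),
           _raw_from_p(dis.p_capture_lp, capture_bounds)]
    )
    comb = fit_mixture(
        hp_rts, lp_rts, baseline, "combined", objective, n_starts, seed,
        capture_bounds, extra_starts=[warm_cap, warm_dis],
    )
    # project the combined optimum back onto the disengagement constraint and
    # keep the refit if it improves the disengagement likelihood
    proj = np.array(
        curve_theta(comb.capture_curve_hp) + curve_theta(comb.capture_curve_lp)
        + [_raw_from_p(0.5 * (comb.p_capture_hp + comb.p_capture_lp), capture_bounds)]
    )
    dis_refined = fit_mixture(
        hp_rts, lp_rts, baseline, "disengagement", objective, 0, seed,
        capture_bounds, extra_starts=[proj, warm_from_cap],
    )
    if dis_refined.loglik > dis.loglik:
        dis = dis_refined
    fits = {"capture": cap, "disengagement": dis, "combined": comb}
    winner_aic = min(fits, key=lambda m: fits[m].aic)
    winner_bic = min(fits, key=lambda m: fits[m].bic)
    base_med = exgauss_median(baseline)
    cap_med = exgauss_median(cap.capture_curve_hp)
    return ModelComparison(
        fits=fits,
        winner_aic=winner_aic,
        winner_bic=winner_bic,
        baseline_median=base_med,
        capture_median=cap_med,
        capture_cost=cap_med - base_med,
    )


def per_participant_comparison(
    data: dict[str, tuple[Sequence[float], Sequence[float], Sequence[float]]],
    objective: Literal["mle", "binned"] = "mle",
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Fit the three models separately to each participant.

    ``data`` maps participant id to (no_distractor_rts, hp_rts, lp_rts); each
    participant's own no-distractor trials provide their baseline.  Returns a
    long table of per-participant criteria and a dict of group statistics: a
    Greenhouse-Geisser-corrected repeated-measures ANOVA over models and
    matched pairwise Wilcoxon tests with rank-biserial effect sizes, for AIC
    and BIC separately.  Participants whose fits fail are excluded and logged.
    """
    import pingouin as pg

    rows, failed = [], []
    for pid, (nd, hp, lp) in data.items():
        try:
            base = fit_baseline(nd, n_starts=n_starts, seed=seed).params
            comp = compare_models(hp, lp, base, objective, n_starts, seed)
        except (ValueError, RuntimeError) as err:
            logger.warning("participant %s excluded from model comparison: %s", pid, err)
            failed.append(pid)
            continue
        for model, fit in comp.fits.items():
            rows.append(
                {
                    "participant": pid,
                    "model": model,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "p_capture_hp": fit.p_capture_hp,
                    "p_capture_lp": fit.p_capture_lp,
                    "winner_bic": comp.winner_bic,
                }
            )
    table = pd.DataFrame(rows)
    group: dict = {"excluded": failed}
    if table["participant"].nunique() >= 3:
        for crit in ("aic", "bic"):
            aov = pg.rm_anova(
                data=table, dv=crit, within="model", subject="participant",
                correction=True,
            )
            row = aov.iloc[0]
            pcol = "p_GG_corr" if "p_GG_corr" in aov.columns and np.isfinite(
                row.get("p_GG_corr", np.nan)
            ) else "p_unc"
            pairwise = {}
            wide = table.pivot(index="participant", columns="model", values=crit)
            for a, b in (("capture", "disengagement"), ("capture", "combined"),
                         ("combined", "disengagement")):
                w = pg.wilcoxon(wide[a], wide[b])
                pairwise[f"{a}_vs_{b}"] = {
                    "W": float(w["W_val"].iloc[0]),
                    "p": float(w["p_val"].iloc[0]),
                    "rank_biserial": float(w["RBC"].iloc[0]),
                }
            group[crit] = {
                "F": float(row["F"]),
                "p": float(row[pcol]),
                "ng2": float(row["ng2"]) if "ng2" in aov.columns else None,
                "mean_by_model": wide.mean().to_dict(),
                "pairwise": pairwise,
            }
    return table, group
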