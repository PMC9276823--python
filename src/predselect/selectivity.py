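"""Likelihood framework for size- vs growth-selective predation.

The original population (before net sampling and predation) is described by
a linear mean age-SL law with Gaussian residuals and an empirical age
distribution. It is inferred from the netted sample by weighted least
squares, each fish weighted by the reciprocal of its net-retention
probability so that length classes the net under-samples count more.

Predation multiplies the population density by a selection weight w:

    f_c(a, l) = f0(a) * phi(l; beta0 + beta1*a, sigma) * w(a, l) / Z

with w = 1 (random predation), a decreasing logistic in l (size selection),
or a decreasing logistic in the residual l - (beta0 + beta1*a) (growth
selection). Population parameters are plug-in (held fixed), so the random
model has k = 0 free parameters and each selective model k = 2 (half-point
and width); AIC = 2k - 2 lnL. The selective models nest the random model in
the flat-weight limit, and each is tested against it with a parametric
bootstrap likelihood-ratio test: resamples are drawn from the null density
f0(a) * phi(l), the alternative refitted on each, and
p = (1 + #{LR_b >= LR_obs}) / (B + 1).

The normaliser Z is a Gauss-Legendre integral over SL (mean +/- 8 sigma per
supported age); for growth selection the weight depends only on the
residual, so Z collapses to a single integral shared by all ages. All
likelihood arithmetic is done in the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import log_expit
from scipy.stats import norm

from .synthdata import RetentionCurve

__all__ = [
    "PopulationModel",
    "SelectionFit",
    "ModelComparison",
    "fit_population",
    "loglik",
    "fit_selection",
    "bootstrap_lrt",
    "compare_models",
    "significance_stars",
    "aic",
]

KINDS = ("random", "size", "growth")

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)
_SL_HALF_RANGE_SIGMA = 8.0  # integrate SL over mean +/- 8 sigma
_MIN_LOG_WIDTH = np.log(0.05)  # mm; keeps the quadrature resolvable


@dataclass(frozen=True)
class PopulationModel:
    """Inferred original-population age-SL law.

    ``ages``/``age_weights`` form the (discrete) age distribution f0;
    weights sum to one.
    """

    beta0: float
    beta1: float
    sigma: float
    ages: np.ndarray
    age_weights: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        w = np.asarray(self.age_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError("age weights must sum to 1")

    def mean_sl(self, ages) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(ages, dtype=float)

    def log_f0(self, ages) -> np.ndarray:
        """Log age-density at the given (integer) ages; -inf off support."""
        a = np.asarray(ages)
        idx = np.searchsorted(self.ages, a)
        idx = np.clip(idx, 0, len(self.ages) - 1)
        ok = self.ages[idx] == a
        out = np.full(a.shape, -np.inf, dtype=float)
        out[ok] = np.log(self.age_weights[idx[ok]])
        return out

    def covering(self, ages) -> "PopulationModel":
        """Extend the age support to cover ``ages`` with floor weights.

        Needed when consumed fish are slightly younger/older than any
        netted fish; the floor is 1 % of total mass spread over the grid.
        """
        a = np.asarray(ages)
        lo = min(self.ages.min(), int(a.min()))
        hi = max(self.ages.max(), int(a.max()))
        if lo >= self.ages.min() and hi <= self.ages.max():
            return self
        grid = np.arange(lo, hi + 1)
        w = np.zeros(grid.size)
        w[np.searchsorted(grid, self.ages)] = self.age_weights
        w += 0.01 / grid.size
        return replace(self, ages=grid, age_weights=w / w.sum())


@dataclass(frozen=True)
class SelectionFit:
    """One predation model fitted to a consumed sample."""

    kind: str
    theta: tuple[float, float] | None  # (half-point mm, width mm)
    loglik: float
    k: int  # free selection parameters: 0 (random) or 2
    aic: float
    boot_p: float | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.boot_p)


@dataclass(frozen=True)
class ModelComparison:
    """Three-model comparison at one spatiotemporal scope."""

    scope: str
    fits: dict
    selected: str
    excluded_sites: tuple = ()


def significance_stars(p: float | None) -> str:
    if p is None:
        return ""
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    return 2.0 * k - 2.0 * loglik


def fit_population(
    netted: pd.DataFrame,
    retention: RetentionCurve | None = None,
    age_grid_pad: int = 2,
) -> PopulationModel:
    """Infer the original population from a netted sample.

    Weighted least squares of SL on age with weights 1 / retention(SL);
    ``retention=None`` (or a curve that is ~1 everywhere) reduces to OLS.
    sigma is the weighted residual SD (denominator n - 2); the age
    distribution is the retention-weighted histogram of netted ages on an
    integer grid padded by ``age_grid_pad`` days, with a small floor so
    nearby unobserved ages keep finite density.
    """
    if len(netted) < 5:
        raise ValueError("need at least 5 netted records")
    ages = netted["age"].to_numpy(dtype=float)
    sl = netted["sl"].to_numpy(dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("all netted fish share one age: design is singular")
    w = np.ones_like(sl) if retention is None else 1.0 / np.maximum(
        retention(sl), 1e-12
    )
    fit = sm.WLS(sl, sm.add_constant(ages), weights=w).fit()
    beta0, beta1 = fit.params
    resid = sl - (beta0 + beta1 * ages)
    n = len(sl)
    sigma = float(np.sqrt((w * resid**2).sum() / w.sum() * n / (n - 2)))

    grid = np.arange(int(ages.min()) - age_grid_pad, int(ages.max()) + age_grid_pad + 1)
    counts = np.zeros(grid.size)
    np.add.at(counts, np.searchsorted(grid, np.round(ages).astype(int)), w)
    counts += counts.sum() / (100.0 * grid.size)
    return PopulationModel(
        beta0=float(beta0),
        beta1=float(beta1),
        sigma=sigma,
        ages=grid,
        age_weights=counts / counts.sum(),
    )


# -- likelihood machinery ----------------------------------------------------


def _log_weight(x: np.ndarray, half: float, width: float) -> np.ndarray:
    """Log of the decreasing logistic selection weight."""
    return log_expit(-(x - half) / width)


class _Likelihood:
    """Precomputed consumed-sample context for fast repeated evaluation."""

    def __init__(self, pop: PopulationModel, consumed):
        ages = np.asarray(consumed["age"], dtype=float)
        if ages.size == 0:
            raise ValueError("consumed sample is empty")
        self.pop = pop = pop.covering(ages)
        self.ages = ages
        self.sl = np.asarray(consumed["sl"], dtype=float)
        self.mu = pop.mean_sl(self.ages)
        self.resid = self.sl - self.mu
        self.n = len(self.sl)
        lf0 = pop.log_f0(np.round(self.ages).astype(int))
        lphi = norm.logpdf(self.sl, self.mu, pop.sigma)
        self.base = float(np.sum(lf0 + lphi))  # random-model log-likelihood
        # quadrature nodes: per supported age for size, residual-scale for growth
        s = _SL_HALF_RANGE_SIGMA * pop.sigma
        self.gl_x = _GL_NODES * s  # offsets about the age mean
        self.gl_w = _GL_WEIGHTS * s
        self.phi_nodes = norm.pdf(self.gl_x, 0.0, pop.sigma)  # shared across ages
        self.support_mu = pop.mean_sl(pop.ages)  # (n_ages,)
        self.support_w = pop.age_weights
        # precombined quadrature mass phi(node) * GL weight, and concatenated
        # evaluation points so one log_expit call serves data + quadrature
        self._phi_mass = self.phi_nodes * self.gl_w  # growth: Z = mass . w(nodes)
        self._growth_x = np.concatenate([self.resid, self.gl_x])
        size_nodes = (self.support_mu[:, None] + self.gl_x[None, :]).ravel()
        self._size_x = np.concatenate([self.sl, size_nodes])
        # age-weighted quadrature mass for the size normaliser, flattened
        self._size_mass = (self.support_w[:, None] * self._phi_mass[None, :]).ravel()

    def __call__(self, kind: str, theta=None) -> float:
        if kind == "random":
            return self.base
        half, width = theta
        if kind == "size":
            lw = _log_weight(self._size_x, half, width)
            z = float(self._size_mass @ np.exp(lw[self.n :]))
        elif kind == "growth":
            lw = _log_weight(self._growth_x, half, width)
            z = float(self._phi_mass @ np.exp(lw[self.n :]))
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        if z <= 0.0:
            return -np.inf
        val = self.base + float(lw[: self.n].sum()) - self.n * np.log(z)
        # degenerate theta (weight vanishing everywhere) gives -inf - (-inf)
        return val if np.isfinite(val) else -np.inf


def loglik(
    kind: str,
    theta,
    pop: PopulationModel,
    consumed: pd.DataFrame,
) -> float:
    """Log-likelihood (nats) of a predation model on a consumed sample."""
    return _Likelihood(pop, consumed)(kind, theta)


def _theta_grid(like: _Likelihood, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Coarse (half, width) grid spanning the plausible selection range."""
    sigma = like.pop.sigma
    if kind == "size":
        lo = like.support_mu.min() - 3.0 * sigma
        hi = like.support_mu.max() + 1.0 * sigma
    else:
        lo, hi = -4.0 * sigma, 2.0 * sigma
    halves = np.linspace(lo, hi, 24)
    widths = sigma * np.geomspace(0.15, 6.0, 12)
    H, W = np.meshgrid(halves, widths)
    return H.ravel(), W.ravel()


def _log_z_grid(like: _Likelihood, kind: str, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Normaliser log Z at every grid point (depends on pop only, not data)."""
    if kind == "size":
        nodes, mass = like._size_x[like.n :], like._size_mass
    else:
        nodes, mass = like.gl_x, like._phi_mass
    wvals = np.exp(_log_weight(nodes[:, None], H[None, :], W[None, :]))
    return np.log(mass @ wvals)


def _starts(like: _Likelihood, kind: str, n_starts: int) -> list[tuple[float, float]]:
    """Dispersed (half, width) starting points from data quantiles."""
    x = like.sl if kind == "size" else like.resid
    sigma = like.pop.sigma
    halves = np.quantile(x, np.linspace(0.1, 0.9, max(n_starts, 2)))
    widths = [0.5 * sigma, 2.0 * sigma]
    starts = [(h, widths[i % 2]) for i, h in enumerate(halves)]
    if n_starts > len(halves):
        starts += [(float(np.median(x)), w) for w in widths]
    return starts[:n_starts] if n_starts >= 2 else starts[:2]


def fit_selection(
    kind: str,
    pop: PopulationModel,
    consumed: pd.DataFrame,
    n_starts: int = 5,
    options: dict | None = None,
    starts: list[tuple[float, float]] | None = None,
    _like: "_Likelihood | None" = None,
) -> SelectionFit:
    """Maximum-likelihood fit of one predation model.

    Selective models are optimised over (half-point, log width) by
    Nelder-Mead from dispersed data-quantile starts; the width is bounded
    below at 0.05 mm so the SL quadrature stays resolvable. Deterministic
    given the data and start grid. ``options`` overrides the Nelder-Mead
    convergence settings.
    """
    like = _like or _Likelihood(pop, consumed)
    if kind == "random":
        ll = like("random")
        return SelectionFit("random", None, ll, 0, aic(ll, 0))
    if like.n < 5:
        raise ValueError("need at least 5 consumed records for a 2-parameter fit")

    def nll(u):
        half, lw = u
        return -like(kind, (half, np.exp(lw if lw > _MIN_LOG_WIDTH else _MIN_LOG_WIDTH)))

    opts = {"xatol": 1e-4, "fatol": 1e-7, "maxiter": 600}
    if options:
        opts.update(options)
    best = None
    for h0, w0 in starts or _starts(like, kind, n_starts):
        res = minimize(
            nll,
            x0=np.array([h0, np.log(w0)]),
            method="Nelder-Mead",
            options=opts,
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"{kind}-model optimisation failed from all starts")
    half, lw = best.x
    theta = (float(half), float(np.exp(max(lw, _MIN_LOG_WIDTH))))
    ll = -float(best.fun)
    return SelectionFit(kind, theta, ll, 2, aic(ll, 2))


def _simulate_null(pop: PopulationModel, n: int, rng: np.random.Generator) -> dict:
    """Parametric resample from the null (random-predation) density."""
    ages = rng.choice(pop.ages, size=n, p=pop.age_weights)
    sl = pop.mean_sl(ages) + rng.normal(0.0, pop.sigma, n)
    return {"age": ages, "sl": sl}


def bootstrap_lrt(
    pop: PopulationModel,
    consumed: pd.DataFrame,
    alt_kind: str,
    B: int = 2000,
    seed: int = 0,
    alt_fit: SelectionFit | None = None,
) -> float:
    """Parametric bootstrap likelihood-ratio test against random predation.

    LR = 2 (lnL_alt - lnL_random); B resamples of the observed sample size
    are drawn from the null density and the alternative refitted on each.
    p = (1 + #{LR_b >= LR_obs}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if alt_kind not in ("size", "growth"):
        raise ValueError("alternative must be 'size' or 'growth'")
    like = _Likelihood(pop, consumed)
    if alt_fit is None:
        alt_fit = fit_selection(alt_kind, pop, consumed, _like=like)
    lr_obs = max(2.0 * (alt_fit.loglik - like.base), 0.0)

    rng = np.random.default_rng(seed)
    n = like.n
    n_ge = 0
    n_failed = 0
    # each resample's refit starts from the argmax of a precomputed theta
    # grid (Z depends only on the population, so the grid normaliser is
    # shared), then a short local polish; the LR only enters through its
    # rank against LR_obs so loose convergence suffices
    H, W = _theta_grid(like, alt_kind)
    log_z = _log_z_grid(like, alt_kind, H, W)
    for _ in range(B):
        boot = _simulate_null(pop, n, rng)
        blike = _Likelihood(pop, boot)
        x = blike.sl if alt_kind == "size" else blike.resid
        score = _log_weight(x[:, None], H[None, :], W[None, :]).sum(axis=0) - n * log_z
        j = int(np.argmax(score))
        h0, lw0 = float(H[j]), float(np.log(W[j]))
        loose = {
            "xatol": 2e-2,
            "fatol": 2e-4,
            "maxiter": 80,
            # small simplex: the grid argmax is already near the optimum
            "initial_simplex": [[h0, lw0], [h0 + 0.4, lw0], [h0, lw0 + 0.3]],
        }
        try:
            bfit = fit_selection(
                alt_kind, pop, boot, options=loose,
                starts=[(H[j], W[j])], _like=blike,
            )
        except RuntimeError:
            n_failed += 1
            continue
        lr_b = max(2.0 * (bfit.loglik - blike.base), 0.0, 2.0 * float(score[j]))
        if lr_b >= lr_obs:
            n_ge += 1
    n_used = B - n_failed
    if n_failed > 0.01 * B:
        import warnings

        warnings.warn(f"{n_failed} of {B} bootstrap refits failed", stacklevel=2)
    return (1 + n_ge) / (n_used + 1)


def compare_models(
    pop: PopulationModel,
    consumed: pd.DataFrame,
    scope: str = "site",
    boot_B: int = 2000,
    seed: int = 0,
    excluded_sites: tuple = (),
) -> ModelComparison:
    """Fit all three predation models, bootstrap-test the selective ones and
    select by minimum AIC.

    ``boot_B=0`` skips the bootstrap (boot_p left None). AIC ties break
    toward fewer parameters, then lexicographic model name. Sites flagged
    by the rejection screen must be excluded upstream and are recorded in
    ``excluded_sites``.
    """
    like = _Likelihood(pop, consumed)
    fits = {}
    for kind in KINDS:
        fits[kind] = fit_selection(kind, pop, consumed, _like=like)
    if boot_B:
        ss = np.random.SeedSequence(seed).spawn(2)
        for i, kind in enumerate(("size", "growth")):
            p = bootstrap_lrt(
                pop,
                consumed,
                kind,
                B=boot_B,
                seed=int(ss[i].generate_state(1)[0] % (2**31)),
                alt_fit=fits[kind],
            )
            fits[kind] = replace(fits[kind], boot_p=p)
    selected = min(fits.values(), key=lambda f: (f.aic, f.k, f.kind)).kind
    return ModelComparison(
        scope=scope, fits=fits, selected=selected, excluded_sites=tuple(excluded_sites)
    )
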