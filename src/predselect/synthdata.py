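"""Synthetic populations, net samples, consumed samples and otoliths.

Everything downstream of field sampling is testable against a known ground
truth: a juvenile fish population with a linear mean age-SL relation and
Gaussian residuals, a logistic net-retention curve, multiplicative predation
selection weights (uniform, decreasing in SL, or decreasing in the
age-standardised SL residual), otolith radii proportional to SL with daily
increments starting at 2 dph, and cubic SL-weight allometry.

Lengths are mm, masses g, otolith radii µm, ages integer days post-hatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PopulationParams",
    "RetentionCurve",
    "SelectionSpec",
    "OtolithGrowthParams",
    "generate_population",
    "sample_net_catch",
    "sample_consumed",
    "generate_otoliths",
]

#: default allometric coefficients for W = p * SL**q (g, mm)
DEFAULT_ALLOMETRY = (1.0e-5, 3.0)


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the original (pre-predation, pre-sampling) population.

    Mean standard length at age ``a`` is ``beta0 + beta1 * a`` with
    homoscedastic Gaussian residual SD ``sigma``. Ages are uniform on
    ``age_range`` unless ``age_cohorts`` supplies a Gaussian mixture
    (means, sds, mixing weights) emulating multi-modal hatch cohorts.
    """

    n_individuals: int = 10_000
    age_range: tuple[float, float] = (25.0, 60.0)
    beta0: float = 1.2
    beta1: float = 0.9
    sigma: float = 3.0
    seed: int = 0
    allometry: tuple[float, float] = DEFAULT_ALLOMETRY
    age_cohorts: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        vals = [self.beta0, self.beta1, self.sigma, *self.age_range]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("population parameters must be finite")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.beta1 <= 0:
            raise ValueError("growth slope beta1 must be positive")
        if self.sigma < 0:
            raise ValueError("residual SD sigma must be non-negative")
        if not self.age_range[1] > self.age_range[0]:
            raise ValueError("age_range must be non-degenerate")


@dataclass(frozen=True)
class RetentionCurve:
    """Logistic net retention: P(caught | SL=l) = expit((l - l50) / delta)."""

    l50: float = 25.0
    delta: float = 3.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("logistic width delta must be positive")

    def __call__(self, sl: np.ndarray | float) -> np.ndarray | float:
        return expit((np.asarray(sl, dtype=float) - self.l50) / self.delta)


@dataclass(frozen=True)
class SelectionSpec:
    """Predation selection weights.

    kind='random' gives uniform weights; kind='size' a decreasing logistic
    in SL with half-selection point ``l50_or_e50``; kind='growth' the same
    logistic in the SL residual about the population mean line (slow growers
    preferred). ``width`` is the logistic scale in mm.
    """

    kind: str = "random"
    l50_or_e50: float = 0.0
    width: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("random", "size", "growth"):
            raise ValueError(f"unknown selection kind {self.kind!r}")
        if self.width <= 0:
            raise ValueError("selection width must be positive")


@dataclass(frozen=True)
class OtolithGrowthParams:
    """Otolith radius grows linearly with SL from a fixed hatch anchor.

    The first increment forms at ``hatch_age`` (2 dph) when the fish is
    ``hatch_sl`` (~3 mm) long and the otolith radius is ``hatch_radius``.
    """

    hatch_radius: float = 10.0
    radius_per_mm: float = 2.5
    hatch_sl: float = 3.0
    hatch_age: int = 2

    def __post_init__(self) -> None:
        for v in (self.hatch_radius, self.radius_per_mm, self.hatch_sl, self.hatch_age):
            if v <= 0:
                raise ValueError("otolith growth parameters must be positive")


def _draw_ages(params: PopulationParams, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.age_range
    if params.age_cohorts is None:
        ages = rng.uniform(lo, hi, params.n_individuals)
    else:
        means, sds, ws = map(np.asarray, zip(*params.age_cohorts))
        ws = ws / ws.sum()
        comp = rng.choice(len(ws), size=params.n_individuals, p=ws)
        ages = rng.normal(means[comp], sds[comp])
        ages = np.clip(ages, lo, hi)
    return np.round(ages).astype(int)


def generate_population(params: PopulationParams) -> pd.DataFrame:
    """Simulate the original population as a table (id, age, sl, weight)."""
    rng = np.random.default_rng(params.seed)
    ages = _draw_ages(params, rng)
    sl = params.beta0 + params.beta1 * ages + rng.normal(0.0, params.sigma, ages.size)
    sl = np.maximum(sl, 0.5)  # degenerate negative lengths are biologically void
    p, q = params.allometry
    return pd.DataFrame(
        {
            "id": np.arange(ages.size),
            "age": ages,
            "sl": sl,
            "weight": p * sl**q,
        }
    )


def sample_net_catch(
    population: pd.DataFrame,
    retention: RetentionCurve,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a net sample: retain each fish with probability retention(SL),
    then take ``n`` of the retained without replacement.

    Returns fewer than ``n`` rows (with a warning) when the net retains
    fewer fish than requested.
    """
    if n > len(population):
        raise ValueError("cannot draw more fish than the population holds")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(population)) < retention(population["sl"].to_numpy())
    retained = population.loc[keep]
    if len(retained) < n:
        warnings.warn(
            f"net retained only {len(retained)} of requested {n} fish",
            stacklevel=2,
        )
        out = retained
    else:
        idx = rng.choice(len(retained), size=n, replace=False)
        out = retained.iloc[np.sort(idx)]
    out = out.copy()
    out["source"] = "netted"
    return out.reset_index(drop=True)


def selection_weights(
    population: pd.DataFrame, spec: SelectionSpec, params: PopulationParams
) -> np.ndarray:
    """Unnormalised predation weights for each individual in the population."""
    if spec.kind == "random":
        return np.ones(len(population))
    sl = population["sl"].to_numpy()
    if spec.kind == "size":
        x = sl
    else:  # growth: residual about the population mean line
        x = sl - (params.beta0 + params.beta1 * population["age"].to_numpy())
    return expit(-(x - spec.l50_or_e50) / spec.width)


def sample_consumed(
    population: pd.DataFrame,
    spec: SelectionSpec,
    n: int,
    seed: int = 0,
    params: PopulationParams | None = None,
) -> pd.DataFrame:
    """Draw ``n`` consumed fish with selection-weighted sampling.

    Growth selection needs the population mean line, taken from ``params``
    (defaults are used when not supplied, which only matches a population
    generated under default parameters).
    """
    if n < 1:
        raise ValueError("must consume at least one fish")
    params = params or PopulationParams()
    w = selection_weights(population, spec, params)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("selection weights are all zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(population), size=n, replace=False, p=w / tot)
    out = population.iloc[np.sort(idx)].copy()
    out["source"] = "consumed"
    return out.reset_index(drop=True)


def generate_otoliths(
    fish: pd.DataFrame,
    og: OtolithGrowthParams = OtolithGrowthParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit left+right otolith reads for each fish.

    Increment count is ``age - hatch_age``; capture radius is linear in SL
    with additive Gaussian measurement noise (µm); increment widths are
    equal (the daily-growth profile of an individual is not resolved here).
    Left and right radii differ only by independent noise. Negative or
    sub-hatch radii are clipped at the hatch radius.
    """
    if (fish["age"] < og.hatch_age).any():
        raise ValueError("fish younger than hatch age have no otolith record")
    rng = np.random.default_rng(seed)
    rows = []
    for _, f in fish.iterrows():
        n_inc = int(f["age"]) - og.hatch_age
        base = og.hatch_radius + og.radius_per_mm * (f["sl"] - og.hatch_sl)
        for side in ("left", "right"):
            radius = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            radius = max(radius, og.hatch_radius)
            width = (radius - og.hatch_radius) / n_inc if n_inc > 0 else 0.0
            rows.append(
                {
                    "fish_id": f["id"],
                    "side": side,
                    "radius_um": radius,
                    "n_increments": n_inc,
                    "widths": ";".join(f"{width:.6f}" for _ in range(n_inc)),
                }
            )
    return pd.DataFrame(rows)
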