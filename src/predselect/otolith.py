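"""Ageing, biological-intercept back-calculation and otolith pairing.

Daily increments begin at 2 days post-hatch, so age = increment count + 2.
Back-calculation anchors a per-fish linear otolith-size/body-size relation
at the hatch point (hatch_sl, hatch_radius) and the capture point
(sl_capture, radius_capture); length at any interior age follows by linear
interpolation on cumulative increment widths.

Consumed juveniles have no measured length, so their capture SL is first
reconstructed from the capture radius through the linear OR-SL calibration,
and mass through the allometric SL-W relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "OtolithRead",
    "Calibration",
    "estimate_age",
    "back_calculate_sl",
    "reconstruct_sl_from_radius",
    "sl_to_weight",
    "weight_to_sl",
    "pair_otoliths",
    "fit_calibration",
]

#: left/right estimated-SL difference below which two otoliths in the same
#: stomach are treated as one fish
PAIRING_SL_TOLERANCE_MM = 2.0

HATCH_AGE_OFFSET = 2  # first increment deposits at 2 dph


@dataclass(frozen=True)
class OtolithRead:
    """One sagittal otolith: side, capture radius (µm) and increment series."""

    fish_or_squid_id: object
    side: str
    radius_capture: float
    increment_widths: tuple[float, ...] = ()
    n_increments: int | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        n = self.n_increments
        if n is None:
            object.__setattr__(self, "n_increments", len(self.increment_widths))
        elif self.increment_widths and n != len(self.increment_widths):
            raise ValueError("n_increments disagrees with the width series")
        if self.increment_widths:
            cum = sum(self.increment_widths)
            if cum > self.radius_capture * 1.01:
                raise ValueError(
                    "cumulative increment widths exceed the capture radius"
                )


@dataclass(frozen=True)
class Calibration:
    """Linear OR->SL map, allometric SL<->W map and the hatch anchor.

    SL = c0 + c1 * radius (mm, µm); W = p * SL**q (g, mm). Defaults are
    consistent with the synthetic otolith-growth defaults (radius grows
    2.5 µm per mm of SL from 10 µm at 3 mm / 2 dph).
    """

    or_sl: tuple[float, float] = (3.0 - 10.0 / 2.5, 1.0 / 2.5)
    allometry: tuple[float, float] = (1.0e-5, 3.0)
    hatch: tuple[float, float, float] = (3.0, 2.0, 10.0)  # (sl mm, age d, radius µm)

    def __post_init__(self) -> None:
        if self.or_sl[1] <= 0:
            raise ValueError("OR-SL slope c1 must be positive")
        if self.allometry[0] <= 0 or self.allometry[1] <= 0:
            raise ValueError("allometric coefficients must be positive")

    @property
    def hatch_sl(self) -> float:
        return self.hatch[0]

    @property
    def hatch_age(self) -> float:
        return self.hatch[1]

    @property
    def hatch_radius(self) -> float:
        return self.hatch[2]


def estimate_age(n_increments: int) -> int:
    """Age in days: increment count plus the 2-day pre-deposition period."""
    if n_increments < 0:
        raise ValueError("increment count cannot be negative")
    return int(n_increments) + HATCH_AGE_OFFSET


def back_calculate_sl(
    read: OtolithRead, sl_capture: float, calib: Calibration = Calibration()
) -> pd.DataFrame:
    """Biological-intercept back-calculation of the SL-at-age series.

    Returns a frame with columns (age, radius_um, sl) from hatch age to
    capture age inclusive. With no width series, equal widths are assumed.
    """
    r_hatch, sl_hatch = calib.hatch_radius, calib.hatch_sl
    if read.radius_capture <= r_hatch:
        raise ValueError("capture radius does not exceed the hatch radius")
    if sl_capture <= sl_hatch:
        raise ValueError("capture SL does not exceed the hatch SL")
    n = read.n_increments
    if read.increment_widths:
        widths = np.asarray(read.increment_widths, dtype=float)
    else:
        widths = np.full(n, (read.radius_capture - r_hatch) / n) if n else np.empty(0)
    radii = r_hatch + np.concatenate([[0.0], np.cumsum(widths)])
    # rescale so the series endpoint meets the measured capture radius exactly
    if n and radii[-1] != read.radius_capture:
        radii = r_hatch + (radii - r_hatch) * (
            (read.radius_capture - r_hatch) / (radii[-1] - r_hatch)
        )
    ages = calib.hatch_age + np.arange(n + 1)
    sl = sl_hatch + (radii - r_hatch) * (
        (sl_capture - sl_hatch) / (read.radius_capture - r_hatch)
    )
    return pd.DataFrame({"age": ages.astype(int), "radius_um": radii, "sl": sl})


def reconstruct_sl_from_radius(radius: float, calib: Calibration = Calibration()) -> float:
    """Capture SL from capture radius through the linear OR-SL calibration."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    c0, c1 = calib.or_sl
    sl = c0 + c1 * radius
    if sl <= 0:
        raise ValueError(
            f"reconstructed SL {sl:.3g} mm is non-positive: calibration mismatch"
        )
    return sl


def sl_to_weight(sl, calib: Calibration = Calibration()):
    """Wet weight (g) from SL (mm): W = p * SL**q."""
    p, q = calib.allometry
    return p * np.asarray(sl, dtype=float) ** q


def weight_to_sl(weight, calib: Calibration = Calibration()):
    """Inverse allometry: SL = (W / p) ** (1/q)."""
    w = np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight must be positive")
    p, q = calib.allometry
    return (w / p) ** (1.0 / q)


def fit_calibration(
    reference: pd.DataFrame, hatch: tuple[float, float, float] = (3.0, 2.0, 10.0)
) -> Calibration:
    """Fit (c0, c1) by OLS of SL on radius and (p, q) by log-log OLS of W on SL
    from a reference table with columns radius_um, sl, weight."""
    c1, c0 = np.polyfit(reference["radius_um"], reference["sl"], 1)
    q, logp = np.polyfit(np.log(reference["sl"]), np.log(reference["weight"]), 1)
    return Calibration(or_sl=(c0, c1), allometry=(float(np.exp(logp)), q), hatch=hatch)


def pair_otoliths(
    reads: list[OtolithRead], calib: Calibration = Calibration()
) -> list[dict]:
    """Group the otoliths found in one stomach into individual fish.

    A left and a right otolith whose reconstructed SLs differ by less than
    2 mm may belong to the same fish; among all feasible left-right
    matchings the one minimising total |ΔSL| is chosen (optimal assignment),
    so the result does not depend on input order. Unmatched reads become
    singleton individuals. The left-side otolith supplies the individual's
    SL whenever present.

    Returns one dict per individual with keys 'reads' and 'sl'.
    """
    lefts = [r for r in reads if r.side == "left"]
    rights = [r for r in reads if r.side == "right"]
    sl_of = {id(r): reconstruct_sl_from_radius(r.radius_capture, calib) for r in reads}

    individuals: list[dict] = []
    matched_r: set[int] = set()
    if lefts and rights:
        big = 1e9
        cost = np.full((len(lefts), len(rights)), big)
        for i, lf in enumerate(lefts):
            for j, rt in enumerate(rights):
                d = abs(sl_of[id(lf)] - sl_of[id(rt)])
                if d < PAIRING_SL_TOLERANCE_MM:
                    cost[i, j] = d
        ri, ci = linear_sum_assignment(cost)
        matched_l = set()
        for i, j in zip(ri, ci):
            if cost[i, j] < big:
                individuals.append(
                    {"reads": [lefts[i], rights[j]], "sl": sl_of[id(lefts[i])]}
                )
                matched_l.add(i)
                matched_r.add(j)
        lefts = [lf for i, lf in enumerate(lefts) if i not in matched_l]
    for lf in lefts:
        individuals.append({"reads": [lf], "sl": sl_of[id(lf)]})
    for j, rt in enumerate(rights):
        if j not in matched_r:
            individuals.append({"reads": [rt], "sl": sl_of[id(rt)]})
    return individuals


def read_otolith_csv(path) -> list[OtolithRead]:
    """Load otolith reads from a CSV with columns
    id, host_id, side, radius_um, n_increments, widths (semicolon list)."""
    df = pd.read_csv(path)
    reads = []
    for _, row in df.iterrows():
        widths = ()
        if isinstance(row.get("widths"), str) and row["widths"]:
            widths = tuple(float(w) for w in row["widths"].split(";"))
        reads.append(
            OtolithRead(
                fish_or_squid_id=row.get("host_id", row.get("id")),
                side=row["side"],
                radius_capture=float(row["radius_um"]),
                increment_widths=widths,
                n_increments=int(row["n_increments"]),
            )
        )
    return reads
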