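"""Head-rejection screening of study sites.

Squids often reject the head of prey fish that are large relative to their
own body mass; for this predator-prey pair rejection is assumed below a
predator-prey mass ratio of 13.2. A site's rejection-threshold SL is the
mean, over its squid, of the prey length whose mass is 1/13.2 of the squid
mass. Fish longer than the threshold are "unpalatable". If rejection (with
probability 0.6-1 per encounter) operated on random predation over a
population containing alpha % unpalatable fish, the unpalatable share of
stomach contents would fall in [0, U(alpha)] with

    U(alpha) = 0.4 * alpha * 100 / (100 - 0.6 * alpha)   (%).

A site is flagged (and excluded from selectivity fitting) when the netted
unpalatable share alpha_n exceeds 5 % while the consumed share alpha_c lies
below U(alpha_n) - i.e. the stomach deficit of large fish is consistent
with rejection rather than with selective predation alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .otolith import Calibration, weight_to_sl

__all__ = [
    "RejectionScreen",
    "REJECTION_PPMR",
    "threshold_sl",
    "expected_rejection_bound",
    "screen_site",
]

REJECTION_PPMR = 13.2  # prey heavier than predator_mass / 13.2 may be rejected
ALPHA_N_TRIGGER = 5.0  # % netted unpalatable share below which screening is moot


@dataclass(frozen=True)
class RejectionScreen:
    """Screening outcome for one site."""

    site: object
    threshold_sl: float  # mm
    alpha_n: float  # % unpalatable among netted
    alpha_c: float  # % unpalatable among consumed
    expected_upper: float  # U(alpha_n), %
    flagged: bool


def threshold_sl(squid_weights, calib: Calibration = Calibration()) -> float:
    """Site rejection-threshold SL: mean over squid of SL(weight / 13.2)."""
    w = np.asarray(squid_weights, dtype=float)
    if w.size == 0:
        raise ValueError("need at least one squid weight")
    if np.any(w <= 0):
        raise ValueError("squid weights must be positive")
    return float(np.mean(weight_to_sl(w / REJECTION_PPMR, calib)))


def expected_rejection_bound(alpha: float) -> float:
    """Upper bound U(alpha) of the unpalatable share expected in stomachs
    under 60-100 % head rejection, in %."""
    if not 0 <= alpha <= 100:
        raise ValueError("alpha must be a percentage in [0, 100]")
    return 0.4 * alpha * 100.0 / (100.0 - 0.6 * alpha)


def screen_site(
    netted_sl,
    consumed_sl,
    threshold: float,
    site: object = None,
) -> RejectionScreen:
    """Evaluate the head-rejection screen for one site.

    alpha uses the strict comparison SL > threshold. An empty consumed set
    yields alpha_c = 0 and the screen is still evaluated.
    """
    netted = np.asarray(netted_sl, dtype=float)
    if netted.size == 0:
        raise ValueError("need a nonempty netted sample")
    consumed = np.asarray(consumed_sl, dtype=float)
    alpha_n = 100.0 * float(np.mean(netted > threshold))
    alpha_c = 100.0 * float(np.mean(consumed > threshold)) if consumed.size else 0.0
    upper = expected_rejection_bound(alpha_n)
    flagged = (alpha_n > ALPHA_N_TRIGGER) and (alpha_c < upper)
    return RejectionScreen(
        site=site,
        threshold_sl=float(threshold),
        alpha_n=alpha_n,
        alpha_c=alpha_c,
        expected_upper=upper,
        flagged=bool(flagged),
    )
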