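"""Hatch-cohort assignment and growth-trajectory comparison.

Juveniles within a year are assigned to hatch cohorts by agglomerative
clustering (Ward linkage) on standardised (age, SL); labels are ordered
young to old by mean cohort age. Back-calculated SL at 5-day age intervals
is then compared between consumed and netted fish with a one-way MANOVA
(Wilks' lambda) over the common age window, followed by per-age univariate
F tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from sklearn.cluster import AgglomerativeClustering
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "TrajectoryMatrix",
    "assign_cohorts",
    "build_trajectory_matrix",
    "compare_trajectories",
]

AGE_STEP = 5  # days between trajectory columns


@dataclass
class TrajectoryMatrix:
    """Back-calculated SL at 5-day ages, one row per individual.

    ``values`` is (n_individuals, n_ages) with NaN beyond an individual's
    capture age; ``groups`` holds 'consumed'/'netted'; ``cohorts`` optional
    cohort labels.
    """

    values: np.ndarray
    ages: np.ndarray
    groups: np.ndarray
    cohorts: np.ndarray | None = None


def assign_cohorts(records: pd.DataFrame, k: int) -> np.ndarray:
    """Ward-linkage clustering of (age, SL) into k cohorts, labelled 0..k-1
    from youngest to oldest mean age. Deterministic and order-invariant."""
    if k < 1:
        raise ValueError("k must be at least 1")
    n = len(records)
    if k > n:
        raise ValueError(f"cannot form {k} cohorts from {n} records")
    if k == 1:
        return np.zeros(n, dtype=int)
    X = records[["age", "sl"]].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    # reorder labels young -> old
    mean_age = [records["age"].to_numpy()[raw == c].mean() for c in range(k)]
    order = np.argsort(mean_age)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def build_trajectory_matrix(
    trajectories: pd.DataFrame,
    groups: pd.Series | dict,
    cohorts: dict | None = None,
) -> TrajectoryMatrix:
    """Pivot long back-calculated series into a 5-day trajectory matrix.

    ``trajectories`` is long format (id, age, sl); only ages on the 5-day
    grid are kept. ``groups`` maps id -> 'consumed'/'netted'.
    """
    df = trajectories[trajectories["age"] % AGE_STEP == 0]
    wide = df.pivot_table(index="id", columns="age", values="sl")
    ids = wide.index.to_numpy()
    gmap = groups if isinstance(groups, dict) else dict(groups)
    return TrajectoryMatrix(
        values=wide.to_numpy(),
        ages=wide.columns.to_numpy(),
        groups=np.array([gmap[i] for i in ids]),
        cohorts=np.array([cohorts[i] for i in ids]) if cohorts else None,
    )


def _common_window(matrix: TrajectoryMatrix, labels: np.ndarray) -> np.ndarray:
    """Column mask where every compared group is fully observed."""
    ok = np.ones(matrix.ages.size, dtype=bool)
    for g in np.unique(labels):
        sub = matrix.values[labels == g]
        ok &= ~np.isnan(sub).any(axis=0)
    return ok


def compare_trajectories(
    matrix: TrajectoryMatrix,
    groups: np.ndarray | None = None,
    alpha: float = 0.05,
) -> dict:
    """One-way MANOVA (Wilks' lambda) of trajectories between groups, with
    per-age post-hoc F tests.

    Uses the common age window (ages observed for every individual of every
    group). When the window holds more ages than residual degrees of freedom
    allow, it is coarsened from the youngest end with a warning. Returns a
    dict with the omnibus statistic, per-age F table and the ages that
    differ at ``alpha``.
    """
    labels = matrix.groups if groups is None else np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups to compare")
    for g in uniq:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 individuals")
    mask = _common_window(matrix, labels)
    if not mask.any():
        raise ValueError("no common age window between groups")
    Y = matrix.values[:, mask]
    ages = matrix.ages[mask]
    n = Y.shape[0]
    max_p = n - uniq.size - 1
    if Y.shape[1] > max_p:
        import warnings

        warnings.warn(
            f"coarsening age window from {Y.shape[1]} to {max_p} columns "
            "(singular covariance)",
            stacklevel=2,
        )
        Y = Y[:, -max_p:]
        ages = ages[-max_p:]

    group_means = np.stack([Y[labels == g].mean(axis=0) for g in uniq])
    if np.allclose(group_means, group_means[0], atol=1e-12):
        # no between-group signal at all: H = 0 exactly
        wilks, f_stat, p_omni = 1.0, 0.0, 1.0
    elif Y.shape[1] == 1:
        # one age column: the multivariate test degenerates to one-way ANOVA
        f_stat, p_omni = (float(v) for v in f_oneway(*[Y[labels == g, 0] for g in uniq]))
        sse = sum(((Y[labels == g, 0] - Y[labels == g, 0].mean()) ** 2).sum() for g in uniq)
        sst = ((Y[:, 0] - Y[:, 0].mean()) ** 2).sum()
        wilks = float(sse / sst)
    else:
        exog = np.column_stack([np.ones(n), pd.get_dummies(labels).to_numpy(float)[:, 1:]])
        mv = MANOVA(endog=Y, exog=exog)
        tbl = mv.mv_test(hypotheses=[("group", np.eye(exog.shape[1])[1:], None)])
        stat = tbl.results["group"]["stat"]
        wilks = float(stat.loc["Wilks' lambda", "Value"])
        f_stat = float(stat.loc["Wilks' lambda", "F Value"])
        p_omni = float(stat.loc["Wilks' lambda", "Pr > F"])

    rows = []
    for j, age in enumerate(ages):
        samples = [Y[labels == g, j] for g in uniq]
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(Y[:, j]) == 0:
            F, p = 0.0, 1.0
        else:
            F, p = f_oneway(*samples)
        rows.append({"age": int(age), "F": float(F), "p": float(p)})
    per_age = pd.DataFrame(rows)
    return {
        "wilks_lambda": wilks,
        "F": f_stat,
        "p": p_omni,
        "per_age": per_age,
        "significant_ages": per_age.loc[per_age["p"] < alpha, "age"].tolist(),
        "n_per_group": {g: int((labels == g).sum()) for g in uniq},
        "ages": ages.tolist(),
    }
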