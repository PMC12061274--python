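"""Distribution-free group and paired comparisons.

Group differences are assessed by label-permutation tests (statistic:
absolute difference of means for two groups, between-group variance of the
group means for three or more); within-animal light ON/OFF designs by
sign-flip tests on the paired differences.  p-values use the add-one
convention ``p = (1 + #{perm >= obs}) / (n_perm + 1)``, which is valid
(never anti-conservative) for any number of permutations.  Every result
records its seed and permutation count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TestResult",
    "permutation_group_test",
    "paired_onoff_test",
    "summarize_group_time",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_perm: int
    effect_size: float   # difference of means (two groups) or max pairwise diff
    seed: int
    statistic_name: str = "abs_mean_diff"


def _group_stat(pooled: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Test statistic for pooled data (last axis = observations).

    Two groups: |mean_1 - mean_2|.  More: population variance of the group
    means (sensitive to any separation of means).
    Works on stacked permutations: ``pooled`` may be (n_perm, N).
    """
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    means = np.stack(
        [pooled[..., bounds[i]:bounds[i + 1]].mean(axis=-1) for i in range(len(sizes))],
        axis=-1,
    )
    if len(sizes) == 2:
        return np.abs(means[..., 0] - means[..., 1])
    return means.var(axis=-1)


def permutation_group_test(
    values_by_group: dict[str, np.ndarray] | list[np.ndarray],
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Label-permutation test that group means are equal.

    All observations are pooled and group labels reshuffled ``n_perm``
    times; the p-value is the add-one-smoothed fraction of permuted
    statistics at least as large as the observed one.  Constant data give
    p = 1 by convention.
    """
    groups = list(values_by_group.values()) if isinstance(values_by_group, dict) \
        else list(values_by_group)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    means = np.array([g.mean() for g in groups])
    effect = float(means.max() - means.min())
    if np.ptp(pooled) == 0:  # degenerate: no variation at all
        return TestResult(0.0, 1.0, n_perm, 0.0, seed,
                          "abs_mean_diff" if len(groups) == 2 else "var_of_means")
    obs = float(_group_stat(pooled[None, :], sizes)[0])
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm_stats = _group_stat(pooled[idx], sizes)
    # strict exceedance: permutations tied with the observed statistic (the
    # re-created observed split itself) do not count against it
    p = (1.0 + np.sum(perm_stats > obs + 1e-12)) / (n_perm + 1.0)
    return TestResult(obs, float(p), n_perm, effect, seed,
                      "abs_mean_diff" if len(groups) == 2 else "var_of_means")


def paired_onoff_test(
    off_values: np.ndarray,
    on_values: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Sign-flip test for a within-animal ON vs OFF design.

    Statistic: ``mean(on - off)``.  Under the null the sign of each
    animal's difference is exchangeable, so the null distribution is built
    from random sign flips; the test is two-sided on |statistic|.
    """
    off = np.asarray(off_values, dtype=float)
    on = np.asarray(on_values, dtype=float)
    if off.shape != on.shape:
        raise ValueError("paired vectors must have equal length")
    if off.size < 2:
        raise ValueError("need >= 2 pairs")
    d = on - off
    obs = float(d.mean())
    if np.all(d == 0):
        return TestResult(0.0, 1.0, n_perm, 0.0, seed, "mean_paired_diff")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    perm = np.abs((signs * d).mean(axis=1))
    # ties count: the identity flip always reproduces |obs|, so the floor
    # is ~2/2^n for n pairs, as exact enumeration gives
    p = (1.0 + np.sum(perm >= abs(obs) - 1e-12)) / (n_perm + 1.0)
    return TestResult(obs, float(p), n_perm, obs, seed, "mean_paired_diff")


def summarize_group_time(
    cohort: pd.DataFrame,
    metric: str,
    task: str,
    condition: str,
) -> pd.DataFrame:
    """Per-genotype, per-minute mean and SEM of a cohort metric.

    ``cohort`` is the long-format cohort table with columns ``animal_id,
    genotype, task, condition, metric, bin, value``.  SEM = sd/sqrt(n) with
    the n-1 sd; undefined (NaN) for single-animal groups.  Duplicate
    (animal, bin) rows violate the table invariant and are rejected.
    """
    sel = cohort[
        (cohort["metric"] == metric)
        & (cohort["task"] == task)
        & (cohort["condition"] == condition)
    ]
    if sel.empty:
        raise ValueError(f"no rows for metric={metric!r} task={task!r} condition={condition!r}")
    if sel.duplicated(["animal_id", "genotype", "bin"]).any():
        raise ValueError("duplicate (animal, bin) rows in cohort table")
    out = (
        sel.groupby(["genotype", "bin"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["sem"] = np.where(out["n"] > 1, out["sd"] / np.sqrt(out["n"]), np.nan)
    return out.drop(columns="sd")
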