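"""Estimation statistics: unpaired mean differences with BCa bootstrap
confidence intervals, permutation p-values, and Welch's t.

Conventions: the effect is ``mean(b) - mean(a)`` with ``a`` the control
group; the permutation test is two-sided on the absolute mean difference
with the (b+1)/(N+1) estimator, so p is never exactly 0; all resampling
takes an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import ttest_ind

__all__ = [
    "EffectSize",
    "mean_difference",
    "bca_ci",
    "permutation_p",
    "welch_t",
    "effect_size",
    "bootstrap_distribution",
]

DEFAULT_N_BOOT = 5000
DEFAULT_N_PERM = 5000


@dataclass(frozen=True)
class EffectSize:
    """Unpaired mean difference with BCa 95% CI and permutation p."""

    mean_difference: float
    ci_low: float
    ci_high: float
    permutation_p: float
    n_boot: int
    n_perm: int
    seed: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")
        if not (0.0 < self.permutation_p <= 1.0):
            raise ValueError("permutation_p must be in (0, 1]")


def _validate_group(values, name: str, min_size: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_size:
        raise ValueError(f"group {name!r} needs >= {min_size} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name!r} contains non-finite values")
    return arr


def mean_difference(a, b) -> float:
    """mean(b) − mean(a); a is the control/reference group."""
    a = _validate_group(a, "a")
    b = _validate_group(b, "b")
    return float(b.mean() - a.mean())


def bootstrap_distribution(a, b, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None) -> np.ndarray:
    """Bootstrap distribution of the unpaired mean difference.

    Each group is resampled with replacement independently; returns the
    ``n_boot`` resampled mean differences.
    """
    a = _validate_group(a, "a", 2)
    b = _validate_group(b, "b", 2)
    rng = np.random.default_rng(seed)
    boot_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boot_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    return boot_b - boot_a


def bca_ci(
    a,
    b,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for the mean difference.

    The bias correction z0 comes from the fraction of bootstrap statistics
    strictly below the observed statistic; the acceleration from a jackknife
    over all pooled leave-one-out mean differences. When z0 is infinite
    (every bootstrap statistic on one side) or the jackknife variance is
    zero, the plain percentile interval is returned with a logged warning.
    """
    a = _validate_group(a, "a", 2)
    b = _validate_group(b, "b", 2)
    theta_hat = float(b.mean() - a.mean())
    boot = bootstrap_distribution(a, b, n_boot=n_boot, seed=seed)

    prop_below = float(np.mean(boot < theta_hat))
    # jackknife over every observation in either group
    n_a, n_b = a.size, b.size
    loo_a = (a.sum() - a) / (n_a - 1)  # mean of a with one value removed
    loo_b = (b.sum() - b) / (n_b - 1)
    jack = np.concatenate([b.mean() - loo_a, loo_b - a.mean()])
    u = jack.mean() - jack
    denom = float((u**2).sum()) ** 1.5

    if prop_below in (0.0, 1.0) or denom == 0.0:
        warnings.warn(
            "BCa undefined (degenerate z0 or zero jackknife variance); "
            "falling back to the percentile interval",
            stacklevel=2,
        )
        lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        return float(lo), float(hi)

    z0 = float(ndtri(prop_below))
    accel = float((u**3).sum()) / (6.0 * denom)
    z_alpha = ndtri([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = ndtr(z0 + (z0 + z_alpha) / (1.0 - accel * (z0 + z_alpha)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)


def permutation_p(
    a,
    b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> float:
    """Two-sided permutation p-value for the mean difference.

    Pooled values are randomly relabeled at fixed group sizes;
    p = (n_extreme + 1) / (n_perm + 1) where a permutation is extreme when
    its |mean difference| is at least the observed one. With
    ``exhaustive=True`` (or automatically when the number of distinct splits
    is at most ``n_perm``) every split is enumerated and the exact fraction
    returned.
    """
    a = _validate_group(a, "a", 2)
    b = _validate_group(b, "b", 2)
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(b.mean() - a.mean())
    tol = 1e-12 * (1.0 + observed)

    n_splits = comb(pooled.size, n_a)
    if exhaustive is None:
        exhaustive = n_splits <= min(n_perm, 20000)

    if exhaustive:
        total = pooled.sum()
        extreme = 0
        for idx in combinations(range(pooled.size), n_a):
            mean_a = pooled[list(idx)].mean()
            mean_b = (total - pooled[list(idx)].sum()) / (pooled.size - n_a)
            if abs(mean_b - mean_a) >= observed - tol:
                extreme += 1
        return extreme / n_splits

    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, pooled.size))
    order = np.argsort(keys, axis=1)
    perm = pooled[order]
    diffs = np.abs(perm[:, n_a:].mean(axis=1) - perm[:, :n_a].mean(axis=1))
    n_extreme = int(np.count_nonzero(diffs >= observed - tol))
    return (n_extreme + 1) / (n_perm + 1)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with the t statistic oriented as
    ``mean(b) - mean(a)`` (consistent with :func:`mean_difference`) and the
    Welch–Satterthwaite degrees of freedom.
    """
    a = _validate_group(a, "a", 2)
    b = _validate_group(b, "b", 2)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both groups have zero variance; Welch's t undefined")
    res = ttest_ind(b, a, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def effect_size(
    a,
    b,
    n_boot: int = DEFAULT_N_BOOT,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    seed: int = 0,
) -> EffectSize:
    """Full estimation-statistics summary for one two-group comparison."""
    boot_seq, perm_seq = np.random.SeedSequence(seed).spawn(2)
    lo, hi = bca_ci(a, b, n_boot=n_boot, alpha=alpha, seed=boot_seq)
    p = permutation_p(a, b, n_perm=n_perm, seed=perm_seq, exhaustive=False)
    return EffectSize(
        mean_difference=mean_difference(a, b),
        ci_low=lo,
        ci_high=hi,
        permutation_p=p,
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )
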