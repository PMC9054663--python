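"""Estimation statistics shared by all pipeline stages.

Inference follows the estimation-statistics style: group differences are
reported as Cohen's d with bootstrap confidence intervals (the numbers behind
a Gardner-Altman plot), and map-on-map comparisons as standardized linear-model
coefficients with parametric 95% intervals. Cohen's d uses the classic
pooled-SD form (Cohen 1988 conventions: small < 0.2, medium < 0.4,
large < 0.8); Hedges' small-sample correction is available as an option.

Bootstrap intervals are percentile by default (5000 resamples, seeded), with a
BCa option. Voxelwise group tests support FDR or permutation-based
cluster-extent correction; random-field cluster correction is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .errors import GeometryError, UndefinedEffectError, ValidationError

__all__ = [
    "EffectEstimate",
    "cohens_d",
    "bootstrap_ci",
    "bootstrap_effect",
    "standardized_coef",
    "voxelwise_group_test",
]


@dataclass
class EffectEstimate:
    """A point estimate with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    method: str  # "pooled-d" | "std-coef"
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    name: Optional[str] = None

    def as_dict(self) -> dict:
        return {"name": self.name, "estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "method": self.method, "n_boot": self.n_boot,
                "seed": self.seed}


def cohens_d(group_a, group_b, hedges: bool = False) -> float:
    """Standardized mean difference ``(mean_a - mean_b) / pooled_sd``.

    The pooled standard deviation uses ``n - 1`` weights. ``hedges=True``
    applies the small-sample bias correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise UndefinedEffectError("pooled variance is zero; d is undefined")
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    if hedges:
        dof = na + nb - 2
        d *= 1 - 3 / (4 * dof - 1)
    return float(d)


def _resample_groups(groups, rng: np.random.Generator):
    return tuple(g[rng.integers(g.size, size=g.size)] for g in groups)


def bootstrap_ci(statistic: Callable, data, n_boot: int = 5000, seed: int = 0,
                 method: str = "percentile") -> tuple[float, float, np.ndarray]:
    """Bootstrap 95% CI of ``statistic`` over within-group resampling.

    ``data`` is a single array or a tuple of group arrays; resampling is with
    replacement within each group. Resamples on which the statistic is
    undefined (raises :class:`UndefinedEffectError` or returns non-finite) are
    skipped and counted; the returned distribution excludes them.

    Returns ``(ci_low, ci_high, resample_distribution)``. ``method`` may be
    ``"percentile"`` (default) or ``"bca"``.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    if method not in ("percentile", "bca"):
        raise ValidationError(f"unknown bootstrap method {method!r}")
    groups = data if isinstance(data, tuple) else (data,)
    groups = tuple(np.asarray(g, dtype=float).ravel() for g in groups)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    skipped = 0
    for i in range(n_boot):
        try:
            val = statistic(*_resample_groups(groups, rng))
        except UndefinedEffectError:
            val = np.nan
        draws[i] = val
        if not np.isfinite(val):
            skipped += 1
    dist = draws[np.isfinite(draws)]
    if dist.size == 0:
        raise UndefinedEffectError("statistic undefined on every bootstrap resample")
    if method == "percentile":
        lo, hi = np.percentile(dist, [2.5, 97.5])
    else:
        lo, hi = _bca_interval(statistic, groups, dist)
    ci = (float(lo), float(hi), dist)
    ci[2].setflags(write=False)
    return ci


def _bca_interval(statistic, groups, dist, alpha: float = 0.05):
    """Bias-corrected and accelerated bounds from jackknife acceleration."""
    theta = statistic(*groups)
    z0 = stats.norm.ppf(np.clip((dist < theta).mean(), 1e-9, 1 - 1e-9))
    jack = []
    for gi, g in enumerate(groups):
        for j in range(g.size):
            parts = list(groups)
            parts[gi] = np.delete(g, j)
            try:
                jack.append(statistic(*parts))
            except UndefinedEffectError:
                continue
    jack = np.asarray(jack, dtype=float)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    return tuple(np.percentile(dist, 100 * adj))


def bootstrap_effect(group_a, group_b, n_boot: int = 5000, seed: int = 0,
                     method: str = "percentile", hedges: bool = False) -> EffectEstimate:
    """Cohen's d of two groups with a bootstrap CI (Gardner-Altman numbers)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    stat = lambda x, y: cohens_d(x, y, hedges=hedges)
    lo, hi, _ = bootstrap_ci(stat, (a, b), n_boot=n_boot, seed=seed, method=method)
    return EffectEstimate(estimate=stat(a, b), ci_low=lo, ci_high=hi,
                          method="pooled-d", n_boot=n_boot, seed=seed)


def standardized_coef(y, x, names: Optional[Sequence[str]] = None) -> list[EffectEstimate]:
    """Standardized OLS coefficients with parametric 95% CIs.

    ``y`` and every column of ``x`` are z-scored (sample SD) before an
    ordinary least-squares fit with intercept; one :class:`EffectEstimate` is
    returned per predictor.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValidationError("y and X must have equal row counts")
    if x.shape[0] < x.shape[1] + 2:
        raise ValidationError("need at least n_predictors + 2 observations")
    if y.std(ddof=1) == 0:
        raise UndefinedEffectError("response has zero variance")
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValidationError("zero-variance predictor column")
    yz = (y - y.mean()) / y.std(ddof=1)
    xz = (x - x.mean(axis=0)) / sds
    model = sm.OLS(yz, sm.add_constant(xz)).fit()
    conf = model.conf_int(alpha=0.05)
    names = list(names) if names is not None else [f"x{i}" for i in range(x.shape[1])]
    out = []
    for i in range(x.shape[1]):
        out.append(EffectEstimate(estimate=float(model.params[i + 1]),
                                  ci_low=float(conf[i + 1, 0]),
                                  ci_high=float(conf[i + 1, 1]),
                                  method="std-coef", name=names[i]))
    return out


def voxelwise_group_test(maps_a: np.ndarray, maps_b: np.ndarray, mask: np.ndarray,
                         correction: str = "fdr", alpha: float = 0.05,
                         n_permutations: int = 1000, cluster_z: float = 2.3,
                         seed: int = 0):
    """Voxelwise two-sample t-test with multiple-comparison control.

    ``maps_a`` and ``maps_b`` are ``(n_subjects, x, y, z)`` stacks on a common
    grid. ``correction`` is ``"none"``, ``"fdr"`` (Benjamini-Hochberg on voxel
    p-values) or ``"permutation-cluster"`` (cluster-extent null from group
    relabeling at threshold ``cluster_z``).

    Returns ``(t_map, significant_mask)`` as 3D arrays (NaN / False outside
    the mask).
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if maps_a.shape[1:] != mask.shape or maps_b.shape[1:] != mask.shape:
        raise GeometryError("maps and mask must share the voxel grid")
    if maps_a.shape[0] < 2 or maps_b.shape[0] < 2:
        raise ValidationError("need at least 2 maps per group")
    a = maps_a[:, mask]
    b = maps_b[:, mask]
    t, p = stats.ttest_ind(a, b, axis=0)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)

    if correction == "none":
        sig = p < alpha
    elif correction == "fdr":
        sig = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    elif correction == "permutation-cluster":
        sig = _permutation_cluster(a, b, mask, t, alpha=alpha, cluster_z=cluster_z,
                                   n_permutations=n_permutations, seed=seed)
    else:
        raise ValidationError(f"unknown correction {correction!r}")

    t_map = np.full(mask.shape, np.nan)
    t_map[mask] = t
    sig_map = np.zeros(mask.shape, dtype=bool)
    sig_map[mask] = sig
    return t_map, sig_map


def _cluster_sizes(stat_3d: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    labeled, n = ndimage.label(np.abs(stat_3d) > threshold)
    if n == 0:
        return labeled, np.array([])
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    return labeled, sizes


def _permutation_cluster(a, b, mask, t_obs, alpha, cluster_z, n_permutations, seed):
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValidationError("permutation-cluster needs at least 2 maps in each group")
    pooled = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    t3 = np.zeros(mask.shape)
    t3[mask] = t_obs
    labeled, sizes = _cluster_sizes(t3, cluster_z)
    if sizes.size == 0:
        return np.zeros(a.shape[1], dtype=bool)
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(na + nb)
        ta, _ = stats.ttest_ind(pooled[perm[:na]], pooled[perm[na:]], axis=0)
        t3p = np.zeros(mask.shape)
        t3p[mask] = np.nan_to_num(ta, nan=0.0)
        _, psizes = _cluster_sizes(t3p, cluster_z)
        null_max[i] = psizes.max() if psizes.size else 0.0
    crit = np.quantile(null_max, 1 - alpha)
    keep = np.zeros(mask.shape, dtype=bool)
    for ci, size in enumerate(sizes, start=1):
        if size > crit:
            keep |= labeled == ci
    return keep[mask]
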