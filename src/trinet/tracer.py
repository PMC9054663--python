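"""Projection-input-similarity mapping from anterograde tracer volumes.

Given N tracer-density volumes from injections confined to one hemisphere, the
input profile of a seed region placed in the *contralateral* hemisphere is its
mean density per experiment — an N-vector describing which injections reach
it. Correlating this profile, across experiments, with the profile of every
other voxel highlights territories that receive inputs from the same sources
as the seed (as opposed to comparing outgoing projections). Repeating the
procedure for several seeds and taking the winner among similarity maps yields
a winner-take-all network partition of the brain.

Similarity is Pearson correlation over experiments by default (Spearman
available); voxels with zero density across all experiments are excluded
(NaN), not set to zero, to avoid artificial background structure. Statistical
thresholding of similarity maps uses a Fisher z-transform with parametric
p-values or a permutation option, in place of random-field cluster machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import GeometryError, InsufficientExperimentsError, ValidationError
from .synthetic import TracerSet

__all__ = [
    "SimilarityMap",
    "seed_input_profile",
    "input_similarity",
    "network_partition",
    "spatial_map_regression",
]


@dataclass
class SimilarityMap:
    """Per-voxel correlation with a seed's input profile."""

    r_values: np.ndarray  # 3D, NaN where undefined
    seed_id: str
    n_experiments_used: int

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        finite = self.r_values[np.isfinite(self.r_values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")


def _seed_hemisphere(seed_mask: np.ndarray) -> str:
    xs = np.nonzero(seed_mask)[0]
    return "left" if xs.mean() < (seed_mask.shape[0] - 1) / 2 else "right"


def seed_input_profile(tracers: TracerSet, seed_mask: np.ndarray,
                       validate_contralateral: bool = True) -> np.ndarray:
    """Mean tracer density within the seed, per experiment (an N-vector).

    The seed is expected to lie contralateral to the injection sites; if the
    majority of seed voxels sit in the injection hemisphere a warning is
    emitted (the profile is still returned).
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != tracers.grid_shape:
        raise GeometryError("seed mask must be on the tracer grid")
    if not seed_mask.any():
        raise ValidationError("seed mask is empty")
    if validate_contralateral and "hemisphere" in tracers.injection_meta:
        inj = tracers.injection_meta["hemisphere"].mode().iat[0]
        if _seed_hemisphere(seed_mask) == inj:
            warnings.warn("seed mask lies ipsilateral to the injection hemisphere",
                          stacklevel=2)
    return tracers.volumes[:, seed_mask].mean(axis=1)


def input_similarity(tracers: TracerSet, profile: np.ndarray, seed_id: str = "seed",
                     method: str = "pearson",
                     normalize_experiments: bool = False) -> SimilarityMap:
    """Correlate every voxel's cross-experiment density profile with the seed profile.

    Voxels whose density is zero across all experiments, or constant, are
    undefined (NaN). Requires at least 3 experiments.

    ``normalize_experiments=True`` z-scores each experiment's volume across
    voxels before correlating (the seed profile, being a masked mean of raw
    densities, is transformed consistently). This removes per-experiment
    amplitude and offset — tracer units are arbitrary per injection — and
    makes the similarity map exactly invariant to a positive affine rescaling
    of any single experiment's volume, which plain Pearson on raw profiles is
    not.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    n = tracers.n_experiments
    if profile.shape[0] != n:
        raise ValidationError("profile length must equal the number of experiments")
    if n < 3:
        raise InsufficientExperimentsError("need at least 3 tracer experiments")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    x = tracers.volumes.reshape(n, -1)  # (N, voxels)
    all_zero = (x == 0).all(axis=0)
    if normalize_experiments:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        # masked means transform affinely with the volume they came from
        profile = ((profile - mu.ravel()) / sd.ravel())
        x = (x - mu) / sd
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
        profile = stats.rankdata(profile)
    pc = profile - profile.mean()
    pn = np.linalg.norm(pc)
    if pn == 0:
        raise ValidationError("seed profile has zero variance")
    xc = x - x.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ pc) / (xn * pn)
    r[xn == 0] = np.nan
    r[all_zero] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return SimilarityMap(r.reshape(tracers.grid_shape), seed_id=seed_id,
                         n_experiments_used=n)


def network_partition(similarity_maps: Union[Sequence[SimilarityMap], Mapping[str, SimilarityMap]],
                      r_threshold: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Winner-take-all network labels from per-seed similarity maps.

    Voxel label is ``1 + argmax`` over seeds of the similarity value, provided
    the winning value exceeds ``r_threshold``; otherwise 0 (background). Ties
    go to the earlier seed in the supplied order and are flagged.

    Returns ``(labels, tie_flags)`` as 3D arrays.
    """
    if isinstance(similarity_maps, Mapping):
        maps = list(similarity_maps.values())
    else:
        maps = list(similarity_maps)
    if len(maps) < 1:
        raise ValidationError("need at least one similarity map")
    shapes = {m.r_values.shape for m in maps}
    if len(shapes) != 1:
        raise GeometryError("similarity maps must share a grid")
    stack = np.stack([m.r_values for m in maps])  # (S, x, y, z)
    filled = np.nan_to_num(stack, nan=-np.inf)
    winner = filled.argmax(axis=0)
    best = filled.max(axis=0)
    labels = np.where(best > r_threshold, winner + 1, 0).astype(np.int32)
    ties = (filled == best[None]).sum(axis=0) > 1
    ties &= labels > 0
    return labels, ties


def spatial_map_regression(response_map: np.ndarray, network_maps: Sequence[np.ndarray],
                           mask: np.ndarray, names: Optional[Sequence[str]] = None):
    """Regress an evoked-response map on network maps within a mask.

    All maps are vectorized over mask voxels and fitted with a multiple linear
    model; standardized coefficients with parametric 95% CIs are returned, one
    per network map. Near-collinear network maps trigger a rank warning.
    """
    from .effectstats import standardized_coef

    mask = np.asarray(mask, dtype=bool)
    response_map = np.asarray(response_map, dtype=float)
    if response_map.shape != mask.shape:
        raise GeometryError("response map and mask must share a grid")
    if not mask.any():
        raise ValidationError("mask is empty")
    cols = []
    for m in network_maps:
        m = np.asarray(m, dtype=float)
        if m.shape != mask.shape:
            raise GeometryError("network maps and mask must share a grid")
        cols.append(m[mask])
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        warnings.warn("network maps are collinear within the mask; "
                      "coefficients are not uniquely determined", stacklevel=2)
    return standardized_coef(response_map[mask], x, names=names)
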