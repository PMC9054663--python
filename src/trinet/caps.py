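"""Co-activation-pattern (CAP) brain-state extraction and transition dynamics.

Resting-state frames are first screened by two criteria — supra-threshold
activity in at least one seed region, and framewise displacement below a
species-specific cutoff — then pooled across runs and clustered with K-means.
Each cluster centroid is one CAP: the average of the frames assigned to it.
The clustering dimension is chosen by consensus clustering over random frame
subsamples, minimizing the percentage of ambiguously clustered pairs (PAC).
Because each retained frame belongs to exactly one CAP, a row-stochastic
transition matrix and per-state entry counts follow directly from the label
sequence (a state repeated on consecutive frames counts as a transition onto
itself).

Two conventions are deliberate and configurable:

* transitions are, by default, only counted between retained frames that were
  adjacent in original acquisition time — a pair spanning scrubbed frames is
  not a one-step transition (``count_across_gaps=True`` restores the pooled
  behaviour);
* a state *entry* is counted when the state differs from the previous adjacent
  retained frame's state, and at the first frame of every retained contiguous
  segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .core_io import MotionTrace, TimeSeriesVolume, mask_frames
from .errors import CapacityError, UndefinedEffectError, ValidationError

__all__ = [
    "FrameSelection",
    "CapModel",
    "TransitionMatrix",
    "PacCurve",
    "framewise_displacement",
    "select_frames",
    "stack_retained_frames",
    "fit_caps",
    "pac_model_selection",
    "transition_stats",
    "match_states",
    "compare_transitions",
]


@dataclass
class FrameSelection:
    """Outcome of the two-criterion volume screen for one run."""

    retained: np.ndarray  # bool per frame
    reason_codes: dict  # rejected frame index -> "seed-fail" | "fd-fail" | "both"
    fd_mm: np.ndarray  # per-frame framewise displacement
    seed_z: np.ndarray  # per-frame max z over seeds

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if np.any(self.fd_mm < 0):
            raise ValidationError("framewise displacement cannot be negative")

    @property
    def retention_fraction(self) -> float:
        return float(self.retained.mean())

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)


@dataclass
class CapModel:
    """K-means CAP solution over the pooled retained frames."""

    K: int
    centroids: np.ndarray  # (K, n_mask_voxels)
    assignments: np.ndarray  # retained-frame -> cluster id 0..K-1
    config: dict = field(default_factory=dict)
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.centroids.shape[0] != self.K:
            raise ValidationError("centroid count must equal K")
        if self.assignments.min(initial=0) < 0 or self.assignments.max(initial=0) >= self.K:
            raise ValidationError("assignments must be in 0..K-1")


@dataclass
class TransitionMatrix:
    """Counts, row-normalized probabilities, and per-state entry counts."""

    counts: np.ndarray
    probabilities: np.ndarray
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        row_sums = self.counts.sum(axis=1)
        probs = self.probabilities[row_sums > 0]
        if probs.size and not np.allclose(probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("probability rows with nonzero counts must sum to 1")

    @property
    def K(self) -> int:
        return self.counts.shape[0]


@dataclass
class PacCurve:
    """Percentage of ambiguously clustered pairs per candidate K."""

    pac: dict  # K -> PAC value in [0, 1]
    n_subsamples: int
    subsample_fraction: float
    ambiguity_bounds: tuple[float, float]
    n_frames_used: int

    @property
    def best_k(self) -> int:
        """Candidate K minimizing PAC (smallest K on ties)."""
        best = min(self.pac.items(), key=lambda kv: (kv[1], kv[0]))
        return best[0]


# ---------------------------------------------------------------------------
# Motion scrubbing


def framewise_displacement(motion: MotionTrace, sphere_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement.

    ``fd(t) = sum |delta translations| + radius * sum |delta rotations|`` with
    ``fd(0) = 0``; rotations are converted to arc length on a sphere of the
    given head radius (conventionally 50 mm for human, 25 mm macaque,
    5 mm mouse).
    """
    if motion.n_frames < 2:
        raise ValidationError("need at least 2 frames to compute displacement")
    dt = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + sphere_radius_mm * dr])
    return fd


# ---------------------------------------------------------------------------
# Frame selection


def select_frames(ts: TimeSeriesVolume, seed_masks: Sequence[np.ndarray],
                  seed_threshold_z: float = 0.0, fd_mm: Optional[np.ndarray] = None,
                  fd_threshold_mm: float = np.inf) -> FrameSelection:
    """Two-criterion volume selection.

    A frame is retained iff (1) the z-scored mean time course of at least one
    seed region exceeds ``seed_threshold_z`` at that frame, and (2) its
    framewise displacement is below ``fd_threshold_mm``. Rejected frames carry
    a reason code (``seed-fail`` / ``fd-fail`` / ``both``).

    ``fd_mm`` defaults to the run's own motion trace (all zeros if absent).
    """
    if len(seed_masks) == 0:
        raise ValidationError("need at least one seed mask")
    n = ts.n_frames
    seed_z = np.full((len(seed_masks), n), -np.inf)
    for i, mask in enumerate(seed_masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ts.spatial_shape:
            raise ValidationError("seed mask shape must equal the run's spatial shape")
        if not mask.any():
            raise ValidationError("seed mask is empty")
        series = ts.frames[mask].mean(axis=0)
        sd = series.std()
        seed_z[i] = (series - series.mean()) / (sd if sd > 0 else 1.0)
    max_z = seed_z.max(axis=0)

    if fd_mm is None:
        fd_mm = (framewise_displacement(ts.motion) if ts.motion is not None
                 else np.zeros(n))
    fd_mm = np.asarray(fd_mm, dtype=float)
    if fd_mm.shape[0] != n:
        raise ValidationError("fd_mm length must equal the number of frames")

    seed_ok = max_z > seed_threshold_z
    fd_ok = fd_mm < fd_threshold_mm
    retained = seed_ok & fd_ok
    reasons = {}
    for t in np.flatnonzero(~retained):
        if not seed_ok[t] and not fd_ok[t]:
            reasons[int(t)] = "both"
        elif not seed_ok[t]:
            reasons[int(t)] = "seed-fail"
        else:
            reasons[int(t)] = "fd-fail"
    return FrameSelection(retained, reasons, fd_mm, max_z)


def stack_retained_frames(runs: Sequence[TimeSeriesVolume],
                          selections: Sequence[FrameSelection]) -> tuple[np.ndarray, pd.DataFrame]:
    """Pool retained frames across runs into masked-matrix form.

    Returns ``(X, info)`` where ``X`` is ``(n_retained_total, n_mask_voxels)``
    and ``info`` records the originating run index and original frame time of
    every row (needed for gap-aware transition counting).
    """
    if len(runs) != len(selections):
        raise ValidationError("one selection per run required")
    blocks, rows = [], []
    for ri, (run, sel) in enumerate(zip(runs, selections)):
        frames = mask_frames(run)
        idx = sel.retained_indices
        blocks.append(frames[idx])
        rows.append(pd.DataFrame({"run": ri, "time": idx}))
    info = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["run", "time"])
    x = np.vstack(blocks) if blocks else np.empty((0, 0))
    return x, info


# ---------------------------------------------------------------------------
# Clustering


def fit_caps(frames: np.ndarray, K: int, seed: int = 0, n_init: int = 20) -> CapModel:
    """K-means CAP extraction on pooled retained frames.

    Squared-Euclidean K-means with ``n_init`` restarts and a fixed seed; each
    centroid is recomputed as the exact mean of its member frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ValidationError("frames must be (n_frames, n_voxels)")
    if frames.shape[0] < K:
        raise CapacityError(f"cannot fit {K} clusters to {frames.shape[0]} frames")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    labels = km.fit_predict(frames)
    centroids = np.vstack([frames[labels == k].mean(axis=0) if np.any(labels == k)
                           else km.cluster_centers_[k] for k in range(K)])
    return CapModel(K=K, centroids=centroids, assignments=labels,
                    inertia=float(km.inertia_),
                    config={"seed": seed, "n_init": n_init})


def _consensus_pac(frames: np.ndarray, k: int, n_subsamples: int, fraction: float,
                   bounds: tuple[float, float], rng: np.random.Generator,
                   kmeans_n_init: int) -> float:
    n = frames.shape[0]
    m = max(int(round(fraction * n)), k)
    co = np.zeros((n, n), dtype=np.float32)
    both = np.zeros((n, n), dtype=np.float32)
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        labels = KMeans(n_clusters=k, n_init=kmeans_n_init,
                        random_state=int(rng.integers(2**31))).fit_predict(frames[idx])
        both[np.ix_(idx, idx)] += 1
        for c in range(k):
            members = idx[labels == c]
            co[np.ix_(members, members)] += 1
    iu = np.triu_indices(n, k=1)
    seen = both[iu] > 0
    consensus = co[iu][seen] / both[iu][seen]
    lo, hi = bounds
    return float(np.mean((consensus > lo) & (consensus < hi))) if consensus.size else 0.0


def pac_model_selection(frames: np.ndarray, k_range: Sequence[int],
                        n_subsamples: int = 40, fraction: float = 0.8,
                        bounds: tuple[float, float] = (0.1, 0.9), seed: int = 0,
                        max_frames: Optional[int] = 2000,
                        kmeans_n_init: int = 1) -> PacCurve:
    """Consensus-clustering model selection by percentage of ambiguously clustered pairs.

    For each candidate K, K-means is repeated on ``n_subsamples`` random
    subsamples of ``fraction`` of the frames; the consensus index of a frame
    pair is its co-clustering frequency among subsamples containing both, and
    PAC is the fraction of pairs whose consensus lies strictly inside
    ``bounds``. Low PAC marks a stable clustering; ``best_k`` is the argmin.

    ``max_frames`` caps the number of frames entering the consensus matrix
    (a deterministic random subsample given the seed) so the quadratic pair
    bookkeeping stays tractable at study scale; single-initialization K-means
    per subsample preserves the instability the criterion is designed to
    expose.
    """
    frames = np.asarray(frames, dtype=float)
    if len(k_range) == 0:
        raise ValidationError("k_range must be non-empty")
    if n_subsamples < 2:
        raise ValidationError("need at least 2 subsamples")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if max_frames is not None and frames.shape[0] > max_frames:
        keep = rng.choice(frames.shape[0], size=max_frames, replace=False)
        frames = frames[keep]
    pac = {}
    for k in sorted(k_range):
        pac[int(k)] = _consensus_pac(frames, int(k), n_subsamples, fraction, bounds,
                                     rng, kmeans_n_init)
    return PacCurve(pac=pac, n_subsamples=n_subsamples, subsample_fraction=fraction,
                    ambiguity_bounds=bounds, n_frames_used=frames.shape[0])


# ---------------------------------------------------------------------------
# Transition dynamics


def transition_stats(assignments: np.ndarray, frame_info: pd.DataFrame, K: int,
                     count_across_gaps: bool = False) -> TransitionMatrix:
    """Transition counts, probabilities, and state entries from CAP labels.

    ``frame_info`` carries the run index and original acquisition time of each
    assigned frame (as produced by :func:`stack_retained_frames`). A pair of
    consecutive retained frames contributes a transition count when it lies in
    the same run and — unless ``count_across_gaps`` — its times are adjacent
    (t, t+1). A repeated state is a transition of the state onto itself.
    Entries count segment starts and within-segment switches into a state.
    """
    assignments = np.asarray(assignments, dtype=int)
    if len(frame_info) != assignments.shape[0]:
        raise ValidationError("assignments must cover all retained frames")
    frame_info = frame_info.reset_index(drop=True)
    counts = np.zeros((K, K), dtype=np.int64)
    entries = np.zeros(K, dtype=np.int64)
    for _, idx in frame_info.groupby("run").groups.items():
        order = frame_info.loc[idx].sort_values("time")
        labels = assignments[order.index.to_numpy()]
        times = order["time"].to_numpy()
        if labels.size == 0:
            continue
        adjacent = np.diff(times) == 1
        countable = adjacent | count_across_gaps
        for i in np.flatnonzero(countable):
            counts[labels[i], labels[i + 1]] += 1
        entries[labels[0]] += 1
        for i in range(1, labels.size):
            if not adjacent[i - 1]:
                entries[labels[i]] += 1  # new contiguous segment
            elif labels[i] != labels[i - 1]:
                entries[labels[i]] += 1  # switch into the state
    row_sums = counts.sum(axis=1, keepdims=True)
    probs = np.divide(counts, row_sums, out=np.zeros((K, K)), where=row_sums > 0)
    return TransitionMatrix(counts=counts, probabilities=probs, entries=entries)


# ---------------------------------------------------------------------------
# Cross-dataset state matching


def match_states(maps_a: np.ndarray, maps_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one state matching by spatial correlation.

    Both inputs are ``(K, n_features)`` state maps expressed in a common space
    (for cross-species use, humanized to the shared atlas first). Solves the
    assignment maximizing total Pearson correlation and returns
    ``(permutation, matched_correlations)`` where ``maps_b[permutation[i]]``
    is the partner of ``maps_a[i]``.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape != b.shape:
        raise ValidationError("state map sets must be equal-shape (K, n_features)")
    k = a.shape[0]
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    corr = az @ bz.T
    rows, cols = linear_sum_assignment(-corr)
    perm = cols[np.argsort(rows)]
    return perm, corr[np.arange(k), perm]


def compare_transitions(tm_a: TransitionMatrix, tm_b: TransitionMatrix,
                        permutation: Optional[np.ndarray] = None):
    """Standardized coefficient between two vectorized transition matrices.

    ``permutation`` aligns the states of ``tm_b`` to those of ``tm_a`` (as
    returned by :func:`match_states`); both probability matrices are then
    vectorized over all K^2 cells and a single-predictor standardized linear
    model of a on b is fitted. Returns an
    :class:`~trinet.effectstats.EffectEstimate`.
    """
    from .effectstats import standardized_coef

    if tm_a.K != tm_b.K:
        raise ValidationError("transition matrices must have equal K")
    pb = tm_b.probabilities
    if permutation is not None:
        permutation = np.asarray(permutation, dtype=int)
        pb = pb[np.ix_(permutation, permutation)]
    va = tm_a.probabilities.ravel()
    vb = pb.ravel()
    if va.std() == 0 or vb.std() == 0:
        raise UndefinedEffectError("degenerate (zero-variance) transition vector")
    return standardized_coef(va, vb, names=["transition_b"])[0]
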