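"""Synthetic data with planted ground truth.

Every estimator in the toolkit has a matching generator here, so parameter
recovery can be tested end-to-end without downloading imaging or expression
databases:

* fMRI runs in which K spatial states evolve under a known Markov chain and
  are observed through Gaussian noise (``simulate_run``);
* motion traces with planted displacement spikes (``simulate_motion``);
* paired mouse/human expression panels sharing latent spatial components
  (``make_gene_panels``);
* tracer-volume sets with a planted input-similarity block structure
  (``make_tracer_set``).

Species presets mirror the acquisition geometry of the study systems
(mouse: TR 1 s, 360 frames, FD cutoff 0.2 mm; human: TR 0.78 s, 900 frames,
0.5 mm; macaque: TR 2.28 s, 1600 frames, 0.5 mm), so retention behaviour can
be explored at realistic run shapes.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import MotionTrace, Parcellation, TimeSeriesVolume, VolumeGrid
from .errors import CapacityError, ValidationError
from .humanize import ExpressionPanel

__all__ = [
    "SPECIES_PRESETS",
    "StateGroundTruth",
    "PanelGroundTruth",
    "TracerSet",
    "TracerGroundTruth",
    "make_atlas",
    "random_transition_matrix",
    "simulate_markov_sequence",
    "simulate_run",
    "normalized_state_maps",
    "simulate_motion",
    "make_gene_panels",
    "make_tracer_set",
    "network_seed_masks",
    "default_state_dataset",
]

#: Acquisition presets per species: repetition time, run length, FD cutoff,
#: and head-radius lever arm used in the framewise-displacement formula.
SPECIES_PRESETS = {
    "mouse": {"tr_seconds": 1.0, "n_frames": 360, "fd_threshold_mm": 0.2, "radius_mm": 5.0},
    "human": {"tr_seconds": 0.78, "n_frames": 900, "fd_threshold_mm": 0.5, "radius_mm": 50.0},
    "macaque": {"tr_seconds": 2.28, "n_frames": 1600, "fd_threshold_mm": 0.5, "radius_mm": 25.0},
}


@dataclass
class StateGroundTruth:
    """Planted brain-state structure behind a set of synthetic runs."""

    patterns: np.ndarray  # (K, n_regions) region-level amplitudes
    transition_true: np.ndarray  # (K, K) row-stochastic
    sequences: dict = field(default_factory=dict)  # run id -> per-frame state (1..K)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.transition_true = np.asarray(self.transition_true, dtype=float)
        _check_stochastic(self.transition_true)

    @property
    def n_states(self) -> int:
        return self.patterns.shape[0]


@dataclass
class PanelGroundTruth:
    """Latent structure shared by a mouse/human expression-panel pair."""

    mouse_factors: np.ndarray  # (n_mouse_locations, n_factors)
    human_factors: np.ndarray  # (n_human_locations, n_factors)
    loading_matrix: np.ndarray  # (n_genes, n_factors)
    matched_map_pairs: list  # [(mouse map, human map), ...] in the shared latent span


@dataclass
class TracerSet:
    """N tracer-density volumes on one grid plus injection metadata."""

    volumes: np.ndarray  # (N, x, y, z) non-negative densities
    injection_meta: pd.DataFrame  # experiment_id, hemisphere, x, y, z

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ValidationError("tracer volumes must be (N, x, y, z)")
        if len(self.injection_meta) != self.volumes.shape[0]:
            raise ValidationError("injection metadata rows must match number of volumes")
        if self.volumes.min() < 0:
            raise ValidationError("tracer densities must be non-negative")

    @property
    def n_experiments(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]


@dataclass
class TracerGroundTruth:
    """Planted network structure of a synthetic tracer set."""

    voxel_labels: np.ndarray  # (x, y, z) network id 1..n, 0 background
    experiment_networks: np.ndarray  # per-experiment network id


def _check_stochastic(matrix: np.ndarray) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("transition matrix must be square")
    if matrix.min() < 0 or not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("transition matrix rows must be non-negative and sum to 1")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Atlas


def make_atlas(n_regions: int, grid_shape: Sequence[int], seed: int = 0,
               atlas_id: Optional[str] = None) -> Parcellation:
    """Partition a grid into ``n_regions`` contiguous, balanced raster blocks.

    Labels run 1..n_regions and every region is non-empty. Hemisphere is
    assigned from the region centroid relative to the x midline. The seed is
    accepted for API uniformity; the partition itself is deterministic.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    n_voxels = int(np.prod(grid_shape))
    if n_regions < 1 or n_regions > n_voxels:
        raise CapacityError(f"cannot fit {n_regions} regions into {n_voxels} voxels")
    bounds = np.linspace(0, n_voxels, n_regions + 1).round().astype(int)
    flat = np.zeros(n_voxels, dtype=np.int32)
    for r in range(n_regions):
        flat[bounds[r]:bounds[r + 1]] = r + 1
    labels = flat.reshape(grid_shape)
    xs = np.arange(grid_shape[0])[:, None, None] * np.ones(grid_shape)
    mid = (grid_shape[0] - 1) / 2.0
    rows = []
    for r in range(1, n_regions + 1):
        cx = xs[labels == r].mean()
        rows.append({"region_id": r, "name": f"region_{r:03d}",
                     "hemisphere": "left" if cx <= mid else "right"})
    table = pd.DataFrame(rows).set_index("region_id")
    return Parcellation(labels, table, atlas_id=atlas_id or f"synth{n_regions}")


# ---------------------------------------------------------------------------
# Markov states


def random_transition_matrix(n_states: int, seed: int = 0, persistence: float = 0.5,
                             balanced: bool = True) -> np.ndarray:
    """A random row-stochastic matrix with a sticky diagonal.

    Each row is ``persistence`` on the diagonal plus ``(1 - persistence)``
    spread over a random stochastic draw, emulating the self-transition
    dominance typical of resting-state brain-state sequences. With
    ``balanced=True`` (default) the random part is made doubly stochastic by
    Sinkhorn balancing, so the chain's stationary occupancy is uniform —
    every planted state is expressed for a comparable share of the recording,
    as empirical brain states are. ``balanced=False`` draws Dirichlet(1) rows
    instead, which can produce strongly skewed occupancies.
    """
    if not 0 <= persistence < 1:
        raise ValidationError("persistence must be in [0, 1)")
    rng = _rng(seed)
    if balanced:
        off = rng.random((n_states, n_states)) + 0.05
        for _ in range(200):
            off /= off.sum(axis=1, keepdims=True)
            off /= off.sum(axis=0, keepdims=True)
        off /= off.sum(axis=1, keepdims=True)
    else:
        off = rng.dirichlet(np.ones(n_states), size=n_states)
    return persistence * np.eye(n_states) + (1 - persistence) * off


def simulate_markov_sequence(n_frames: int, transition_true: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sample a state sequence (values 1..K) from a Markov chain.

    The initial state is uniform; the walk is reproducible given the seed.
    """
    _check_stochastic(transition_true)
    transition_true = np.asarray(transition_true, dtype=float)
    k = transition_true.shape[0]
    rng = _rng(seed)
    cum = np.cumsum(transition_true, axis=1)
    seq = np.empty(n_frames, dtype=np.int64)
    state = rng.integers(k)
    u = rng.random(n_frames)
    for t in range(n_frames):
        seq[t] = state + 1
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, k - 1)  # guard against u == 1 rounding
    return seq


def simulate_run(atlas: Parcellation, ground_truth: StateGroundTruth, snr: float,
                 tr_seconds: float = 1.0, seed: int = 0, run_id: Optional[str] = None,
                 ar_coef: float = 0.0, n_frames: Optional[int] = None) -> TimeSeriesVolume:
    """Generate one fMRI run from planted states.

    Frame ``t`` is the region-level amplitude pattern of the state active at
    ``t``, broadcast to voxels, plus white Gaussian noise of standard
    deviation ``1 / snr`` (optionally AR(1)-smoothed in time with coefficient
    ``ar_coef``). Voxel time series are z-scored on output, matching the
    normalization under which co-activation patterns are clustered.

    The realized state sequence is stored in ``ground_truth.sequences`` under
    ``run_id``.
    """
    if snr <= 0:
        raise ValidationError("snr must be positive")
    k, n_regions = ground_truth.patterns.shape
    if n_regions != atlas.n_regions:
        raise ValidationError("patterns must be defined on the atlas regions")
    rng = _rng(seed)
    if n_frames is None:
        n_frames = 360
    seq = simulate_markov_sequence(n_frames, ground_truth.transition_true,
                                   seed=rng.integers(2**31))
    run_id = run_id or f"run{seed}"
    ground_truth.sequences[run_id] = seq

    signal = _signal_frames(atlas, ground_truth.patterns, seq)  # (t, voxels)
    if np.isfinite(snr):
        noise = rng.standard_normal(signal.shape) / snr
        if ar_coef:
            for t in range(1, noise.shape[0]):
                noise[t] = ar_coef * noise[t - 1] + np.sqrt(1 - ar_coef**2) * noise[t]
        signal = signal + noise
    signal = _zscore_columns(signal)
    frames = signal.T.reshape(atlas.labels.shape + (n_frames,))
    return TimeSeriesVolume(frames, tr_seconds=tr_seconds, mask=atlas.labels > 0)


def _signal_frames(atlas: Parcellation, patterns: np.ndarray, seq: np.ndarray) -> np.ndarray:
    """Noiseless (t, voxels) signal for a state sequence."""
    voxel_patterns = np.zeros((patterns.shape[0], atlas.labels.size))
    flat = atlas.labels.ravel()
    for j, rid in enumerate(atlas.region_ids):
        voxel_patterns[:, flat == rid] = patterns[:, j][:, None]
    return voxel_patterns[seq - 1]


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def normalized_state_maps(atlas: Parcellation, ground_truth: StateGroundTruth,
                          sequences: Optional[Sequence[np.ndarray]] = None) -> np.ndarray:
    """Planted state patterns in the z-scored voxel space of the emitted runs.

    Because runs are z-scored per voxel, recovered centroids live in a
    per-voxel affine transform of the raw amplitude space. This helper applies
    the identical transform (using the realized state sequences, by default all
    sequences recorded in ``ground_truth``) to the noiseless patterns, so that
    in the noiseless limit each frame equals its transformed pattern exactly.

    Returns ``(K, n_voxels)`` over the full grid.
    """
    if sequences is None:
        sequences = list(ground_truth.sequences.values())
    if not sequences:
        raise ValidationError("no realized sequences available")
    seq = np.concatenate(list(sequences))
    voxel_patterns = _signal_frames(atlas, ground_truth.patterns,
                                    np.arange(1, ground_truth.n_states + 1))
    signal = voxel_patterns[seq - 1]
    mu = signal.mean(axis=0)
    sd = signal.std(axis=0)
    sd[sd == 0] = 1.0
    return (voxel_patterns - mu) / sd


# ---------------------------------------------------------------------------
# Motion


def simulate_motion(n_frames: int, spike_frames: Sequence[int] = (), spike_mm: float = 1.0,
                    seed: int = 0, jitter_mm: float = 0.01) -> tuple[MotionTrace, np.ndarray]:
    """White translation jitter plus planted displacement steps.

    At each frame in ``spike_frames`` the x translation steps by ``spike_mm``
    (and stays), producing a framewise-displacement excursion of at least
    ``spike_mm`` at exactly that frame. Returns the trace and the planted
    over-threshold frame set (sorted array of frame indices).
    """
    spike_frames = np.asarray(sorted(set(int(f) for f in spike_frames)), dtype=int)
    if spike_frames.size and (spike_frames.min() < 1 or spike_frames.max() >= n_frames):
        raise ValidationError("spike_frames must lie in [1, n_frames)")
    rng = _rng(seed)
    translations = rng.standard_normal((n_frames, 3)) * jitter_mm
    for f in spike_frames:
        translations[f:, 0] += spike_mm
    rotations = np.zeros((n_frames, 3))
    return MotionTrace(translations, rotations), spike_frames


# ---------------------------------------------------------------------------
# Expression panels


def make_gene_panels(n_genes: int, mouse_atlas: Parcellation, n_human_regions: int,
                     n_factors: int = 6, noise_sd: float = 0.0, seed: int = 0,
                     n_pairs: int = 6) -> tuple[ExpressionPanel, ExpressionPanel, PanelGroundTruth]:
    """Paired mouse/human expression panels sharing latent spatial components.

    Each species' expression matrix is ``factors @ loadings.T`` plus noise,
    with species-specific factor maps but one shared gene-loading matrix.
    Factors live in [0, 1] and loadings are positive; each species' factor
    matrix additionally contains a null-expression row and a full-expression
    row (calibration locations at which every gene attains its minimum 0 and
    maximum ``sum(loadings)``). Per-gene 0-1 normalization constants are
    therefore identical across species in the noiseless case, which makes
    translation of any latent-span map exact.

    ``n_pairs`` matched map pairs (mouse map, human twin) with a common latent
    coordinate are returned in the ground truth.
    """
    n_mouse = mouse_atlas.n_regions
    if n_factors >= min(n_genes, n_mouse, n_human_regions):
        raise ValidationError("n_factors must be smaller than both gene and location counts")
    if n_mouse < 3 or n_human_regions < 3:
        raise ValidationError("need at least 3 locations per species")
    rng = _rng(seed)

    def factors(n_loc: int) -> np.ndarray:
        f = rng.random((n_loc, n_factors))
        f[0] = 0.0  # null-expression calibration location
        f[1] = 1.0  # full-expression calibration location
        return f

    f_mouse = factors(n_mouse)
    f_human = factors(n_human_regions)
    loadings = rng.uniform(0.2, 1.0, size=(n_genes, n_factors))

    def panel(f: np.ndarray, species: str, ids) -> ExpressionPanel:
        x = f @ loadings.T
        if noise_sd > 0:
            x = x + rng.normal(scale=noise_sd, size=x.shape)
        return ExpressionPanel(
            matrix=x,
            gene_ids=[f"gene_{g:04d}" for g in range(n_genes)],
            species_tag=species,
            location_kind="region",
            location_ids=list(ids),
        )

    mouse_panel = panel(f_mouse, "mouse", mouse_atlas.region_ids)
    human_panel = panel(f_human, "human", range(1, n_human_regions + 1))

    pairs = []
    for _ in range(n_pairs):
        w = rng.standard_normal(n_factors)
        pairs.append((f_mouse @ w, f_human @ w))
    gt = PanelGroundTruth(f_mouse, f_human, loadings, pairs)
    return mouse_panel, human_panel, gt


# ---------------------------------------------------------------------------
# Tracer sets


def make_tracer_set(n_experiments: int, grid_shape: Sequence[int], n_networks: int,
                    seed: int = 0, noise_sd: float = 0.05) -> tuple[TracerSet, TracerGroundTruth]:
    """Tracer volumes with a planted block input-similarity structure.

    The grid is split along y into ``n_networks`` bilateral slabs (networks).
    Experiments are assigned to networks round-robin; each injection sits in
    the right-hemisphere half of its network's slab and deposits density of a
    random per-experiment amplitude over the whole bilateral slab, plus
    truncated Gaussian noise. A seed placed contralaterally (left hemisphere)
    inside a network slab then has a cross-experiment profile loading only on
    that network's experiments.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if n_experiments < n_networks:
        raise ValidationError("need at least one experiment per network")
    if grid_shape[1] < n_networks:
        raise CapacityError("grid too small for the requested number of networks")
    rng = _rng(seed)
    nx, ny, nz = grid_shape
    y_bounds = np.linspace(0, ny, n_networks + 1).round().astype(int)
    voxel_labels = np.zeros(grid_shape, dtype=np.int32)
    for n in range(n_networks):
        voxel_labels[:, y_bounds[n]:y_bounds[n + 1], :] = n + 1

    networks = np.arange(n_experiments) % n_networks + 1
    volumes = np.zeros((n_experiments,) + grid_shape)
    meta = []
    x_mid = nx // 2
    for i, net in enumerate(networks):
        amp = rng.uniform(0.5, 1.5)
        volumes[i][voxel_labels == net] = amp
        if noise_sd > 0:
            volumes[i] += rng.normal(scale=noise_sd, size=grid_shape)
        np.maximum(volumes[i], 0.0, out=volumes[i])
        inj_y = rng.integers(y_bounds[net - 1], y_bounds[net])
        meta.append({"experiment_id": f"exp_{i:03d}", "hemisphere": "right",
                     "x": int(rng.integers(x_mid, nx)), "y": int(inj_y),
                     "z": int(rng.integers(nz))})
    tracers = TracerSet(volumes, pd.DataFrame(meta))
    return tracers, TracerGroundTruth(voxel_labels, networks)


def network_seed_masks(ground_truth: TracerGroundTruth) -> dict[int, np.ndarray]:
    """Left-hemisphere (contralateral) seed mask per planted network."""
    labels = ground_truth.voxel_labels
    x_mid = labels.shape[0] // 2
    masks = {}
    for net in np.unique(labels[labels > 0]):
        mask = labels == net
        mask[x_mid:, :, :] = False
        masks[int(net)] = mask
    return masks


# ---------------------------------------------------------------------------
# Canonical study-scale dataset


def default_state_dataset(seed: int = 0, n_runs: int = 47, n_frames: int = 360,
                          n_states: int = 6, snr: float = 1.0,
                          grid_shape: Sequence[int] = (8, 8, 4), n_regions: int = 24,
                          tr_seconds: float = 1.0, persistence: float = 0.5,
                          fd_spike_fraction: float = 0.05, spike_mm: float = 1.0):
    """The canonical planted-state dataset used in recovery experiments.

    Defaults mirror the anesthetized-mouse study arm: 47 runs of 360 frames at
    TR 1 s, six planted states at SNR 1, with ~5% of frames carrying planted
    motion spikes well above the 0.2 mm scrubbing cutoff.

    Returns ``(atlas, ground_truth, runs)`` where each run carries its motion
    trace.
    """
    rng = _rng(seed)
    atlas = make_atlas(n_regions, grid_shape)
    # random orthogonal state directions: maximally distinct planted states,
    # scaled to unit per-region amplitude variance
    basis, _ = np.linalg.qr(rng.standard_normal((n_regions, n_states)))
    patterns = basis.T * np.sqrt(n_regions)
    transition = random_transition_matrix(n_states, seed=rng.integers(2**31),
                                          persistence=persistence)
    gt = StateGroundTruth(patterns, transition)
    runs = []
    for r in range(n_runs):
        run = simulate_run(atlas, gt, snr=snr, tr_seconds=tr_seconds,
                           seed=int(rng.integers(2**31)), run_id=f"run{r:02d}",
                           n_frames=n_frames)
        n_spikes = rng.binomial(n_frames, fd_spike_fraction)
        spikes = rng.choice(np.arange(1, n_frames), size=n_spikes, replace=False)
        run.motion, _ = simulate_motion(n_frames, spikes, spike_mm=spike_mm,
                                        seed=int(rng.integers(2**31)))
        runs.append(run)
    return atlas, gt, runs
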