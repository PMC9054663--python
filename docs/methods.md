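# Methods

This note documents the models and procedures implemented in `trinet`, the
assumptions behind them, the parameters that matter, and what the synthetic
data generator does and does not emulate.

## Co-activation-pattern (CAP) brain states

### Frame selection

Resting-state volumes enter the state analysis only if they pass two screens:

1. **Seed activity.** The mean time course of each seed region is z-scored
   over the run; a frame passes if *any* seed exceeds a threshold θ
   (default θ = 0). With three statistically independent seeds and θ = 0 this
   retains 1 − 0.5³ = 87.5% of frames before motion scrubbing, consistent
   with retention levels reported for lightly anesthetized rodents. θ is a
   free parameter because published CAP analyses rarely state it; it is
   recorded in every selection output.
2. **Motion.** Framewise displacement (FD) is the Power
   sum-of-absolute-derivatives form,
   `fd(t) = Σ|Δtrans| + r·Σ|Δrot|`, with `fd(0) = 0` and a head-radius lever
   arm `r` converting radians to millimetres. Defaults follow head-size
   convention: 50 mm (human), 25 mm (macaque), 5 mm (mouse). A frame passes
   if FD is strictly below the species cutoff (0.5 mm human/macaque, 0.2 mm
   mouse).

Rejected frames carry a reason code (`seed-fail`, `fd-fail`, `both`), so the
codes partition the rejections exactly.

### Clustering and model selection

Retained frames from all runs are pooled in masked-voxel space and clustered
with squared-Euclidean K-means (20 restarts, fixed seed). Each CAP is a
cluster centroid, recomputed as the exact mean of its member frames.

The clustering dimension K is selected by consensus clustering: for each
candidate K, K-means is repeated on random subsamples of 80% of frames
(default 40 subsamples); the consensus index of a frame pair is the fraction
of co-occurring subsamples in which the pair co-clusters, and the
**percentage of ambiguously clustered pairs (PAC)** is the fraction of pairs
whose consensus lies strictly inside (0.1, 0.9). The best K minimizes PAC.
Two numerical choices matter:

- **Single-initialization K-means inside the consensus loop.** Multi-restart
  K-means converges to the same local optimum on nearly every subsample,
  which makes even badly misspecified K look perfectly stable (PAC → 0 at
  K = 2 on six-cluster data). One random initialization per subsample lets
  subsample variability surface as partition variability, which is exactly
  the signal PAC measures. This follows the practice of the
  consensus-clustering literature. The 40-subsample default keeps the
  Monte-Carlo standard error of each PAC value well below the typical gap
  between neighbouring candidate K at moderate SNR; with ~20 subsamples that
  sampling noise is of the same order as the gap and the argmin becomes
  unreliable.
- **Frame cap.** The consensus matrix is quadratic in the number of frames;
  `max_frames` (default 2000, a deterministic seeded subsample) bounds the
  pair bookkeeping at study scale (≈14 000 retained frames for 47 × 360-frame
  runs). The PAC curve is insensitive to this cap well above ~1000 frames on
  the default synthetic data.

### Transition dynamics

Because every retained frame belongs to exactly one CAP, the label sequence
yields a K × K count matrix over consecutive frame pairs; a state repeated on
adjacent frames counts as a transition onto itself. Rows with nonzero counts
are normalized to probabilities. Two boundary conventions are deliberate:

- **Scrubbed gaps are not bridged** by default: a pair of retained frames
  whose original acquisition times are not adjacent is not a one-step
  transition. `count_across_gaps=True` restores pooled counting; which
  convention the original toolbox used is not documented, so both exist.
- **State entries** count the first frame of every retained contiguous
  segment plus every within-segment switch into the state. Without the
  segment-start rule, entry counts would be undefined at scrub boundaries.

Cross-dataset comparison first aligns states by optimal one-to-one assignment
(Hungarian algorithm) on spatial correlations in a common space, then
vectorizes both K² probability matrices and reports the standardized
linear-model coefficient of one on the other with a parametric 95% CI.

## Humanization of brain maps

A source-species (mouse) map `y` over locations is modeled as a linear
combination of 0–1-normalized gene-expression maps:
`y ≈ β₀ + X β`, where `X` is the locations × genes panel. The fitted β is
applied, gene by homologous gene, to the target species' normalized panel and
summed, giving a synthetic map on the target atlas. Agreement is Pearson
spatial correlation over atlas regions; matched state pairs are compared to
mismatched pairs by Cohen's d with a bootstrap CI.

Design choices where the procedure is genuinely open:

- **Intercept included.** State maps are z-scored around zero while
  normalized expression lives in [0, 1]; omitting the intercept would force
  spurious gene loadings.
- **Minimum-norm least squares** is the default solver. With thousands of
  genes on tens of regions the design is always rank-deficient; the
  minimum-norm solution is the most neutral choice and an optional ridge
  penalty (λ configurable) is surfaced rather than silently applied.
- Constant gene columns cannot be 0–1 normalized; they are flagged and
  excluded from fitting, and contribute nothing at projection time.
- Homolog matching is an upstream data-preparation concern: panels arrive
  with identical, identically ordered gene identifiers.

The exactness property the synthetic generator is built to exhibit: if the
target panel equals the source panel, projection returns the fitted values
identically; and if a map lies in the shared latent span of noiseless panels
whose per-gene normalization constants agree across species, the projected
map equals its target-species twin up to an additive constant (invisible to
correlation).

## Tracer input similarity

For N anterograde tracer volumes injected in one hemisphere, a contralateral
seed's **input profile** is its mean density per experiment. Correlating this
N-vector with every voxel's own cross-experiment profile (Pearson by default,
Spearman optional) maps territories receiving input from the same sources as
the seed. Voxels with zero density in every experiment are undefined (NaN),
not zero — zeros would imprint artificial background structure on the map.
Seeds whose voxel majority lies ipsilateral to the injections trigger a
warning.

Winner-take-all over several seeds' similarity maps yields a network
partition: a voxel is labeled by the seed with the highest similarity if that
value exceeds a threshold, ties going to the earlier seed in the supplied
order (flagged). Because tracer units are arbitrary per injection, an
optional per-experiment z-normalization of volumes is available; under it the
similarity map is exactly invariant to a positive affine rescaling of any
single experiment. The default correlates raw profiles.

Evoked-response maps are related to network maps by vectorizing within a mask
and fitting a multiple linear model with standardized coefficients and
parametric CIs. Cluster-corrected random-field thresholding is out of scope;
FDR and permutation-based cluster-extent correction are provided instead.

## Estimation statistics

Cohen's d uses the classic pooled-SD form (n − 1 weights); Hedges' correction
is optional. Bootstrap CIs are percentile with 5000 resamples by default
(seed mandatory), resampling within groups; BCa is available. A single-
predictor standardized coefficient equals the Pearson correlation, which
serves as an internal cross-check. Voxelwise two-sample t-tests support
Benjamini–Hochberg FDR or permutation cluster-extent correction.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure so every estimator has a
parameter-recovery test:

- **State runs.** K = 6 spatial states on a region atlas, evolving under a
  known row-stochastic chain, observed through white Gaussian noise of
  SD 1/snr and z-scored per voxel (as the clustering stage expects). Defaults
  mirror the anesthetized-mouse arm: 47 runs × 360 frames at TR 1 s, SNR 1,
  ~5% of frames carrying planted motion spikes of 1 mm against a 0.2 mm
  scrubbing cutoff. Planted patterns are random *orthogonal* directions —
  maximally distinct states, the structure the recovery tests presuppose —
  and the default chain is sticky (0.5 self-transition) with a
  Sinkhorn-balanced off-diagonal part, so its stationary occupancy is
  uniform: every planted state is expressed for a comparable share of the
  recording, as empirical brain states are. Skewed-occupancy chains remain
  available (`balanced=False`). Because runs are z-scored per voxel, planted
  patterns are exposed in that same space via `normalized_state_maps`, making
  the noiseless frame-equals-pattern identity exact.
- **Motion traces.** White translation jitter (0.01 mm) far below threshold,
  plus planted step displacements at known frames; scrubbing must recover
  exactly the planted set.
- **Expression panels.** Both species' panels are `factors @ loadings.T`
  (+ noise) with species-specific factor maps in [0, 1], one shared
  non-negative loading matrix, and two calibration locations per species (a
  null-expression and a full-expression row). Every raw gene column then
  attains minimum 0 and maximum Σ loadings in *both* species, so per-gene
  0–1 normalization constants agree across species, which is what makes
  noiseless humanization of latent-span maps exact. Default scale for
  recovery experiments: 150 genes, 30 mouse regions, 81 human regions,
  6 factors, 6 matched map pairs.
- **Tracer sets.** Networks are bilateral slabs; each experiment deposits a
  random-amplitude density over its network's slab (injection coordinates in
  the right-hemisphere half) plus truncated Gaussian noise, so a
  contralateral seed's profile loads only on its network's experiments.

Not emulated: hemodynamic convolution (an optional AR(1) temporal-smoothing
switch exists, off by default — CAP analysis treats frames as approximately
instantaneous), physiological/vascular noise structure, spatial noise
correlations, registration error, partial-volume effects, and realistic gene
coexpression structure. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to every
artifact of real acquisitions.

## Problem sizes used in the shipped experiments

The recovery experiments run at the study's acquisition shape for the state
analysis (47 × 360 frames, ≈14 000 retained frames) with a reduced spatial
grid (8 × 8 × 4 voxels, 24 regions) — spatial resolution is irrelevant to the
estimators once patterns are distinct, and region-level patterns make the
voxel dimension a pure broadcast. Panels are scaled to 150 genes over the
81-region human atlas (the full panel would be 3218 genes; the fit is
rank-limited by regions either way, so gene count does not change the
mathematics being tested). Tracer experiments use 48 injections over 3
planted networks on a 12 × 12 × 6 grid. The PAC consensus runs on a
2000-frame seeded subsample per candidate K, 40 subsamples, K ∈ {2..10}.

## Known limitations

- PAC selection is evaluated against planted, comparably occupied,
  orthogonal states; heavily imbalanced or correlated state geometries can
  legitimately shift the PAC minimum.
- The minimum-norm humanization fit is reported per map without uncertainty
  on β; only map-level correlations carry inference.
- The permutation cluster correction permutes group labels only (no
  sign-flipping one-sample variant).
- No spatial resampling: all inputs of one analysis must share a grid.
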