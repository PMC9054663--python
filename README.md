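# trinet

Tools for studying the brain's large-scale network organization across
species: co-activation-pattern (CAP) brain-state extraction from
resting-state fMRI with transition dynamics, transcriptomic "humanization" of
brain maps between species, and projection-input-similarity network mapping
from viral tracer volumes — together with a synthetic-data generator that
plants known ground truth for every stage, so the whole pipeline is testable
end-to-end without downloading any imaging database.

## What it computes

**Brain states.** Frames of a 4D run are screened by two criteria — z-scored
activity above a threshold θ in at least one seed region, and framewise
displacement `fd(t) = Σ|Δtrans| + r·Σ|Δrot|` below a species cutoff — then
pooled and clustered with K-means. Each CAP is a cluster centroid. The number
of states K is selected by consensus clustering over 80% frame subsamples,
minimizing the percentage of ambiguously clustered pairs (PAC): the fraction
of frame pairs whose co-clustering frequency lies strictly between 0.1 and
0.9. Because every retained frame has exactly one state, a row-stochastic
transition matrix `P(k→l)` and per-state entry counts follow from the label
sequence (a repeated state is a transition onto itself; scrubbed gaps are not
bridged). Datasets are compared by optimally matching states (Hungarian
assignment on spatial correlations) and regressing one vectorized transition
matrix on the other (standardized coefficient, 95% CI).

**Humanization.** A mouse state map `y` is fitted as
`y ≈ β₀ + X_mouse β` on a 0–1-normalized locations × genes expression panel;
β is applied to the homolog-matched human panel, `ŷ_human = β₀ + X_human β`,
yielding a synthetic map on the human atlas. Validation compares matched
vs. mismatched state pairs by spatial correlation and Cohen's d.

**Tracer input similarity.** For N right-hemisphere tracer injections, a
contralateral seed's input profile is its mean density per experiment;
correlating that N-vector with every voxel's cross-experiment profile maps
territories that receive input from the same sources as the seed.
Winner-take-all across seed maps partitions voxels into networks, and evoked
response maps are regressed on network maps with standardized coefficients.

**Estimation statistics.** Cohen's d (pooled SD) with bootstrap percentile
(or BCa) confidence intervals, standardized linear-model coefficients, and
voxelwise group tests with FDR or permutation cluster correction.

## Worked example

Six orthogonal spatial states evolving under a sticky Markov chain, observed
through noise at SNR 1 across 8 runs of 360 frames, are recovered from
scratch:

```python
import numpy as np
from trinet import caps, synthetic

atlas, truth, runs = synthetic.default_state_dataset(seed=1, n_runs=8)
seeds = [atlas.labels == r for r in (1, 2, 3)]
sels = [caps.select_frames(run, seeds, seed_threshold_z=0.0,
                           fd_mm=caps.framewise_displacement(run.motion, 5.0),
                           fd_threshold_mm=0.2) for run in runs]
print(f"retention {np.mean([s.retention_fraction for s in sels]):.3f}")

x, info = caps.stack_retained_frames(runs, sels)
model = caps.fit_caps(x, K=6, seed=0)
planted = synthetic.normalized_state_maps(atlas, truth)[:, atlas.labels.ravel() > 0]
perm, corrs = caps.match_states(model.centroids, planted)
print("matched centroid correlations", np.round(corrs, 4))
```

prints

```
retention 0.772
matched centroid correlations [0.9817 0.9783 0.9846 0.9822 0.966  0.9725]
```

— 77% of frames survive the two screens (three pure-noise seeds at θ = 0
would retain 1 − 0.5³ = 87.5%; here the seed regions also carry state
signal, and planted 1 mm motion spikes remove a few percent more, consistent
with retention levels reported for lightly anesthetized rodents), and every
recovered centroid correlates > 0.96 with the state that generated it.

The same stages are available from the shell:

```sh
trinet simulate --kind fmri --species mouse --seed 3 --out-dir data/
trinet select --func data/run00.nii.gz --motion data/run00_motion.tsv \
      --atlas data/atlas.nii.gz --atlas-table data/atlas.tsv \
      --out data/run00_selection.tsv
trinet caps --data-dir data/ --k 6 --out-dir caps/
trinet pac --data-dir data/ --out pac.json
trinet transitions --assignments caps/assignments.tsv --k 6 --out-dir tm/
```

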