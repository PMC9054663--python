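"""Cross-species brain-map translation through shared gene-expression panels.

A brain map measured in a source species (e.g. a mouse co-activation-pattern
map) is modeled as a linear combination of that species' gene-expression maps:

    map(location) ~ intercept + sum_g beta_g * expression_g(location)

after every gene has been 0-1 normalized to absorb amplitude differences. The
fitted per-gene coefficients are then applied, gene by homologous gene, to the
target species' expression panel and summed, yielding a "synthetic" map in the
target species' coordinate frame. Agreement is quantified by Pearson spatial
correlation over atlas regions, comparing matched against mismatched state
pairs.

With thousands of genes on a few dozen regions the design is necessarily
rank-deficient; the default solver is minimum-norm least squares, with an
optional ridge penalty. The regression includes an intercept because state
maps are centered around zero while normalized expression lives in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_io import RegionVector
from .errors import AlignmentError, UndefinedEffectError, ValidationError

__all__ = [
    "ExpressionPanel",
    "GeneWeights",
    "SyntheticMap",
    "normalize_panel",
    "fit_gene_weights",
    "project_to_target",
    "spatial_correlation",
    "matched_vs_mismatched",
    "humanize_map",
]


@dataclass
class ExpressionPanel:
    """Locations x genes expression matrix for one species.

    ``gene_ids`` must be unique and are shared (same order) with the homolog
    panel of the other species. ``excluded`` flags genes unusable for fitting
    (constant columns after normalization).
    """

    matrix: np.ndarray
    gene_ids: Sequence[str]
    species_tag: str = ""
    normalized: bool = False
    location_kind: str = "region"  # "voxel" | "region"
    location_ids: Optional[Sequence] = None
    excluded: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("panel matrix must be locations x genes")
        self.gene_ids = list(self.gene_ids)
        if len(self.gene_ids) != self.matrix.shape[1]:
            raise ValidationError("gene_ids length must match the number of columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids must be unique")
        if self.location_ids is None:
            self.location_ids = list(range(self.matrix.shape[0]))
        else:
            self.location_ids = list(self.location_ids)
            if len(self.location_ids) != self.matrix.shape[0]:
                raise ValidationError("location_ids length must match the number of rows")
        if self.excluded is None:
            self.excluded = np.zeros(self.matrix.shape[1], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)

    @property
    def n_locations(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.location_ids, columns=self.gene_ids)


@dataclass
class GeneWeights:
    """Per-gene coefficients of a fitted source map."""

    beta: np.ndarray
    intercept: float
    gene_ids: Sequence[str]
    excluded: np.ndarray
    residual_variance: float
    effective_rank: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape[0] != len(self.gene_ids):
            raise ValidationError("beta must have one coefficient per gene")


@dataclass
class SyntheticMap:
    """A source-species map re-expressed on the target species' locations."""

    values: np.ndarray
    location_ids: Sequence
    source_state_id: Optional[Union[int, str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_region_vector(self, atlas_id: str = "target") -> RegionVector:
        return RegionVector(pd.Series(self.values, index=list(self.location_ids)),
                            atlas_id=atlas_id)


# ---------------------------------------------------------------------------


def normalize_panel(panel: ExpressionPanel) -> ExpressionPanel:
    """0-1 normalize every gene column: ``(x - min) / (max - min)``.

    Constant columns cannot be scaled; they are set to zero and flagged in
    ``excluded`` so downstream fits ignore them.
    """
    if panel.normalized:
        raise ValidationError("panel is already normalized")
    x = panel.matrix
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    constant = rng == 0
    safe = np.where(constant, 1.0, rng)
    out = (x - lo) / safe
    out[:, constant] = 0.0
    return ExpressionPanel(out, panel.gene_ids, species_tag=panel.species_tag,
                           normalized=True, location_kind=panel.location_kind,
                           location_ids=panel.location_ids,
                           excluded=panel.excluded | constant)


def _as_values(map_values) -> np.ndarray:
    if isinstance(map_values, RegionVector):
        return map_values.to_array()
    return np.asarray(map_values, dtype=float).ravel()


def fit_gene_weights(map_values, panel: ExpressionPanel, ridge: float = 0.0) -> GeneWeights:
    """Least-squares fit of a source map on a normalized expression panel.

    Rank-deficient systems (genes > locations, collinear genes) are solved by
    minimum-norm least squares; ``ridge > 0`` switches to a ridge solution on
    centered data. Excluded (constant) genes get coefficient 0.
    """
    if not panel.normalized:
        raise ValidationError("panel must be normalized before fitting")
    y = _as_values(map_values)
    if y.shape[0] != panel.n_locations:
        raise AlignmentError(
            f"map has {y.shape[0]} locations but panel has {panel.n_locations}")
    keep = ~panel.excluded
    x = panel.matrix[:, keep]
    x_mean = x.mean(axis=0)
    y_mean = y.mean()
    xc = x - x_mean
    yc = y - y_mean
    if ridge > 0:
        gram = xc.T @ xc + ridge * np.eye(xc.shape[1])
        beta_k = np.linalg.solve(gram, xc.T @ yc)
        rank = int(np.linalg.matrix_rank(xc))
    else:
        beta_k, _, rank, _ = np.linalg.lstsq(xc, yc, rcond=None)
    resid = yc - xc @ beta_k
    dof = max(x.shape[0] - rank - 1, 1)
    beta = np.zeros(panel.n_genes)
    beta[keep] = beta_k
    intercept = float(y_mean - x_mean @ beta_k)
    return GeneWeights(beta, intercept, panel.gene_ids, panel.excluded.copy(),
                       residual_variance=float(resid @ resid) / dof,
                       effective_rank=int(rank))


def project_to_target(weights: GeneWeights, target_panel: ExpressionPanel,
                      source_state_id=None) -> SyntheticMap:
    """Apply fitted gene weights to the target species' normalized panel.

    Value at each target location is ``intercept + expression_row . beta``;
    genes excluded at fit time contribute nothing.
    """
    if not target_panel.normalized:
        raise ValidationError("target panel must be normalized")
    if list(weights.gene_ids) != list(target_panel.gene_ids):
        raise AlignmentError("gene identifiers (and their order) must match between panels")
    beta = np.where(weights.excluded, 0.0, weights.beta)
    values = weights.intercept + target_panel.matrix @ beta
    return SyntheticMap(values, target_panel.location_ids, source_state_id=source_state_id)


def humanize_map(map_values, source_panel: ExpressionPanel, target_panel: ExpressionPanel,
                 ridge: float = 0.0, source_state_id=None) -> SyntheticMap:
    """Fit on the source panel and project to the target panel in one step.

    Panels may be raw (they are then 0-1 normalized first) or pre-normalized.
    """
    src = source_panel if source_panel.normalized else normalize_panel(source_panel)
    tgt = target_panel if target_panel.normalized else normalize_panel(target_panel)
    weights = fit_gene_weights(map_values, src, ridge=ridge)
    return project_to_target(weights, tgt, source_state_id=source_state_id)


# ---------------------------------------------------------------------------


def spatial_correlation(map_a, map_b) -> float:
    """Pearson correlation over jointly defined (non-NaN) regions.

    Requires at least 3 shared defined regions and nonzero variance on both
    sides.
    """
    a = _as_values(map_a)
    b = _as_values(map_b)
    if a.shape != b.shape:
        raise AlignmentError("maps must be on the same atlas (equal length)")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValidationError("need at least 3 shared defined regions")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise UndefinedEffectError("correlation undefined for zero-variance map")
    return float(np.corrcoef(a, b)[0, 1])


def matched_vs_mismatched(synthetic_maps: Sequence, target_maps: Sequence,
                          n_boot: int = 5000, seed: int = 0):
    """Full K x K spatial-correlation matrix plus a matched-vs-mismatched effect.

    Entry ``(i, j)`` is the correlation of synthetic map ``i`` with target map
    ``j``; the effect size is Cohen's d of the diagonal (matched) cells against
    the off-diagonal (mismatched) cells, with a bootstrap percentile CI.

    Returns ``(corr_matrix, EffectEstimate)``.
    """
    from .effectstats import bootstrap_ci, cohens_d, EffectEstimate

    k = len(synthetic_maps)
    if len(target_maps) != k:
        raise ValidationError("need equally many synthetic and target maps")
    corr = np.empty((k, k))
    for i, s in enumerate(synthetic_maps):
        for j, t in enumerate(target_maps):
            corr[i, j] = spatial_correlation(s, t)
    matched = np.diag(corr)
    mismatched = corr[~np.eye(k, dtype=bool)]
    d = cohens_d(matched, mismatched)
    lo, hi, _ = bootstrap_ci(cohens_d, (matched, mismatched), n_boot=n_boot, seed=seed)
    est = EffectEstimate(estimate=d, ci_low=lo, ci_high=hi, method="pooled-d",
                         n_boot=n_boot, seed=seed)
    return corr, est
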