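"""Cross-species comparison of developmental expression timelines.

Two species' datasets are compared through an ortholog map: for every pair
of (source age, target age) the Spearman rank correlation of ortholog
expression profiles is computed per mapped region pair and averaged,
yielding a cross-correlation matrix whose high-correlation ridge traces the
developmental-time translation between the species.  Mapped region sets
(e.g. rhombomere 1 + isthmus vs cerebellar cortex) are averaged into a
single profile before comparison.  Region-specific specialization curves of
mapped regions are computed within each species' own dataset and emitted
side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionDataset, OrthologMap, ValidationError
from .region_analysis import region_specific_index

logger = logging.getLogger(__name__)

__all__ = [
    "RegionPairMap",
    "CrossCorrelationMatrix",
    "cross_correlation",
    "parallel_region_curves",
]

MIN_ORTHOLOGS = 10


@dataclass
class RegionPairMap:
    """List of (source region set, target region set) pairs; each set's
    members are averaged into one profile before comparison."""

    pairs: list[tuple[tuple[str, ...], tuple[str, ...]]]

    @classmethod
    def identity(cls, regions: Sequence[str]) -> "RegionPairMap":
        return cls([((r,), (r,)) for r in regions])

    @classmethod
    def from_dict(cls, mapping: dict) -> "RegionPairMap":
        pairs = []
        for src, tgt in mapping.items():
            src_set = (src,) if isinstance(src, str) else tuple(src)
            tgt_set = (tgt,) if isinstance(tgt, str) else tuple(tgt)
            pairs.append((src_set, tgt_set))
        return cls(pairs)

    def validate(self, source: ExpressionDataset, target: ExpressionDataset) -> None:
        for src_set, tgt_set in self.pairs:
            for r in src_set:
                if r not in source.regions:
                    raise ValidationError(f"source region {r!r} not in dataset")
            for r in tgt_set:
                if r not in target.regions:
                    raise ValidationError(f"target region {r!r} not in dataset")


@dataclass
class CrossCorrelationMatrix:
    """Source-age x target-age Spearman matrix plus provenance."""

    matrix: pd.DataFrame
    n_orthologs: int
    mapping: RegionPairMap = field(repr=False, default=None)

    def ridge(self) -> pd.Series:
        """Per-source-row argmax target age (the warp estimate)."""
        return self.matrix.idxmax(axis=1)


def _set_profile(ds: ExpressionDataset, members: Sequence[str],
                 gene_idx: np.ndarray, t_idx: int) -> np.ndarray:
    """Mean profile over a region set for the selected genes at one age."""
    r_idx = [ds.region_index(r) for r in members]
    block = ds.values[np.ix_(gene_idx, r_idx, [t_idx])][:, :, 0]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=1)


def cross_correlation(
    source: ExpressionDataset,
    target: ExpressionDataset,
    orthologs: OrthologMap,
    mapping: RegionPairMap | None = None,
    average: str = "pairwise",
) -> CrossCorrelationMatrix:
    """Spearman cross-correlation over all (source age, target age) pairs.

    For each age pair and each mapped region pair, member profiles are
    averaged per set, ortholog genes with missing values are dropped
    pairwise, and the Spearman rho across genes is computed (ties get
    average ranks).  ``average='pairwise'`` (default) averages rho over
    region pairs; ``average='profile'`` instead averages the mapped-set
    profiles over all region pairs first and computes one rho.
    """
    if mapping is None:
        common = [r for r in source.regions if r in target.regions]
        if not common:
            raise ValidationError("no common regions for an identity mapping")
        mapping = RegionPairMap.identity(common)
    mapping.validate(source, target)
    usable = orthologs.restrict(source.genes, target.genes)
    if len(usable) < MIN_ORTHOLOGS:
        raise ValidationError(
            f"only {len(usable)} usable ortholog pairs (< {MIN_ORTHOLOGS})")
    if average not in ("pairwise", "profile"):
        raise ValueError("average must be 'pairwise' or 'profile'")

    src_idx = np.array([source.gene_index(a) for a, _ in usable.pairs])
    tgt_idx = np.array([target.gene_index(b) for _, b in usable.pairs])

    out = np.full((source.n_timepoints, target.n_timepoints), np.nan)
    for ti, ts in enumerate(source.timepoints):
        for tj, tt in enumerate(target.timepoints):
            xs, ys = [], []
            rhos = []
            for src_set, tgt_set in mapping.pairs:
                x = _set_profile(source, src_set, src_idx, ti)
                y = _set_profile(target, tgt_set, tgt_idx, tj)
                ok = ~(np.isnan(x) | np.isnan(y))
                if average == "profile":
                    xs.append(np.where(ok, x, np.nan))
                    ys.append(np.where(ok, y, np.nan))
                    continue
                if ok.sum() < MIN_ORTHOLOGS:
                    continue
                rho = stats.spearmanr(x[ok], y[ok]).statistic
                if not np.isnan(rho):
                    rhos.append(rho)
            if average == "profile":
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    x = np.nanmean(np.stack(xs), axis=0)
                    y = np.nanmean(np.stack(ys), axis=0)
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() >= MIN_ORTHOLOGS:
                    out[ti, tj] = stats.spearmanr(x[ok], y[ok]).statistic
            elif rhos:
                out[ti, tj] = float(np.mean(rhos))
    matrix = pd.DataFrame(out, index=list(source.timepoints),
                          columns=list(target.timepoints))
    return CrossCorrelationMatrix(matrix, len(usable), mapping)


def _collapse(ds: ExpressionDataset, members: Sequence[str],
              name: str) -> ExpressionDataset:
    """Replace a set of regions by their average as one new region."""
    if len(members) == 1 and members[0] == name:
        return ds
    import warnings

    idx = [ds.region_index(r) for r in members]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        merged = np.nanmean(ds.values[:, idx, :], axis=1, keepdims=True)
    keep = [j for j, r in enumerate(ds.regions) if r not in set(members)]
    values = np.concatenate([ds.values[:, keep, :], merged], axis=1)
    regions = [ds.regions[j] for j in keep] + [name]
    return ExpressionDataset(list(ds.genes), regions, list(ds.timepoints),
                             values, ds.species)


def parallel_region_curves(
    source: ExpressionDataset,
    target: ExpressionDataset,
    mapping: RegionPairMap,
) -> dict[str, dict[str, pd.Series]]:
    """Side-by-side region-specific specialization curves for mapped regions.

    Each mapped set is collapsed to one averaged region within its own
    dataset, then the region-specific index is computed against that
    species' remaining regions.  Returns, per mapped pair, the source and
    target curves keyed by a readable pair name.
    """
    mapping.validate(source, target)
    out: dict[str, dict[str, pd.Series]] = {}
    for src_set, tgt_set in mapping.pairs:
        src_name = "+".join(src_set)
        tgt_name = "+".join(tgt_set)
        src_ds = _collapse(source, src_set, src_name)
        tgt_ds = _collapse(target, tgt_set, tgt_name)
        if src_ds.n_regions < 3 or tgt_ds.n_regions < 3:
            raise ValidationError(
                f"fewer than 3 regions remain for pair {src_name} ~ {tgt_name}")
        out[f"{src_name}~{tgt_name}"] = {
            "source": region_specific_index(src_ds, src_name),
            "target": region_specific_index(tgt_ds, tgt_name),
        }
    return out
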