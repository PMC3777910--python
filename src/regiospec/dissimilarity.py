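"""Inter-region dissimilarity: matrices, the hourglass curve and robustness.

A region at one age is a vector of expression densities over genes; the
dissimilarity between two regions is ``1 - PCC`` of those vectors (range
[0, 2]), computed over the genes observed in both regions.  The mean of all
pairwise dissimilarities per timepoint traces the developmental curve whose
U ("hourglass") shape is the central statistic, summarized per timepoint by
mean, median, quartiles and 1.5x-IQR whiskers.

Four robustness procedures probe the curve: random gene subsets, removal of
the most region-variable genes per timepoint, leave-one-region-out, and
re-aggregation of regions at coarser ontology levels.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionDataset, RegionOntology, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MIN_COMMON_GENES",
    "pairwise_dissimilarity",
    "dissimilarity_set",
    "pair_values",
    "curve",
    "fit_quadratic",
    "age_anova",
    "subset_robustness",
    "drop_top_variable",
    "leave_one_region_out",
    "ontology_level_curves",
]

#: minimum number of commonly observed genes for a region pair to be scored
MIN_COMMON_GENES = 3

CURVE_COLUMNS = ["mean", "median", "q1", "q3", "whisker_lo", "whisker_hi", "n_pairs"]


def _pair_dissim(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson r over commonly observed entries; NaN if unscorable."""
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < MIN_COMMON_GENES:
        return np.nan
    xs, ys = x[mask], y[mask]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0.0 or vy == 0.0:
        return np.nan
    return 1.0 - (xc @ yc) / np.sqrt(vx * vy)


def _matrix_from_slice(m: np.ndarray) -> np.ndarray:
    """Symmetric region x region dissimilarity matrix from a gene x region
    slice (NaN = missing).  Fast path: no missing data -> one corrcoef call."""
    n = m.shape[1]
    out = np.zeros((n, n))
    if not np.isnan(m).any():
        sd = m.std(axis=0)
        ok = sd > 0
        corr = np.full((n, n), np.nan)
        if ok.sum() >= 2:
            corr_ok = np.corrcoef(m[:, ok].T)
            corr[np.ix_(ok, ok)] = corr_ok
        out = 1.0 - corr
        out[~ok, :] = np.nan
        out[:, ~ok] = np.nan
        if m.shape[0] < MIN_COMMON_GENES:
            out[:] = np.nan
        np.fill_diagonal(out, 0.0)
        return out
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _pair_dissim(m[:, i], m[:, j])
    np.fill_diagonal(out, 0.0)
    return out


def pairwise_dissimilarity(dataset: ExpressionDataset, timepoint: str) -> pd.DataFrame:
    """Region x region ``1 - PCC`` matrix at one timepoint.

    Only regions with at least one observed gene at the timepoint appear.
    Pairs with fewer than :data:`MIN_COMMON_GENES` common genes, or with a
    zero-variance expression vector, are NaN.  Raises if fewer than two
    regions are present.
    """
    present = dataset.regions_present_at(timepoint)
    if len(present) < 2:
        raise ValidationError(
            f"fewer than 2 regions present at timepoint {timepoint!r}")
    idx = [dataset.region_index(r) for r in present]
    m = dataset.matrix_at(timepoint)[:, idx]
    return pd.DataFrame(_matrix_from_slice(m), index=present, columns=present)


def dissimilarity_set(dataset: ExpressionDataset) -> dict[str, pd.DataFrame]:
    """Per-timepoint dissimilarity matrices; timepoints with <2 regions are
    skipped with a logged warning."""
    out: dict[str, pd.DataFrame] = {}
    for t in dataset.timepoints:
        try:
            out[t] = pairwise_dissimilarity(dataset, t)
        except ValidationError as exc:
            logger.warning("timepoint %s skipped: %s", t, exc)
    return out


def pair_values(matrix: pd.DataFrame) -> np.ndarray:
    """Non-missing upper-triangle values of a dissimilarity matrix."""
    a = matrix.to_numpy()
    iu = np.triu_indices(a.shape[0], k=1)
    vals = a[iu]
    return vals[~np.isnan(vals)]


def _summarize(vals: np.ndarray) -> list[float]:
    if vals.size == 0:
        return [np.nan] * 6 + [0]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo = vals[vals >= q1 - 1.5 * iqr].min()
    hi = vals[vals <= q3 + 1.5 * iqr].max()
    return [vals.mean(), med, q1, q3, lo, hi, int(vals.size)]


def curve(dataset: ExpressionDataset) -> pd.DataFrame:
    """Hourglass curve: per-timepoint summary of all pairwise dissimilarities.

    Returns a frame indexed by timepoint with columns
    ``mean, median, q1, q3, whisker_lo, whisker_hi, n_pairs``.  A timepoint
    with no valid pairs gets NaN summaries and ``n_pairs = 0``.
    """
    if dataset.n_timepoints < 2:
        raise ValidationError("need at least 2 timepoints for a curve")
    rows = []
    for t in dataset.timepoints:
        try:
            vals = pair_values(pairwise_dissimilarity(dataset, t))
        except ValidationError:
            vals = np.array([])
        rows.append(_summarize(vals))
    return pd.DataFrame(rows, index=list(dataset.timepoints), columns=CURVE_COLUMNS)


def fit_quadratic(curve_summary: pd.DataFrame) -> tuple[float, float, float]:
    """OLS quadratic through (timepoint rank, mean dissimilarity).

    Ranks are 0, 1, 2, ... in declared developmental order (the age axis is
    treated as categorical spacing).  Returns ``(a2, a1, a0)`` of
    ``a2*x^2 + a1*x + a0``.
    """
    means = curve_summary["mean"].to_numpy(dtype=float)
    x = np.arange(len(means), dtype=float)
    ok = ~np.isnan(means)
    if ok.sum() < 3:
        raise ValidationError("need >= 3 non-missing curve points for a quadratic")
    a2, a1, a0 = np.polyfit(x[ok], means[ok], 2)
    return float(a2), float(a1), float(a0)


def age_anova(dissim: dict[str, pd.DataFrame]) -> float:
    """One-way ANOVA p-value: groups = timepoints, observations = pairwise
    dissimilarities.  Degenerate case of zero between-group variation
    returns p = 1 (F = 0)."""
    groups = [pair_values(m) for m in dissim.values()]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValidationError("need >= 2 timepoints with >= 2 pair values each")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    if ss_between == 0.0:
        return 1.0
    return float(stats.f_oneway(*groups).pvalue)


def subset_robustness(
    dataset: ExpressionDataset,
    sizes: Sequence[int],
    n_subsets: int = 100,
    seed: int = 0,
) -> dict[int, list[pd.DataFrame]]:
    """Curves on random gene subsets (without replacement), per subset size.

    Emulates the check that the hourglass shape is not driven by a
    particular set of genes.  Deterministic given the seed.
    """
    for size in sizes:
        if size > dataset.n_genes:
            raise ValidationError(f"subset size {size} > n_genes {dataset.n_genes}")
        if size < 1:
            raise ValidationError("subset size must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[int, list[pd.DataFrame]] = {}
    genes = np.array(dataset.genes)
    for size in sizes:
        fam = []
        for _ in range(n_subsets):
            chosen = rng.choice(genes, size=size, replace=False)
            fam.append(curve(dataset.subset_genes(list(chosen))))
        out[int(size)] = fam
    return out


def drop_top_variable(
    dataset: ExpressionDataset, k_list: Sequence[int]
) -> dict[int, pd.DataFrame]:
    """Curves after removing, per timepoint, the k genes with the highest
    across-region standard deviation at that timepoint.

    The removal set is recomputed at every timepoint, so different genes may
    be dropped at different ages.  SD is computed on raw densities over the
    regions where the gene is observed (sample SD, ddof=1).
    """
    for k in k_list:
        if k >= dataset.n_genes:
            raise ValidationError(f"k={k} must be < n_genes={dataset.n_genes}")
        if k < 0:
            raise ValidationError("k must be >= 0")
    out: dict[int, pd.DataFrame] = {}
    for k in k_list:
        rows = []
        for t in dataset.timepoints:
            m = dataset.matrix_at(t)
            if k > 0:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    sd = np.nanstd(m, axis=1, ddof=1)
                sd = np.where(np.isnan(sd), -np.inf, sd)
                drop = set(np.argsort(-sd, kind="stable")[:k])
                keep = [g for i, g in enumerate(dataset.genes) if i not in drop]
            else:
                keep = list(dataset.genes)
            sub = dataset.subset_genes(keep)
            try:
                vals = pair_values(pairwise_dissimilarity(sub, t))
            except ValidationError:
                vals = np.array([])
            rows.append(_summarize(vals))
        out[int(k)] = pd.DataFrame(rows, index=list(dataset.timepoints),
                                   columns=CURVE_COLUMNS)
    return out


def leave_one_region_out(
    dataset: ExpressionDataset,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """One curve per excluded region, plus the per-timepoint mean/SD envelope
    of the excluded-region curve means."""
    if dataset.n_regions < 3:
        raise ValidationError("need >= 3 regions to leave one out")
    curves = {r: curve(dataset.drop_regions([r])) for r in dataset.regions}
    means = pd.DataFrame({r: c["mean"] for r, c in curves.items()})
    envelope = pd.DataFrame({
        "mean": means.mean(axis=1),
        "sd": means.std(axis=1, ddof=1),
    })
    return curves, envelope


def ontology_level_curves(
    dataset: ExpressionDataset,
    ontology: RegionOntology,
    n_levels: int,
) -> dict[int, pd.DataFrame]:
    """Curves with regions re-aggregated at successive ontology levels.

    A level-l parent region's profile is the unweighted mean of its
    constituent leaf profiles per gene and timepoint (NaN-aware).  Leaves
    without expression data are excluded with a warning.
    """
    leaves_with_data = [l for l in ontology.leaves if l in dataset.regions]
    skipped = [l for l in ontology.leaves if l not in dataset.regions]
    if skipped:
        logger.warning("ontology leaves without expression data excluded: %s",
                       skipped)
    if len(leaves_with_data) < 2:
        raise ValidationError("fewer than 2 ontology leaves have expression data")
    out: dict[int, pd.DataFrame] = {}
    for level in range(1, n_levels + 1):
        groups = ontology.level_cut(level)
        agg_regions = []
        cols = []
        for parent, members in groups.items():
            members = [m for m in members if m in dataset.regions]
            if not members:
                continue
            idx = [dataset.region_index(m) for m in members]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                prof = np.nanmean(dataset.values[:, idx, :], axis=1)
            agg_regions.append(parent)
            cols.append(prof)
        values = np.stack(cols, axis=1)
        agg = ExpressionDataset(list(dataset.genes), agg_regions,
                                list(dataset.timepoints), values,
                                dataset.species)
        out[level] = curve(agg)
    return out
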