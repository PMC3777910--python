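"""Region-level specialization: indices, NMDS embeddings, lineage correlation.

The *region-specific index* of region R at age t is its mean dissimilarity to
all other regions divided by the overall mean inter-region dissimilarity at
that age — values above 1 mark regions more specialized than the brain-wide
average (the postnatal cerebellum being the canonical case).

Embeddings use non-metric MDS (Kruskal stress-1 minimized by iterative
majorization with monotone regression of distances on dissimilarities), with
one classical-scaling start plus seeded random restarts.  Successive
timepoint configurations are aligned with Procrustes (translation +
rotation/reflection + isotropic scaling).  The lineage analysis correlates
inter-region dissimilarity with the path distance between the regions'
embryonic origins on a fixed four-leaf vesicle tree (telencephalon and
diencephalon under forebrain; midbrain; hindbrain under the root).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .io_core import ExpressionDataset, RegionOntology, ValidationError
from .dissimilarity import pairwise_dissimilarity, pair_values

logger = logging.getLogger(__name__)

__all__ = [
    "region_specific_index",
    "nmds_embed",
    "procrustes_align",
    "within_region_sd",
    "lineage_tree_distance",
    "lineage_distance_correlation",
    "region_gene_contributions",
    "embed_timepoints",
]

# fixed embryonic lineage tree with unit branch lengths:
#   root -- forebrain -- telencephalon / diencephalon; root -- midbrain;
#   root -- hindbrain.  Path lengths between origin leaves:
_LINEAGE_PATH = {
    ("forebrain-telencephalon", "forebrain-diencephalon"): 2,
    ("forebrain-telencephalon", "midbrain"): 3,
    ("forebrain-telencephalon", "hindbrain"): 3,
    ("forebrain-diencephalon", "midbrain"): 3,
    ("forebrain-diencephalon", "hindbrain"): 3,
    ("midbrain", "hindbrain"): 2,
}


def lineage_tree_distance(origin_a: str, origin_b: str) -> int:
    """Edge-path length between two embryonic origins (0 for same origin)."""
    if origin_a == origin_b:
        return 0
    key = (origin_a, origin_b) if (origin_a, origin_b) in _LINEAGE_PATH \
        else (origin_b, origin_a)
    try:
        return _LINEAGE_PATH[key]
    except KeyError:
        raise KeyError(f"unknown origin pair ({origin_a!r}, {origin_b!r})") from None


# ---------------------------------------------------------------------------
# Region-specific index
# ---------------------------------------------------------------------------

def region_specific_index(dataset: ExpressionDataset, region: str) -> pd.Series:
    """Per-timepoint specialization index of one region.

    index(t) = mean_{R' != R} d(R, R') / Dbar(t).  Timepoints where the
    region is absent are NaN; a timepoint with Dbar(t) = 0 is an error.
    """
    if region not in dataset.regions:
        raise KeyError(f"unknown region {region!r}")
    out = pd.Series(np.nan, index=list(dataset.timepoints), name=region)
    for t in dataset.timepoints:
        try:
            mat = pairwise_dissimilarity(dataset, t)
        except ValidationError:
            continue
        if region not in mat.index:
            continue
        others = [r for r in mat.index if r != region]
        if len(others) < 2:
            continue
        row = mat.loc[region, others].to_numpy(dtype=float)
        row = row[~np.isnan(row)]
        allvals = pair_values(mat)
        if allvals.size == 0 or row.size == 0:
            continue
        dbar = allvals.mean()
        if dbar == 0.0:
            raise ValidationError(f"overall mean dissimilarity is 0 at {t!r}; "
                                  "region index undefined")
        out[t] = row.mean() / dbar
    return out


# ---------------------------------------------------------------------------
# Non-metric MDS
# ---------------------------------------------------------------------------

def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = np.sum(dist**2)
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def _pair_dist(x: np.ndarray, iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    diff = x[iu[0]] - x[iu[1]]
    return np.sqrt((diff**2).sum(axis=1))


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson scaling: eigen-decomposition of the double-centered squared
    distance matrix; exact for Euclidean-realizable input."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def nmds_embed(
    d: np.ndarray | pd.DataFrame,
    dims: int = 2,
    seed: int = 0,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS minimizing Kruskal stress-1; returns (coords, stress).

    SMACOF-style iteration: monotone (isotonic) regression of configuration
    distances on the input dissimilarities gives disparities, followed by a
    Guttman transform.  One start is classical scaling (exact when the input
    is realizable in ``dims`` dimensions); the remaining starts are seeded
    random configurations.  Missing entries are imputed with the maximum
    observed dissimilarity; the best (lowest-stress) start is returned.
    """
    labels = None
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        d = d.to_numpy(dtype=float)
    d = np.asarray(d, dtype=float).copy()
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(np.nan_to_num(d), np.nan_to_num(d.T), atol=1e-12):
        raise ValidationError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(n, dtype=bool)
    if np.isnan(d[off]).any():
        fill = np.nanmax(d[off]) if not np.all(np.isnan(d[off])) else 1.0
        d[np.isnan(d)] = fill
        np.fill_diagonal(d, 0.0)

    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def run(x0: np.ndarray) -> tuple[np.ndarray, float]:
        x = x0.copy()
        last = np.inf
        stress = np.inf
        for _ in range(max_iter):
            dist = _pair_dist(x, iu)
            disp = iso.fit_transform(dvec, dist)
            stress = _stress1(dist, disp)
            if stress < 1e-12 or (last - stress) <= tol * max(last, 1e-30):
                break
            last = stress
            # Guttman transform with unit weights
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, disp / dist, 0.0)
            b = np.zeros((n, n))
            b[iu] = -ratio
            b += b.T
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
        return x, stress

    starts = [_classical_mds(d, dims)]
    scale = max(dvec.max(), 1.0) if dvec.size else 1.0
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(0.0, scale, size=(n, dims)))
    best_x, best_s = None, np.inf
    for x0 in starts:
        x, s = run(x0)
        if s < best_s:
            best_x, best_s = x, s
    coords = best_x - best_x.mean(axis=0)
    if labels is not None:
        coords = pd.DataFrame(coords, index=labels,
                              columns=[f"dim{i+1}" for i in range(dims)])
    return coords, best_s


# ---------------------------------------------------------------------------
# Procrustes alignment
# ---------------------------------------------------------------------------

def procrustes_align(
    reference: np.ndarray | pd.DataFrame,
    coords: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray | pd.DataFrame, float]:
    """Align ``coords`` to ``reference`` by translation + orthogonal
    transform (reflection allowed) + isotropic scaling.

    Returns the aligned configuration *in the reference's frame* and the
    disparity: the minimized sum of squared differences after both
    configurations are standardized to zero mean and unit Frobenius norm
    (the convention of the classical orthogonal Procrustes statistic).
    If the inputs are labelled frames, alignment uses the common regions.
    """
    ref_labels = out_labels = None
    if isinstance(reference, pd.DataFrame) and isinstance(coords, pd.DataFrame):
        common = [r for r in reference.index if r in coords.index]
        if len(common) < 2:
            raise ValidationError("need >= 2 common regions for alignment")
        ref_labels = common
        out_labels = common
        reference = reference.loc[common].to_numpy(dtype=float)
        coords = coords.loc[common].to_numpy(dtype=float)
    a = np.asarray(reference, dtype=float)
    b = np.asarray(coords, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("configurations must have identical shape")
    if a.shape[0] < 2:
        raise ValidationError("need >= 2 points for alignment")

    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - mu_a, b - mu_b
    na = np.linalg.norm(a0)
    nb = np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise ValidationError("degenerate (all-coincident) configuration")
    a0 /= na
    b0 /= nb
    u, s, vt = np.linalg.svd(b0.T @ a0)
    rot = u @ vt
    scale = s.sum()
    b_std = scale * (b0 @ rot)
    disparity = float(np.sum((a0 - b_std) ** 2))
    aligned = na * b_std + mu_a  # back to the reference frame
    if out_labels is not None:
        aligned = pd.DataFrame(aligned, index=out_labels,
                               columns=[f"dim{i+1}" for i in range(a.shape[1])])
    return aligned, disparity


# ---------------------------------------------------------------------------
# Within-region SD and lineage correlation
# ---------------------------------------------------------------------------

def within_region_sd(dataset: ExpressionDataset, region: str, timepoint: str) -> float:
    """Sample SD (ddof=1) of a region's expression values across genes at
    one timepoint (the marker size of the embedding plots)."""
    vals = dataset.matrix_at(timepoint)[:, dataset.region_index(region)]
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValidationError(
            f"region {region!r} has < 2 observed genes at {timepoint!r}")
    return float(np.std(vals, ddof=1))


def lineage_distance_correlation(
    dissim: Mapping[str, pd.DataFrame],
    ontology: RegionOntology,
) -> tuple[pd.Series, float]:
    """Pearson r between inter-region dissimilarity and embryonic tree
    distance, per timepoint, plus the mean over timepoints.

    Timepoints where either vector is constant (r undefined) are excluded
    with a warning.
    """
    per_tp = {}
    for t, mat in dissim.items():
        regions = list(mat.index)
        iu = np.triu_indices(len(regions), k=1)
        dvals = mat.to_numpy()[iu]
        tvals = np.array([
            lineage_tree_distance(ontology.origin_of(regions[i]),
                                  ontology.origin_of(regions[j]))
            for i, j in zip(*iu)], dtype=float)
        ok = ~np.isnan(dvals)
        if ok.sum() < 3 or np.ptp(tvals[ok]) == 0 or np.ptp(dvals[ok]) == 0:
            logger.warning("lineage correlation undefined at %s; excluded", t)
            continue
        per_tp[t] = float(stats.pearsonr(dvals[ok], tvals[ok]).statistic)
    if not per_tp:
        raise ValidationError("lineage correlation undefined at every timepoint")
    series = pd.Series(per_tp)
    return series, float(series.mean())


# ---------------------------------------------------------------------------
# Per-region gene contributions
# ---------------------------------------------------------------------------

def region_gene_contributions(
    dataset: ExpressionDataset,
    region: str,
    timepoint: str,
    top_n: int = 20,
) -> pd.DataFrame:
    """Genes ranked by their contribution to one region's dissimilarity.

    For each gene g, contribution = mean_{R' != R} d(R, R') minus the same
    mean recomputed on the gene-deleted dataset (honest recomputation).
    Returns the ``top_n`` genes, descending, with their values.
    """
    if dataset.n_genes < 3:
        raise ValidationError("need >= 3 genes")
    mat = pairwise_dissimilarity(dataset, timepoint)
    if region not in mat.index:
        raise ValidationError(f"region {region!r} absent at {timepoint!r}")

    def region_mean(m: pd.DataFrame) -> float:
        others = [r for r in m.index if r != region]
        row = m.loc[region, others].to_numpy(dtype=float)
        row = row[~np.isnan(row)]
        if row.size == 0:
            raise ValidationError(f"region {region!r} has no scorable pairs")
        return float(row.mean())

    full = region_mean(mat)
    rows = []
    for gene in dataset.genes:
        reduced = dataset.drop_genes([gene])
        rows.append((gene, full - region_mean(
            pairwise_dissimilarity(reduced, timepoint))))
    out = pd.DataFrame(rows, columns=["gene", "contribution"])
    out = out.sort_values("contribution", ascending=False, kind="stable")
    return out.head(top_n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Chained embedding across timepoints
# ---------------------------------------------------------------------------

def embed_timepoints(
    dataset: ExpressionDataset,
    dims: int = 2,
    seed: int = 0,
    n_starts: int = 10,
) -> dict[str, dict]:
    """NMDS embedding per timepoint, Procrustes-chained for visual
    continuity: the first age is the reference; each later age is aligned to
    the previous aligned configuration.  Marker sizes are the within-region
    expression SDs."""
    out: dict[str, dict] = {}
    prev: pd.DataFrame | None = None
    for i, t in enumerate(dataset.timepoints):
        try:
            mat = pairwise_dissimilarity(dataset, t)
        except ValidationError as exc:
            logger.warning("embedding skipped at %s: %s", t, exc)
            continue
        coords, stress = nmds_embed(mat, dims=dims, seed=seed + i,
                                    n_starts=n_starts)
        aligned_flag = False
        if prev is not None:
            try:
                coords, _ = procrustes_align(prev, coords)
                aligned_flag = True
            except ValidationError as exc:
                logger.warning("alignment failed at %s: %s", t, exc)
        sizes = {}
        for r in coords.index:
            try:
                sizes[r] = within_region_sd(dataset, r, t)
            except ValidationError:
                sizes[r] = np.nan
        out[t] = {"coords": coords, "stress": stress,
                  "aligned": aligned_flag, "marker_sd": pd.Series(sizes)}
        prev = coords
    return out
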