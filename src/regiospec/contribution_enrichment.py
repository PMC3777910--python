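"""Gene contribution profiles, clustering, GO enrichment with double FDR.

The contribution of gene *g* to regional specialization at age *t* is the
leave-one-out statistic

    dD_g(t) = Dbar(t) - Dbar_without_g(t)

where ``Dbar(t)`` is the mean pairwise inter-region dissimilarity and
``Dbar_without_g(t)`` the same quantity recomputed after deleting *g* from
the expression table.  A positive value means the gene increases inter-region
dissimilarity.  Both means are taken over the identical set of region pairs:
a pair that is scorable in the full data must remain scorable after the
deletion, otherwise the computation errors out rather than silently changing
the pair mask.

Profiles are clustered with k-means over a grid of k; each (cluster, GO
category) cell is tested with an upper-tail hypergeometric test; p-values get
a two-stage ("double") Benjamini-Hochberg correction — across all tests
within each clustering, then per category across the k grid — followed by a
GO-hierarchy screen that keeps only the most refined enriched categories.
Clusters are labelled embryonic/postnatal/neither with a two-sample rank
test on pooled contribution values.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionDataset, GeneAnnotation, ValidationError
from .dissimilarity import pairwise_dissimilarity, pair_values

logger = logging.getLogger(__name__)

__all__ = [
    "contribution_profiles",
    "cluster_profiles",
    "hypergeometric_enrichment",
    "double_fdr",
    "enriched_categories",
    "screen_hierarchy",
    "phase_assignment",
    "category_contribution_index",
    "DEFAULT_K_GRID",
]

#: k-means grid used in the reference analysis
DEFAULT_K_GRID = (10, 15, 20, 25, 30, 35, 40, 45, 50)


def _mean_dissim(dataset: ExpressionDataset, timepoint: str,
                 mask: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean pairwise dissimilarity at a timepoint and the validity mask of
    the upper-triangle pairs (for mask-consistency checks)."""
    m = pairwise_dissimilarity(dataset, timepoint).to_numpy()
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    valid = ~np.isnan(vals)
    if mask is not None:
        if valid.shape != mask.shape or not np.all(valid[mask]):
            raise ValidationError(
                f"region-pair mask changed after gene deletion at {timepoint!r}; "
                "a pair lost its minimum common genes or became constant")
        valid = mask
    if not valid.any():
        raise ValidationError(f"no valid region pairs at {timepoint!r}")
    return float(vals[valid].mean()), valid


def contribution_profiles(
    dataset: ExpressionDataset,
    timepoints: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Leave-one-gene-out contribution matrix (genes x timepoints).

    ``timepoints`` defaults to all dataset timepoints; pass the developmental
    subset to exclude an adult age from the profiles.  Every entry is an
    honest recomputation of the mean dissimilarity on the gene-deleted
    dataset (no incremental shortcuts), so it matches a brute-force oracle to
    machine precision.
    """
    if dataset.n_genes < 3:
        raise ValidationError("need >= 3 genes for leave-one-out contributions")
    tps = list(timepoints) if timepoints is not None else list(dataset.timepoints)
    ref: dict[str, tuple[float, np.ndarray]] = {}
    for t in tps:
        ref[t] = _mean_dissim(dataset, t)
    out = np.zeros((dataset.n_genes, len(tps)))
    for gi, gene in enumerate(dataset.genes):
        reduced = dataset.drop_genes([gene])
        for ti, t in enumerate(tps):
            dbar, mask = ref[t]
            dbar_wo, _ = _mean_dissim(reduced, t, mask=mask)
            out[gi, ti] = dbar - dbar_wo
    return pd.DataFrame(out, index=list(dataset.genes), columns=tps)


def cluster_profiles(
    profiles: pd.DataFrame,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    restarts: int = 10,
    seed: int = 0,
) -> dict[int, pd.Series]:
    """k-means over a grid of k on raw contribution profiles.

    For each k the best of ``restarts`` k-means++ initializations (lowest
    within-cluster sum of squares) is kept.  Deterministic given the seed.
    Returns per k a gene -> cluster-id Series.
    """
    if len(k_grid) == 0:
        raise ValidationError("empty k grid")
    for k in k_grid:
        if k > len(profiles):
            raise ValidationError(f"k={k} exceeds number of genes {len(profiles)}")
        if k < 1:
            raise ValidationError("k must be >= 1")
    x = profiles.to_numpy(dtype=float)
    out: dict[int, pd.Series] = {}
    for i, k in enumerate(k_grid):
        km = KMeans(n_clusters=int(k), n_init=restarts,
                    random_state=(seed + i) % (2**31), init="k-means++")
        labels = km.fit_predict(x)
        out[int(k)] = pd.Series(labels, index=profiles.index, name=f"k{k}")
    return out


def hypergeometric_enrichment(
    assignment: pd.Series,
    annotation: GeneAnnotation,
    min_genes: int = 10,
    category_whitelist: set[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment p per (cluster, category).

    The universe is the set of clustered genes.  Categories are restricted to
    the whitelist (if given) and to those with at least ``min_genes``
    annotated genes inside the universe.  Returns columns
    ``cluster, category, n_category, n_in_cluster, overlap, p_raw``.
    """
    universe = list(assignment.index)
    uni_set = set(universe)
    m_total = len(universe)
    t2g = {t: gs & uni_set for t, gs in annotation.term_to_genes().items()}
    cats = {t: gs for t, gs in t2g.items()
            if len(gs) >= min_genes
            and (category_whitelist is None or t in category_whitelist)}
    if not cats:
        raise ValidationError(
            "no category passes the whitelist and minimum-size filters")
    rows = []
    for cluster_id, members in assignment.groupby(assignment).groups.items():
        cluster_genes = set(members)
        n_c = len(cluster_genes)
        for cat, cat_genes in sorted(cats.items()):
            ov = len(cat_genes & cluster_genes)
            # P(X >= ov), X ~ Hypergeom(M=m_total, n=|cat|, N=n_c)
            p = float(stats.hypergeom.sf(ov - 1, m_total, len(cat_genes), n_c))
            rows.append((cluster_id, cat, len(cat_genes), n_c, ov, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["cluster", "category", "n_category",
                                       "n_in_cluster", "overlap", "p_raw"])


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone after the cummin transform)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def double_fdr(
    tables_by_k: Mapping[int, pd.DataFrame],
    stage2_on_raw: bool = False,
) -> pd.DataFrame:
    """Two-stage FDR over a per-k family of enrichment tables.

    Stage 1: BH across all (cluster, category) tests within each k.
    Stage 2: each category receives one value per k — the minimum stage-1 q
    over that k's clusters (its best-calling cluster); those per-k values are
    BH-corrected across the k grid, per category.  With
    ``stage2_on_raw=True`` the per-k summary is the minimum raw p instead.

    Returns the concatenated table with added columns ``k, q_stage1,
    q_stage2`` (the stage-2 q of the (k, category) family member is repeated
    on each of its rows).
    """
    if not tables_by_k:
        raise ValidationError("empty enrichment input")
    frames = []
    for k, tab in tables_by_k.items():
        tab = tab.copy()
        tab.insert(0, "k", int(k))
        tab["q_stage1"] = benjamini_hochberg(tab["p_raw"].to_numpy())
        frames.append(tab)
    full = pd.concat(frames, ignore_index=True)

    col = "p_raw" if stage2_on_raw else "q_stage1"
    per_k_cat = full.groupby(["category", "k"])[col].min().reset_index()
    per_k_cat["q_stage2"] = np.nan
    for cat, grp in per_k_cat.groupby("category"):
        q = benjamini_hochberg(grp[col].to_numpy())
        per_k_cat.loc[grp.index, "q_stage2"] = q
    full = full.merge(per_k_cat[["category", "k", "q_stage2"]],
                      on=["category", "k"], how="left")
    return full


def enriched_categories(table: pd.DataFrame, threshold: float = 0.01) -> pd.Series:
    """Category -> best (minimum over k) stage-2 q, filtered at the
    threshold.  The reference analysis uses q < 0.01."""
    best = table.groupby("category")["q_stage2"].min()
    return best[best < threshold].sort_values()


def screen_hierarchy(
    category_q: Mapping[str, float],
    annotation: GeneAnnotation,
) -> set[str]:
    """Keep only the most refined enriched categories.

    A category is discarded iff one of its DAG descendants is also in the
    enriched set with a strictly lower q.
    """
    kept: set[str] = set()
    enriched = dict(category_q)
    for cat, q in enriched.items():
        desc = annotation.descendants(cat)
        if any(d in enriched and enriched[d] < q for d in desc):
            continue
        kept.add(cat)
    return kept


def phase_assignment(
    profiles: pd.DataFrame,
    cluster_genes: Sequence[str],
    embryonic_tps: Sequence[str],
    postnatal_tps: Sequence[str],
    alpha: float = 0.05,
) -> str:
    """Label a cluster embryonic / postnatal / neither.

    Pools all contribution values of the cluster's genes at embryonic ages
    and separately at postnatal ages, compares the pools with a two-sample
    rank test (Mann-Whitney; the pools are unpaired and of unequal size), and
    if significant assigns the phase with the larger median.
    """
    genes = [g for g in cluster_genes if g in profiles.index]
    if not genes:
        raise ValidationError("cluster has no genes in the profile universe")
    emb = profiles.loc[genes, list(embryonic_tps)].to_numpy().ravel()
    post = profiles.loc[genes, list(postnatal_tps)].to_numpy().ravel()
    if emb.size == 0 or post.size == 0:
        raise ValidationError("both phase pools must be non-empty")
    if np.ptp(np.concatenate([emb, post])) == 0.0:
        logger.info("phase test degenerate (all values tied); labelling neither")
        return "neither"
    p = float(stats.mannwhitneyu(emb, post, alternative="two-sided").pvalue)
    if p >= alpha:
        return "neither"
    return "embryonic" if np.median(emb) > np.median(post) else "postnatal"


def annotate_enrichment(
    table: pd.DataFrame,
    profiles: pd.DataFrame,
    assignments: Mapping[int, pd.Series],
    annotation: GeneAnnotation,
    embryonic_tps: Sequence[str],
    postnatal_tps: Sequence[str],
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Finish the enrichment table: per-cluster phase labels and the
    hierarchy-screen keep flag for enriched categories.

    ``table`` is the double-FDR output; ``assignments`` the per-k
    clusterings it was built from.  Adds a ``phase`` column (the cluster's
    embryonic/postnatal/neither call) and a boolean ``kept`` column that is
    True for rows of enriched categories surviving the descendant screen.
    """
    table = table.copy()
    phases: dict[tuple[int, object], str] = {}
    for k, assignment in assignments.items():
        for cluster_id, members in assignment.groupby(assignment).groups.items():
            phases[(int(k), cluster_id)] = phase_assignment(
                profiles, list(members), embryonic_tps, postnatal_tps)
    table["phase"] = [phases.get((int(k), c), "neither")
                      for k, c in zip(table["k"], table["cluster"])]
    enriched = enriched_categories(table, threshold)
    kept = screen_hierarchy(enriched.to_dict(), annotation)
    table["kept"] = table["category"].isin(kept)
    return table


def category_contribution_index(
    profiles: pd.DataFrame,
    annotation: GeneAnnotation,
    category: str,
    timepoint: str,
) -> float:
    """Mean contribution dD_g(t) over the genes annotated to the category
    (restricted to the profile universe)."""
    genes = sorted(annotation.term_to_genes().get(category, set())
                   & set(profiles.index))
    if not genes:
        raise ValidationError(
            f"category {category!r} has no genes in the profile universe")
    return float(profiles.loc[genes, timepoint].mean())
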