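"""Contribution profiles, k-means clustering, enrichment and double FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from regiospec import synthetic_data as syn
from regiospec.contribution_enrichment import (benjamini_hochberg,
                                               category_contribution_index,
                                               cluster_profiles,
                                               contribution_profiles,
                                               double_fdr,
                                               enriched_categories,
                                               hypergeometric_enrichment,
                                               phase_assignment,
                                               screen_hierarchy)
from regiospec.io_core import GeneAnnotation, ValidationError

from conftest import make_dataset


def brute_force_contributions(ds, timepoints=None):
    """Independent oracle: recompute mean dissimilarity with scipy.pearsonr
    on the gene-deleted data, pair by pair."""
    tps = timepoints or ds.timepoints

    def mean_d(values):
        out = []
        nr = values.shape[1]
        for i in range(nr):
            for j in range(i + 1, nr):
                x, y = values[:, i], values[:, j]
                mask = ~(np.isnan(x) | np.isnan(y))
                if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                    continue
                out.append(1 - stats.pearsonr(x[mask], y[mask]).statistic)
        return np.mean(out)

    result = np.zeros((ds.n_genes, len(tps)))
    for ti, t in enumerate(tps):
        m = ds.matrix_at(t)
        dbar = mean_d(m)
        for gi in range(ds.n_genes):
            reduced = np.delete(m, gi, axis=0)
            result[gi, ti] = dbar - mean_d(reduced)
    return pd.DataFrame(result, index=list(ds.genes), columns=list(tps))


class TestContributionProfiles:
    def test_identical_genes_give_zero(self):
        # every gene flat across regions -> all regions share one profile,
        # Dbar = 0 and every leave-one-out contribution is 0
        vals = np.tile(np.arange(1, 7.0)[:, None, None], (1, 4, 2))
        ds = make_dataset(vals)
        prof = contribution_profiles(ds)
        assert (prof.abs() < 1e-14).all().all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(20)
        ds = make_dataset(rng.uniform(0, 5, size=(12, 5, 3)))
        prof = contribution_profiles(ds)
        oracle = brute_force_contributions(ds)
        np.testing.assert_allclose(prof.to_numpy(), oracle.to_numpy(),
                                   atol=1e-12)

    def test_planted_driver_has_max_contribution(self):
        rng = np.random.default_rng(21)
        base = rng.uniform(2, 4, size=15)
        vals = np.tile(base[:, None, None], (1, 6, 2))
        vals += rng.normal(0, 0.01, size=vals.shape)
        vals[0, :, :] += np.array([0, 8, 0, 8, 0, 8])[:, None]
        ds = make_dataset(np.clip(vals, 0, None))
        prof = contribution_profiles(ds)
        assert (prof.idxmax(axis=0) == "g0").all()

    def test_too_few_genes_errors(self):
        ds = make_dataset(np.ones((2, 3, 2)))
        with pytest.raises(ValidationError):
            contribution_profiles(ds)


class TestClustering:
    def test_k1_single_cluster(self):
        rng = np.random.default_rng(22)
        prof = pd.DataFrame(rng.normal(size=(10, 4)))
        asg = cluster_profiles(prof, [1], seed=0)[1]
        assert asg.nunique() == 1

    def test_two_separated_groups_recovered(self):
        # two well-separated profile groups: ARI 1.0 in >= 9/10 seeds
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            a = rng.normal(0, 0.05, size=(20, 5))
            b = rng.normal(3, 0.05, size=(20, 5))
            prof = pd.DataFrame(np.vstack([a, b]))
            truth = [0] * 20 + [1] * 20
            asg = cluster_profiles(prof, [2], restarts=10, seed=s)[2]
            hits += adjusted_rand_score(truth, asg.to_numpy()) == 1.0
        assert hits >= 9

    def test_seeded_determinism(self):
        rng = np.random.default_rng(23)
        prof = pd.DataFrame(rng.normal(size=(30, 4)))
        a = cluster_profiles(prof, [3, 5], seed=11)
        b = cluster_profiles(prof, [3, 5], seed=11)
        for k in (3, 5):
            pd.testing.assert_series_equal(a[k], b[k])

    def test_empty_grid_errors(self):
        prof = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ValidationError):
            cluster_profiles(prof, [], seed=0)


class TestHypergeometric:
    def test_exact_extreme_overlap(self):
        # universe 100, cluster 10, category 10, overlap 10:
        # p = 1 / C(100, 10) by direct enumeration of the single tail case
        from math import comb

        genes = [f"g{i}" for i in range(100)]
        asg = pd.Series([0] * 10 + [1] * 90, index=genes)
        ann = GeneAnnotation({g: {"GO:X"} for g in genes[:10]},
                             {"GO:X": set()})
        tab = hypergeometric_enrichment(asg, ann, min_genes=10)
        row = tab[(tab["cluster"] == 0) & (tab["category"] == "GO:X")]
        assert row["p_raw"].iloc[0] == pytest.approx(1 / comb(100, 10),
                                                     rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        genes = [f"g{i}" for i in range(40)]
        asg = pd.Series([0] * 20 + [1] * 20, index=genes)
        ann = GeneAnnotation({g: {"GO:X"} for g in genes[20:30]},
                             {"GO:X": set()})
        tab = hypergeometric_enrichment(asg, ann, min_genes=10)
        row = tab[(tab["cluster"] == 0) & (tab["category"] == "GO:X")]
        assert row["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_small_category_excluded(self):
        genes = [f"g{i}" for i in range(40)]
        asg = pd.Series([0] * 20 + [1] * 20, index=genes)
        ann = GeneAnnotation({g: {"GO:X"} for g in genes[:9]},
                             {"GO:X": set(), "GO:Y": set()})
        ann.gene_to_terms.update({g: {"GO:Y"} for g in genes[9:20]})
        tab = hypergeometric_enrichment(asg, ann, min_genes=10)
        assert set(tab["category"]) == {"GO:Y"}

    def test_whitelist_restricts(self):
        genes = [f"g{i}" for i in range(40)]
        asg = pd.Series([0] * 20 + [1] * 20, index=genes)
        g2t = {g: {"GO:X", "GO:Y"} for g in genes[:15]}
        ann = GeneAnnotation(g2t, {"GO:X": set(), "GO:Y": set()})
        tab = hypergeometric_enrichment(asg, ann, min_genes=10,
                                        category_whitelist={"GO:X"})
        assert set(tab["category"]) == {"GO:X"}


class TestBHAndDoubleFDR:
    def test_bh_matches_hand_computation(self):
        p = np.array([0.01, 0.04, 0.03, 0.005, 0.2])
        # hand computation: sort, q_(i) = p_(i) * m / i, cummin from largest
        order = np.argsort(p)
        m = len(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1)
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_bh_constant_vector_unchanged(self):
        p = np.full(6, 0.02)
        np.testing.assert_allclose(benjamini_hochberg(p), p, atol=1e-15)

    def test_bh_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(24)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_single_k_single_category_stage2_equals_stage1(self):
        tab = pd.DataFrame({"cluster": [0, 1], "category": ["GO:X"] * 2,
                            "n_category": [10] * 2, "n_in_cluster": [5, 5],
                            "overlap": [3, 1], "p_raw": [0.004, 0.6]})
        full = double_fdr({10: tab})
        best = full.groupby("category")["q_stage2"].min()
        stage1_min = full.groupby("category")["q_stage1"].min()
        assert best["GO:X"] == pytest.approx(stage1_min["GO:X"])

    def test_constant_raw_p_passes_through_both_stages(self):
        tabs = {}
        for k in (2, 3):
            tabs[k] = pd.DataFrame({
                "cluster": list(range(k)), "category": ["GO:X"] * k,
                "n_category": [10] * k, "n_in_cluster": [5] * k,
                "overlap": [2] * k, "p_raw": [0.05] * k})
        full = double_fdr(tabs)
        assert np.allclose(full["q_stage1"], 0.05)
        assert np.allclose(full["q_stage2"], 0.05)


class TestAnnotatedTable:
    def test_phase_and_keep_columns(self):
        # one cluster of embryonic-heavy genes, one postnatal-heavy; a parent
        # category outranked by its enriched child gets kept=False
        from regiospec.contribution_enrichment import annotate_enrichment

        cols = list(syn.DEFAULT_TIMEPOINTS)
        rng = np.random.default_rng(70)
        vals = rng.normal(0, 0.001, size=(40, 7))
        vals[:20, :4] += 1.0   # embryonic program
        vals[20:, 4:] += 1.0   # postnatal program
        prof = pd.DataFrame(vals, index=[f"g{i}" for i in range(40)],
                            columns=cols)
        asg = pd.Series([0] * 20 + [1] * 20, index=prof.index)
        g2t = {f"g{i}": {"child", "parent"} for i in range(15)}
        ann = GeneAnnotation(g2t, {"child": {"parent"}, "parent": set()})
        tab = hypergeometric_enrichment(asg, ann, min_genes=10)
        # make the child strictly stronger than the propagated parent (a
        # factor large enough to survive the BH rank correction)
        tab.loc[tab["category"] == "child", "p_raw"] *= 0.1
        full = double_fdr({2: tab})
        out = annotate_enrichment(full, prof, {2: asg}, ann,
                                  syn.EMBRYONIC_TIMEPOINTS,
                                  syn.POSTNATAL_TIMEPOINTS, threshold=0.01)
        assert set(out.columns) >= {"phase", "kept"}
        phases = out.set_index("cluster")["phase"].to_dict()
        assert phases[0] == "embryonic" and phases[1] == "postnatal"
        kept = out.groupby("category")["kept"].first()
        assert bool(kept["child"]) and not bool(kept["parent"])


class TestHierarchyScreen:
    def test_unrelated_categories_all_kept(self):
        ann = GeneAnnotation({}, {"a": set(), "b": set()})
        kept = screen_hierarchy({"a": 0.004, "b": 0.005}, ann)
        assert kept == {"a", "b"}

    def test_parent_dropped_when_child_lower(self):
        ann = GeneAnnotation({}, {"child": {"parent"}, "parent": set()})
        kept = screen_hierarchy({"parent": 0.005, "child": 0.001}, ann)
        assert kept == {"child"}

    def test_three_chain_rule(self):
        # grandparent(0.004) -> parent(0.002) -> child(0.003):
        # grandparent dropped (parent is lower), parent kept (its only
        # enriched descendant, child, is higher), child kept (no descendant)
        ann = GeneAnnotation({}, {"child": {"parent"},
                                  "parent": {"grandparent"},
                                  "grandparent": set()})
        kept = screen_hierarchy(
            {"grandparent": 0.004, "parent": 0.002, "child": 0.003}, ann)
        assert kept == {"parent", "child"}


class TestPhaseAndIndex:
    def test_identical_pools_neither(self):
        prof = pd.DataFrame(np.ones((10, 7)),
                            columns=list(syn.DEFAULT_TIMEPOINTS))
        phase = phase_assignment(prof, list(prof.index),
                                 syn.EMBRYONIC_TIMEPOINTS,
                                 syn.POSTNATAL_TIMEPOINTS)
        assert phase == "neither"

    def test_all_embryonic_mass(self):
        # embryonic values 1, postnatal 0, n=40 per pool: the rank test is
        # maximally significant and the embryonic median is larger
        cols = list(syn.DEFAULT_TIMEPOINTS)
        vals = np.zeros((10, 7))
        vals[:, :4] = 1.0
        prof = pd.DataFrame(vals, columns=cols)
        phase = phase_assignment(prof, list(prof.index),
                                 syn.EMBRYONIC_TIMEPOINTS,
                                 syn.POSTNATAL_TIMEPOINTS)
        assert phase == "embryonic"
        u, p = stats.mannwhitneyu(np.ones(40), np.zeros(30),
                                  alternative="two-sided")
        assert p < 0.05  # oracle: exact rank test on the same pools

    def test_postnatal_direction(self):
        cols = list(syn.DEFAULT_TIMEPOINTS)
        rng = np.random.default_rng(25)
        vals = rng.normal(0, 0.01, size=(10, 7))
        vals[:, 4:] += 1.0
        prof = pd.DataFrame(vals, columns=cols)
        assert phase_assignment(prof, list(prof.index),
                                syn.EMBRYONIC_TIMEPOINTS,
                                syn.POSTNATAL_TIMEPOINTS) == "postnatal"

    def test_category_index_is_arithmetic_mean(self):
        prof = pd.DataFrame({"t0": [0.001, 0.002, 0.003, 0.5]},
                            index=["a", "b", "c", "d"])
        ann = GeneAnnotation({"a": {"GO:X"}, "b": {"GO:X"}, "c": {"GO:X"}},
                             {"GO:X": set()})
        idx = category_contribution_index(prof, ann, "GO:X", "t0")
        assert idx == pytest.approx(0.002)

    def test_category_without_genes_errors(self):
        prof = pd.DataFrame({"t0": [0.1]}, index=["a"])
        ann = GeneAnnotation({}, {"GO:X": set()})
        with pytest.raises(ValidationError):
            category_contribution_index(prof, ann, "GO:X", "t0")

    def test_construction_vs_plasticity_index_order(self):
        # the planted construction category out-contributes the plasticity
        # category at the first age; the order reverses at the last age
        ds, truth = syn.generate(syn.SyntheticConfig(seed=30))
        prof = contribution_profiles(ds)
        g2t = {}
        for cat, genes in truth.planted_categories.items():
            for g in genes:
                g2t.setdefault(g, set()).add(cat)
        ann = GeneAnnotation(g2t, {c: set() for c in truth.planted_categories})
        con_cat, pla_cat = sorted(truth.planted_categories)
        first, last = ds.timepoints[0], ds.timepoints[-1]
        assert (category_contribution_index(prof, ann, con_cat, first)
                > category_contribution_index(prof, ann, pla_cat, first))
        assert (category_contribution_index(prof, ann, pla_cat, last)
                > category_contribution_index(prof, ann, con_cat, last))
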