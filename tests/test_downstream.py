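"""Regulated genes, pathway pair counts, bridge genes, enrichment.

Oracles: scipy's hypergeometric survival function, scipy's pearsonr p-value,
and exhaustive double-loop scans over a constructed toy dataset.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from dnbscope import (
    bridge_genes,
    hypergeom_upper,
    pathway_pair_counts,
    pcc_pvalue,
    regulated_genes,
)
from tests.conftest import make_dataset, two_timepoint_map


class TestPccPvalue:
    def test_zero_correlation_uninformative(self):
        assert pcc_pvalue(0.0, 10) == 1.0

    def test_perfect_correlation_degenerate(self):
        assert pcc_pvalue(1.0, 5) == 0.0
        assert pcc_pvalue(-1.0, 5) == 0.0

    def test_boundary_of_significance_at_four_samples(self):
        # t = 0.95*sqrt(2/(1-0.95^2)) = 4.30 is almost exactly t_{0.975, 2}
        assert pcc_pvalue(0.95, 4) == pytest.approx(0.05, abs=0.001)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_pearsonr(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 8))
        r, p_ref = stats.pearsonr(x, y)
        assert pcc_pvalue(r, 8) == pytest.approx(p_ref, rel=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pcc_pvalue(0.5, 2)


class TestHypergeomUpper:
    @pytest.mark.parametrize(
        "N,K,n,k",
        [(50, 10, 20, 5), (100, 30, 40, 20), (20899, 3458, 1049, 209)],
    )
    def test_matches_scipy_survival_function(self, N, K, n, k):
        assert hypergeom_upper(N, K, n, k) == pytest.approx(
            float(stats.hypergeom.sf(k - 1, N, K, n)), rel=1e-10
        )

    def test_zero_observed_is_certain(self):
        assert hypergeom_upper(100, 20, 30, 0) == 1.0

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_upper(100, 30, 40, k) for k in range(0, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[0] > ps[-1]

    def test_complement_identity(self):
        N, K, n = 200, 50, 60
        for k in (1, 10, 25):
            lower = float(stats.hypergeom.cdf(k - 1, N, K, n))
            assert hypergeom_upper(N, K, n, k) + lower == pytest.approx(1.0, abs=1e-10)

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(10, 20, 5, 1)
        with pytest.raises(ValueError):
            hypergeom_upper(100, 20, 30, 25)


def toy_dataset(seed=0, n_genes=30):
    """Random two-time-point dataset for exhaustive-oracle comparisons.

    Random expression gives a rich, irregular link/DE structure; the oracle
    below recomputes both filters gene by gene with library statistics.
    """
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=0, sigma=0.5, size=(n_genes, 13))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    return make_dataset(vals, genes, two_timepoint_map(6, 7, "crit", "onset"))


def oracle_regulated(ds, members, critical, onset, min_links, alpha):
    """Exhaustive double loop using scipy statistics only."""
    sl_on = ds.slice_timepoint(onset)
    sl_cr = ds.slice_timepoint(critical)
    idx_on = {g: i for i, g in enumerate(sl_on.gene_ids)}
    idx_cr = {g: i for i, g in enumerate(sl_cr.gene_ids)}
    out = {}
    for g in ds.gene_ids:
        if g in set(members):
            continue
        links = 0
        for m in members:
            r, p = stats.pearsonr(sl_on.values[idx_on[g]], sl_on.values[idx_on[m]])
            if p < alpha:
                links += 1
        if links < min_links:
            continue
        p_de = stats.ttest_ind(
            sl_cr.values[idx_cr[g]], sl_on.values[idx_on[g]], equal_var=True
        ).pvalue
        if p_de < alpha or alpha >= 1.0:
            out[g] = links
    return out


class TestRegulatedGenes:
    @pytest.mark.parametrize("min_links,alpha", [(2, 0.3), (3, 0.2), (1, 0.05)])
    def test_equals_exhaustive_oracle(self, min_links, alpha):
        ds = toy_dataset(seed=1)
        members = [f"g{i:02d}" for i in range(8)]
        got = regulated_genes(ds, members, "crit", "onset", min_links=min_links, alpha=alpha)
        expected = oracle_regulated(ds, members, "crit", "onset", min_links, alpha)
        assert dict((g, l) for g, (l, _) in got.genes.items()) == expected

    def test_link_count_boundary_is_inclusive(self):
        # pick min_links equal to an observed link count: that gene must stay in
        ds = toy_dataset(seed=2)
        members = [f"g{i:02d}" for i in range(8)]
        base = regulated_genes(ds, members, "crit", "onset", min_links=1, alpha=0.5)
        counts = sorted({l for l, _ in base.genes.values()})
        assert len(counts) >= 2, "toy must produce a spread of link counts"
        cut = counts[-2]  # an interior observed count
        at_cut = regulated_genes(ds, members, "crit", "onset", min_links=cut, alpha=0.5)
        assert any(l == cut for l, _ in at_cut.genes.values())
        assert all(l >= cut for l, _ in at_cut.genes.values())

    def test_degenerate_filters_return_all_non_members(self):
        ds = toy_dataset(seed=3)
        members = [f"g{i:02d}" for i in range(5)]
        got = regulated_genes(ds, members, "crit", "onset", min_links=0, alpha=1.0)
        assert set(got.gene_ids()) == set(ds.gene_ids) - set(members)

    def test_unknown_member_rejected(self):
        ds = toy_dataset()
        with pytest.raises(KeyError):
            regulated_genes(ds, ["nope", "g00"], "crit", "onset")


class TestPathwayPairCounts:
    def test_fully_correlated_disjoint_sets(self):
        base = np.array([1.0, 2.0, 4.0, 8.0, 3.0])
        vals = np.vstack([base * (i + 1) for i in range(7)])  # all pairwise r = 1
        genes = [f"g{i}" for i in range(7)]
        ds = make_dataset(vals, genes, [(f"s{i}", "t1", 1) for i in range(5)])
        s = pathway_pair_counts(ds, "t1", genes[:3], genes[3:], high_threshold=0.9)
        assert (s.n_pairs, s.n_dnb_genes_involved, s.n_pathway_genes_involved) == (12, 3, 4)

    def test_nothing_above_threshold(self, rng):
        vals = rng.lognormal(size=(6, 5))
        genes = [f"g{i}" for i in range(6)]
        ds = make_dataset(vals, genes, [(f"s{i}", "t1", 1) for i in range(5)])
        s = pathway_pair_counts(ds, "t1", genes[:3], genes[3:], high_threshold=1.0)
        assert (s.n_pairs, s.n_dnb_genes_involved, s.n_pathway_genes_involved) == (0, 0, 0)

    def test_shared_gene_counts_on_both_sides_but_not_with_itself(self):
        ds = toy_dataset(seed=4, n_genes=12)
        sl = ds.slice_timepoint("onset")
        idx = {g: i for i, g in enumerate(sl.gene_ids)}
        dnb = [f"g{i:02d}" for i in range(5)]
        pathway = [f"g{i:02d}" for i in range(3, 9)]  # shares g03, g04
        thr = 0.3
        s = pathway_pair_counts(ds, "onset", dnb, pathway, high_threshold=thr)
        expected = 0
        for d in dnb:
            for p in pathway:
                if d == p:
                    continue
                r = abs(stats.pearsonr(sl.values[idx[d]], sl.values[idx[p]])[0])
                expected += r > thr
        assert s.n_pairs == expected

    def test_swap_symmetry(self):
        ds = toy_dataset(seed=5, n_genes=14)
        a = [f"g{i:02d}" for i in range(4)]
        b = [f"g{i:02d}" for i in range(4, 10)]
        s1 = pathway_pair_counts(ds, "onset", a, b, high_threshold=0.4)
        s2 = pathway_pair_counts(ds, "onset", b, a, high_threshold=0.4)
        assert s1.n_pairs == s2.n_pairs
        assert (s1.n_dnb_genes_involved, s1.n_pathway_genes_involved) == (
            s2.n_pathway_genes_involved,
            s2.n_dnb_genes_involved,
        )

    def test_empty_intersection_warns_and_zeroes(self):
        ds = toy_dataset(seed=6, n_genes=10)
        with pytest.warns(RuntimeWarning, match="empty intersection"):
            s = pathway_pair_counts(ds, "onset", ["absent1"], ["g01"], high_threshold=0.5)
        assert s.n_pairs == 0


class TestBridgeGenes:
    def test_empty_regulated_set_gives_empty_result(self):
        ds = toy_dataset(seed=7)
        reg = regulated_genes(ds, [f"g{i:02d}" for i in range(8)], "crit", "onset",
                              min_links=8, alpha=0.001)
        assert len(reg) == 0
        res = bridge_genes(ds, reg, ["g20", "g21", "g22"], "crit", "onset")
        assert len(res) == 0

    @pytest.mark.parametrize("min_links,alpha", [(2, 0.3), (1, 0.2)])
    def test_equals_exhaustive_oracle(self, min_links, alpha):
        ds = toy_dataset(seed=8)
        dnb1 = [f"g{i:02d}" for i in range(6)]
        dnb2 = [f"g{i:02d}" for i in range(20, 28)]
        reg1 = regulated_genes(ds, dnb1, "crit", "onset", min_links=1, alpha=0.4)
        got = bridge_genes(ds, reg1, dnb2, "crit", "onset", min_links=min_links, alpha=alpha)

        sl_cr = ds.slice_timepoint("crit")
        sl_on = ds.slice_timepoint("onset")
        idx_cr = {g: i for i, g in enumerate(sl_cr.gene_ids)}
        idx_on = {g: i for i, g in enumerate(sl_on.gene_ids)}
        expected = {}
        for g in reg1.gene_ids():
            links = 0
            for m in dnb2:
                if m == g:
                    continue
                _, p = stats.pearsonr(sl_cr.values[idx_cr[g]], sl_cr.values[idx_cr[m]])
                if p < alpha:
                    links += 1
            if links < min_links:
                continue
            p_de = stats.ttest_ind(
                sl_cr.values[idx_cr[g]], sl_on.values[idx_on[g]], equal_var=True
            ).pvalue
            if p_de < alpha:
                expected[g] = links
        assert dict((g, l) for g, (l, _) in got.genes.items()) == expected

    def test_overlap_with_second_module_reported(self):
        ds = toy_dataset(seed=9)
        dnb1 = [f"g{i:02d}" for i in range(6)]
        dnb2 = [f"g{i:02d}" for i in range(8, 16)]
        reg1 = regulated_genes(ds, dnb1, "crit", "onset", min_links=0, alpha=1.0)
        res = bridge_genes(ds, reg1, dnb2, "crit", "onset", min_links=0, alpha=1.0)
        assert set(res.overlap_with_dnb2) == set(reg1.gene_ids()) & set(dnb2)
        # a DNB2 member passing both (degenerate) filters is included
        assert set(res.overlap_with_dnb2) <= set(res.gene_ids())
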