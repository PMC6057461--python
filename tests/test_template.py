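"""ANOVA screen, clustering, and Pavlidis Template Matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radtx import (
    FoldChangeMatrix,
    anova_screen,
    centroid_profiles,
    cluster_genes,
    default_design,
    gradual_template,
    ptm,
    select_correlated,
)
from radtx.template import TemplateProfile, anova_pvalues


def make_fc(values, arms, genes=None, log2=True):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return FoldChangeMatrix(frame, pd.Series(arms, index=samples, name="arm"), log2=log2)


def brute_force_f_pvalue(groups):
    """Textbook one-way ANOVA F statistic and p, written out longhand."""
    from scipy.stats import f as f_dist

    k = len(groups)
    ns = [len(g) for g in groups]
    n = sum(ns)
    grand = sum(sum(g) for g in groups) / n
    ss_between = sum(m * (np.mean(g) - grand) ** 2 for m, g in zip(ns, groups))
    ss_within = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups)
    F = (ss_between / (k - 1)) / (ss_within / (n - k))
    return F, float(f_dist.sf(F, k - 1, n - k))


class TestAnovaScreen:
    ARMS = ["a"] * 3 + ["b"] * 3 + ["c"] * 3

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        values = np.vstack([np.zeros(9), rng.normal(size=9)])
        fc = make_fc(values, self.ARMS)
        assert "g0" not in anova_screen(fc, alpha=0.5)

    def test_clear_separation_selected(self):
        rng = np.random.default_rng(1)
        values = np.array([[0, 0, 0, 0, 0, 0, 1, 1, 1]], dtype=float)
        values = values + rng.normal(0, 1e-6, size=values.shape)
        fc = make_fc(values, self.ARMS)
        assert anova_screen(fc, alpha=0.01) == ["g0"]

    def test_pvalues_match_longhand_f_computation(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(20, 9))
        fc = make_fc(values, self.ARMS)
        ours = anova_pvalues(fc)
        for i in range(20):
            groups = [values[i, :3], values[i, 3:6], values[i, 6:]]
            _, p = brute_force_f_pvalue(groups)
            assert ours.iloc[i] == pytest.approx(p, rel=1e-9)

    def test_ranked_ascending_and_truncated(self):
        rng = np.random.default_rng(3)
        signal = np.outer(np.linspace(0.2, 2.0, 10), [0, 0, 0, 1, 1, 1, 2, 2, 2])
        values = signal + rng.normal(0, 0.3, size=signal.shape)
        fc = make_fc(values, self.ARMS)
        hits = anova_screen(fc, alpha=0.05, top_n=3)
        assert len(hits) <= 3
        pvals = anova_pvalues(fc)[hits]
        assert list(pvals) == sorted(pvals)

    def test_too_few_arms_rejected(self):
        fc = make_fc(np.ones((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            anova_screen(fc)


class TestClustering:
    ARMS = ["a", "b"]

    def test_identical_profiles_merge_at_distance_zero(self):
        fc = make_fc([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]], self.ARMS)
        _, link = cluster_genes(fc, ["g0", "g1", "g2"], n_clusters=2)
        assert link[0, 2] == pytest.approx(0.0)

    def test_first_merge_is_closest_pair(self):
        # profiles (0,0), (0,3), (4,0): closest pair at Euclidean distance 3
        fc = make_fc([[0.0, 0.0], [0.0, 3.0], [4.0, 0.0]], self.ARMS)
        _, link = cluster_genes(fc, ["g0", "g1", "g2"], n_clusters=2)
        assert sorted(link[0, :2]) == [0, 1]
        assert link[0, 2] == pytest.approx(3.0)

    def test_flat_clusters_invariant_to_gene_order(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(12, 4))
        arms = ["a", "b", "c", "d"]
        fc = make_fc(values, arms)
        genes = [f"g{i}" for i in range(12)]
        c1, _ = cluster_genes(fc, genes, n_clusters=3)
        perm = list(rng.permutation(genes))
        fc2 = make_fc(values, arms)
        c2, _ = cluster_genes(fc2, perm, n_clusters=3)
        parts1 = {frozenset(c1.index[c1 == k]) for k in set(c1)}
        parts2 = {frozenset(c2.index[c2 == k]) for k in set(c2)}
        assert parts1 == parts2

    def test_single_gene_rejected(self):
        fc = make_fc([[1.0, 2.0]], self.ARMS)
        with pytest.raises(ValueError):
            cluster_genes(fc, ["g0"])


class TestCentroids:
    def test_singleton_centroid_is_the_gene_profile(self):
        fc = make_fc([[1.0, 3.0]], ["a", "b"])
        clusters = pd.Series([1], index=["g0"])
        centroids, sizes = centroid_profiles(fc, clusters)
        assert list(centroids.loc[1]) == [1.0, 3.0]
        assert sizes[1] == 1

    def test_two_gene_centroid_is_the_mean(self):
        fc = make_fc([[0.0, 2.0], [2.0, 0.0]], ["a", "b"])
        clusters = pd.Series([1, 1], index=["g0", "g1"])
        centroids, _ = centroid_profiles(fc, clusters)
        assert list(centroids.loc[1]) == [1.0, 1.0]

    def test_random_clusters_match_brute_force_means(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(10, 3))
        fc = make_fc(values, ["a", "b", "c"])
        assign = rng.integers(1, 4, size=10)
        clusters = pd.Series(assign, index=fc.gene_ids)
        centroids, sizes = centroid_profiles(fc, clusters)
        for k in sorted(set(assign)):
            expected = values[assign == k].mean(axis=0)
            assert np.allclose(centroids.loc[k], expected)
            assert sizes[k] == int((assign == k).sum())

    def test_empty_clusters_rejected(self):
        fc = make_fc([[1.0, 2.0]], ["a", "b"])
        with pytest.raises(ValueError):
            centroid_profiles(fc, pd.Series(dtype=int))


class TestGradualTemplate:
    def test_three_arm_template_values(self):
        arms = pd.Series(
            ["endo", "endo", "ebrt", "ebrt", "comb", "comb"],
            index=[f"s{i}" for i in range(6)],
        )
        cats = {"endo": "endoRT", "ebrt": "EBRT", "comb": "combined"}
        template = gradual_template(arms, cats)
        assert list(template.values) == [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]

    def test_photon_and_carbon_share_the_ebrt_level(self, design):
        arms = design.sample_arms()
        template = gradual_template(arms, dict(design.categories))
        photon = template.values[arms[template.sample_ids] == "photon_EBRT"]
        carbon = template.values[arms[template.sample_ids] == "carbon_EBRT"]
        assert set(photon) == set(carbon) == {2.0}
        # control samples are excluded from the template domain
        assert not set(arms.index[arms == "control"]) & set(template.sample_ids)

    def test_affine_level_rescaling_leaves_r_unchanged(self, design):
        rng = np.random.default_rng(6)
        arms = design.sample_arms()
        values = rng.normal(size=(15, len(arms)))
        fc = make_fc(values, list(arms), genes=[f"g{i}" for i in range(15)])
        fc.values.columns = arms.index
        fc.arms = arms
        cats = dict(design.categories)
        t1 = gradual_template(arms, cats, levels={"endoRT": 1, "EBRT": 2, "combined": 3})
        t2 = gradual_template(arms, cats, levels={"endoRT": 10, "EBRT": 20, "combined": 30})
        r1 = ptm(fc, t1)["r"]
        r2 = ptm(fc, t2)["r"]
        assert np.allclose(r1, r2)

    def test_missing_category_rejected(self):
        arms = pd.Series(["endo", "ebrt"], index=["s0", "s1"])
        cats = {"endo": "endoRT", "ebrt": "EBRT"}
        with pytest.raises(ValueError):
            gradual_template(arms, cats)


def _template(n_per_level=5):
    vals = pd.Series(
        np.repeat([1.0, 2.0, 3.0], n_per_level),
        index=[f"s{i}" for i in range(3 * n_per_level)],
    )
    return TemplateProfile(values=vals, levels={"endoRT": 1, "EBRT": 2, "combined": 3})


def fc_for_template(rows, template):
    values = np.asarray(rows, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=template.sample_ids)
    arms = pd.Series("arm", index=template.sample_ids)
    return FoldChangeMatrix(frame, arms, log2=True)


class TestPTM:
    def test_gene_equal_to_template_has_r_one(self):
        template = _template()
        fc = fc_for_template([template.values, -template.values], template)
        res = ptm(fc, template)
        assert res.loc["g0", "r"] == pytest.approx(1.0)
        assert res.loc["g1", "r"] == pytest.approx(-1.0)

    def test_t_transform_significance_at_r_08_n_15(self):
        """r=0.8 with 15 observations: t=4.807, two-sided p ~ 3.4e-4 (< 0.001)."""
        template = _template(5)  # 15 samples
        t = template.values.to_numpy()
        th = (t - t.mean()) / np.linalg.norm(t - t.mean())
        u = np.sin(np.arange(15.0))  # arbitrary direction
        u = u - u.mean() - (u - u.mean()) @ th * th
        uh = u / np.linalg.norm(u)
        gene = 0.8 * th + 0.6 * uh  # Pearson r with template exactly 0.8
        res = ptm(fc_for_template([gene], template), template)
        assert res.loc["g0", "r"] == pytest.approx(0.8)
        t_stat = 0.8 * np.sqrt(13 / (1 - 0.64))
        assert t_stat == pytest.approx(4.807, abs=0.001)
        # independent oracle: numerically integrate the t density tail
        x = np.linspace(t_stat, 200.0, 2_000_001)
        df = 13
        from math import gamma, sqrt, pi
        dens = (gamma((df + 1) / 2) / (sqrt(df * pi) * gamma(df / 2))
                * (1 + x**2 / df) ** (-(df + 1) / 2))
        p_oracle = 2 * np.trapezoid(dens, x)
        assert res.loc["g0", "p"] == pytest.approx(p_oracle, rel=1e-4)
        assert res.loc["g0", "p"] < 1e-3

    def test_constant_gene_and_short_gene_excluded(self):
        template = _template()
        rows = [np.ones(15), np.r_[[1.0, 2.0], [np.nan] * 13]]
        res = ptm(fc_for_template(rows, template), template)
        assert len(res) == 0

    def test_pairwise_deletion_counts_paired_observations(self):
        template = _template()
        row = template.values.to_numpy().astype(float).copy()
        row[0] = np.nan
        res = ptm(fc_for_template([row], template), template)
        assert res.loc["g0", "n_obs"] == 14

    def test_affine_invariance_and_sign_flip(self):
        template = _template()
        rng = np.random.default_rng(7)
        gene = rng.normal(size=15)
        fc = fc_for_template([gene, 3.0 * gene + 2.0, -2.0 * gene], template)
        res = ptm(fc, template)
        assert res.loc["g1", "r"] == pytest.approx(res.loc["g0", "r"])
        assert res.loc["g2", "r"] == pytest.approx(-res.loc["g0", "r"])


class TestSelectCorrelated:
    RESULTS = pd.DataFrame(
        {"r": [0.85, 0.75, -0.9], "n_obs": [15, 15, 15], "p": [1e-4, 1e-3, 1e-5]},
        index=["gA", "gB", "gC"],
    )

    def test_cutoff_08(self):
        sel = select_correlated(self.RESULTS, r_min=0.8)
        assert sel.up_cor == ["gA"] and sel.down_cor == ["gC"]

    def test_cutoff_07(self):
        sel = select_correlated(self.RESULTS, r_min=0.7)
        assert sel.up_cor == ["gA", "gB"] and sel.down_cor == ["gC"]

    def test_invalid_cutoff_rejected(self):
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                select_correlated(self.RESULTS, r_min=bad)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rs=st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False),
                       min_size=1, max_size=40),
           lo=st.floats(min_value=0.05, max_value=0.45),
           hi=st.floats(min_value=0.5, max_value=0.95))
    def test_monotone_nesting(self, rs, lo, hi):
        """Selection at a stricter cutoff is nested in the looser one."""
        results = pd.DataFrame({"r": rs}, index=[f"g{i}" for i in range(len(rs))])
        strict = select_correlated(results, r_min=hi)
        loose = select_correlated(results, r_min=lo)
        assert set(strict.up_cor) <= set(loose.up_cor)
        assert set(strict.down_cor) <= set(loose.down_cor)
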