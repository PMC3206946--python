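"""Dissimilarity, NMDS and PERMANOVA behaviour."""

import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from photoquad import (
    ValidationError,
    bray_curtis_binary,
    nmds,
    pairwise_braycurtis,
    pairwise_euclidean,
    permanova_nested,
    permanova_oneway,
    replicate_matrix,
    vc_to_diss,
)


class TestBrayCurtisBinary:
    def test_identical_nonempty_vectors(self):
        assert bray_curtis_binary([1, 0, 1], [1, 0, 1]) == 0.0

    def test_disjoint_vectors(self):
        assert bray_curtis_binary([1, 1, 0], [0, 0, 1]) == 1.0

    def test_direct_count_example(self):
        # x={s1,s2,s3}, y={s1}: a=1, b=2, c=0 -> 1 - 2/4
        assert bray_curtis_binary([1, 1, 1], [1, 0, 0]) == pytest.approx(0.5)

    def test_two_empty_vectors_undefined(self):
        with pytest.raises(ValidationError):
            bray_curtis_binary([0, 0], [0, 0])

    @given(
        st.lists(st.integers(0, 1), min_size=4, max_size=12),
        st.lists(st.integers(0, 1), min_size=4, max_size=12),
    )
    def test_equals_quantitative_bray_curtis_on_binary_data(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        from scipy.spatial.distance import braycurtis

        assert bray_curtis_binary(x, y) == pytest.approx(braycurtis(x, y))

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(6, 15))
        x[:, 0] = 1  # no empty unit
        dm = pairwise_braycurtis(x)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else bray_curtis_binary(x[i], x[j])
                assert dm.data[i, j] == pytest.approx(expected)

    def test_empty_unit_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            pairwise_braycurtis(np.array([[1, 0], [0, 0]]))


class TestNmds:
    def test_planar_points_embed_with_negligible_stress(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 2))
        dm = skbio.DistanceMatrix(squareform(pdist(pts)))
        result = nmds(dm, seed=0, restarts=8)
        assert result.stress < 1e-3

    def test_three_points_always_embeddable(self):
        dm = skbio.DistanceMatrix(squareform(pdist(np.random.default_rng(2).normal(size=(3, 4)))))
        assert nmds(dm, seed=0).stress < 1e-6

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, size=(8, 20))
        x[:, 0] = 1
        dm = pairwise_braycurtis(x)
        a = nmds(dm, seed=7, restarts=5)
        b = nmds(dm, seed=7, restarts=5)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_all_equal_distances_flagged_degenerate(self):
        dm = skbio.DistanceMatrix(np.ones((4, 4)) - np.eye(4))
        result = nmds(dm, seed=0)
        assert result.degenerate and result.stress == 0.0


class TestOneWayPermanova:
    def test_equals_classical_anova_f_on_univariate_euclidean(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=24)
        labels = np.repeat(["a", "b", "c"], 8)
        table = permanova_oneway(pairwise_euclidean(y[:, None]), labels, n_perm=9, seed=0)
        f_ref = stats.f_oneway(*(y[labels == g] for g in "abc")).statistic
        assert table.row("Groups")["pseudo_F"] == pytest.approx(f_ref, abs=1e-9)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, size=(15, 25))
        x[:, 0] = 1
        labels = np.repeat(["u", "v", "w"], 5)
        dm = pairwise_braycurtis(x)
        mine = permanova_oneway(dm, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(dm, grouping=list(labels), permutations=99)
        assert mine.row("Groups")["pseudo_F"] == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_df_ledger_and_ss_additivity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(22, 3))
        labels = ["a"] * 10 + ["b"] * 7 + ["c"] * 5
        table = permanova_oneway(pairwise_euclidean(x), labels, n_perm=9, seed=0).to_frame()
        df = table.set_index("source")["df"]
        assert df["Groups"] + df["Residual"] == df["Total"] == 21
        ss = table.set_index("source")["SS"]
        assert ss["Groups"] + ss["Residual"] == pytest.approx(ss["Total"], abs=1e-9)

    def test_p_invariant_to_group_renaming(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, size=(12, 18))
        x[:, 0] = 1
        dm = pairwise_braycurtis(x)
        labels = np.repeat(["a", "b"], 6)
        renamed = np.where(labels == "a", "zebra", "ant")
        p1 = permanova_oneway(dm, labels, n_perm=199, seed=3).row("Groups")["p_perm"]
        p2 = permanova_oneway(dm, renamed, n_perm=199, seed=3).row("Groups")["p_perm"]
        assert p1 == p2

    def test_degenerate_all_zero_distances_flagged(self):
        dm = skbio.DistanceMatrix(np.zeros((4, 4)))
        table = permanova_oneway(dm, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert table.degenerate
        assert table.row("Total")["SS"] == 0.0

    def test_single_group_rejected(self):
        dm = skbio.DistanceMatrix(np.zeros((3, 3)))
        with pytest.raises(ValidationError):
            permanova_oneway(dm, ["a", "a", "a"], n_perm=9)


def _nested_univariate_oracle(y, region, site):
    """Textbook balanced nested random-effects ANOVA from raw data."""
    frame = pd.DataFrame({"y": y, "region": region, "site": site})
    gm = frame["y"].mean()
    r_means = frame.groupby("region")["y"].mean()
    s_means = frame.groupby(["region", "site"])["y"].mean()
    n_per_site = frame.groupby(["region", "site"]).size().iloc[0]
    sites_per_region = s_means.groupby("region").size().iloc[0]
    ss_region = n_per_site * sites_per_region * ((r_means - gm) ** 2).sum()
    region_of_site = r_means.reindex(s_means.index.get_level_values(0)).to_numpy()
    ss_site = n_per_site * ((s_means.to_numpy() - region_of_site) ** 2).sum()
    fitted = frame.set_index(["region", "site"]).index.map(s_means)
    ss_resid = ((frame["y"].to_numpy() - np.asarray(fitted)) ** 2).sum()
    return ss_region, ss_site, ss_resid, n_per_site, sites_per_region


class TestNestedPermanova:
    @staticmethod
    def _balanced(seed=8, n_regions=3, n_sites=3, n_rep=4):
        rng = np.random.default_rng(seed)
        region = np.repeat([f"R{i}" for i in range(n_regions)], n_sites * n_rep)
        site = np.repeat(
            [f"S{i}{j}" for i in range(n_regions) for j in range(n_sites)], n_rep
        )
        y = (
            np.repeat(rng.normal(0, 2, n_regions), n_sites * n_rep)
            + np.repeat(rng.normal(0, 1.5, n_regions * n_sites), n_rep)
            + rng.normal(0, 1, n_regions * n_sites * n_rep)
        )
        return y, region, site

    def test_balanced_df_ledger(self):
        y, region, site = self._balanced()
        table = permanova_nested(pairwise_euclidean(y[:, None]), region, site, n_perm=9, seed=0)
        df = table.to_frame().set_index("source")["df"]
        assert df.tolist() == [2, 6, 27, 35]

    def test_matches_univariate_nested_anova(self):
        y, region, site = self._balanced()
        table = permanova_nested(pairwise_euclidean(y[:, None]), region, site, n_perm=9, seed=0)
        ss_r, ss_s, ss_e, n, s = _nested_univariate_oracle(y, region, site)
        assert table.row("Region")["SS"] == pytest.approx(ss_r, abs=1e-8)
        assert table.row("Site(Region)")["SS"] == pytest.approx(ss_s, abs=1e-8)
        assert table.row("Residual")["SS"] == pytest.approx(ss_e, abs=1e-8)
        ms_r, ms_s, ms_e = ss_r / 2, ss_s / 6, ss_e / 27
        assert table.row("Region")["pseudo_F"] == pytest.approx(ms_r / ms_s, abs=1e-10)
        assert table.row("Site(Region)")["pseudo_F"] == pytest.approx(ms_s / ms_e, abs=1e-10)
        # EMS ladder: VC_site = (MS_S - MS_E)/n, VC_region = (MS_R - MS_E - n*VC_site)/(n*s)
        vc_s = (ms_s - ms_e) / n
        vc_r = (ms_r - ms_e - n * vc_s) / (n * s)
        assert table.row("Site(Region)")["VC"] == pytest.approx(vc_s, abs=1e-10)
        assert table.row("Region")["VC"] == pytest.approx(vc_r, abs=1e-10)
        assert table.row("Residual")["VC"] == pytest.approx(ms_e, abs=1e-10)

    def test_vc_sum_reconstructs_total_variance_univariate(self):
        # with all VCs positive the EMS ladder decomposes the total variance
        y, region, site = self._balanced(seed=12)
        table = permanova_nested(pairwise_euclidean(y[:, None]), region, site, n_perm=0)
        vcs = table.to_frame().set_index("source")["VC"]
        if (vcs[["Region", "Site(Region)", "Residual"]] > 0).all():
            ss_r, ss_s, ss_e, n, s = _nested_univariate_oracle(y, region, site)
            # expectation check: observed mean squares reproduce through the ladder
            ms = {"Region": ss_r / 2, "Site(Region)": ss_s / 6, "Residual": ss_e / 27}
            assert ms["Site(Region)"] == pytest.approx(
                vcs["Residual"] + n * vcs["Site(Region)"], abs=1e-8
            )
            assert ms["Region"] == pytest.approx(
                vcs["Residual"] + n * vcs["Site(Region)"] + n * s * vcs["Region"], abs=1e-8
            )

    def test_unbalanced_df_ledger(self, hierarchy_table):
        # drop two replicates to unbalance the design
        table = hierarchy_table.drop(index=[0, 5]).reset_index(drop=True)
        x, _ = replicate_matrix(table)
        dm = pairwise_braycurtis(x)
        result = permanova_nested(dm, table["region"], table["site"], n_perm=9, seed=0)
        df = result.to_frame().set_index("source")["df"]
        n = len(table)
        assert df["Region"] == 2 and df["Site(Region)"] == 6
        assert df["Residual"] == n - 9
        assert df[["Region", "Site(Region)", "Residual"]].sum() == df["Total"] == n - 1

    def test_region_with_single_site_rejected(self):
        y = np.arange(8.0)
        region = ["A"] * 4 + ["B"] * 4
        site = ["A1", "A1", "A2", "A2", "B1", "B1", "B1", "B1"]
        with pytest.raises(ValidationError, match="pool"):
            permanova_nested(pairwise_euclidean(y[:, None]), region, site, n_perm=9)

    def test_p_values_reproducible_and_in_range(self, hierarchy_table):
        x, _ = replicate_matrix(hierarchy_table)
        dm = pairwise_braycurtis(x)
        args = (dm, hierarchy_table["region"], hierarchy_table["site"])
        a = permanova_nested(*args, n_perm=199, seed=42)
        b = permanova_nested(*args, n_perm=199, seed=42)
        for source in ("Region", "Site(Region)"):
            p1, p2 = a.row(source)["p_perm"], b.row(source)["p_perm"]
            assert p1 == p2
            assert 0 < p1 <= 1

    def test_unrestricted_scheme_runs(self, hierarchy_table):
        x, _ = replicate_matrix(hierarchy_table)
        dm = pairwise_braycurtis(x)
        result = permanova_nested(
            dm, hierarchy_table["region"], hierarchy_table["site"],
            n_perm=99, seed=1, scheme="unrestricted",
        )
        assert 0 < result.row("Region")["p_perm"] <= 1


class TestVcToDiss:
    def test_published_value_pairs(self):
        assert vc_to_diss(669.28) == pytest.approx(25.87, abs=0.005)
        assert vc_to_diss(558.22) == pytest.approx(23.63, abs=0.005)

    def test_zero_and_negative(self):
        assert vc_to_diss(0.0) == 0.0
        assert vc_to_diss(-4.0) == pytest.approx(-2.0)
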