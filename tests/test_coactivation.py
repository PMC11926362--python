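"""Co-activation: Pearson matrices, Ward clustering, Mann-Whitney."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from iegnet import (
    CorrelationMatrix,
    ValidationError,
    default_panel,
    mann_whitney,
    pearson_matrix,
    rvalue_compare,
    select_pairs,
    ward_cluster,
)


def _activation_from_wide(wide, group="vehicle", marker="H1a"):
    long = wide.reset_index().melt(
        id_vars="index", var_name="region", value_name="pct_positive"
    ).rename(columns={"index": "animal_id"})
    long["group"] = group
    long["marker"] = marker
    return long


def _wide(panel, columns, n=6):
    """Animals x regions table; unset regions get iid noise."""
    rng = np.random.default_rng(123)
    if columns:
        n = len(next(iter(columns.values())))
    data = {r: rng.normal(10, 2, n) for r in panel.region_ids}
    data.update({k: np.asarray(v, float) for k, v in columns.items()})
    return pd.DataFrame(data, index=[f"a{i}" for i in range(n)])


class TestPearsonMatrix:
    def test_affine_dependence_gives_r_one(self, panel):
        wide = _wide(panel, {})
        wide["lowDG"] = 2 * wide["upDG"] + 1
        cm = pearson_matrix(_activation_from_wide(wide), "vehicle", "H1a", panel)
        assert cm.matrix.at["upDG", "lowDG"] == pytest.approx(1.0)

    def test_negation_gives_r_minus_one(self, panel):
        wide = _wide(panel, {})
        wide["lowDG"] = -wide["upDG"]
        cm = pearson_matrix(_activation_from_wide(wide), "vehicle", "H1a", panel)
        assert cm.matrix.at["upDG", "lowDG"] == pytest.approx(-1.0)

    def test_product_moment_formula_example(self, panel):
        wide = _wide(panel, {"upDG": [1, 2, 3, 4], "lowDG": [1, 3, 2, 4]})
        cm = pearson_matrix(_activation_from_wide(wide), "vehicle", "H1a", panel)
        assert cm.matrix.at["upDG", "lowDG"] == pytest.approx(0.8)

    def test_positive_affine_invariance(self, panel, activation):
        cm1 = pearson_matrix(activation, "vehicle", "H1a", panel)
        scaled = activation.copy()
        mask = (scaled["region"] == "upDG")
        scaled.loc[mask, "pct_positive"] = 0.3 * scaled.loc[mask, "pct_positive"] + 2
        cm2 = pearson_matrix(scaled, "vehicle", "H1a", panel)
        np.testing.assert_allclose(
            cm1.matrix.to_numpy(), cm2.matrix.to_numpy(), atol=1e-12)

    def test_zero_variance_region_flagged_undefined(self, panel):
        wide = _wide(panel, {"upDG": [5, 5, 5, 5, 5]})
        cm = pearson_matrix(_activation_from_wide(wide), "vehicle", "H1a", panel)
        off = cm.matrix.loc["upDG"].drop("upDG")
        assert off.isna().all()
        assert cm.matrix.at["upDG", "upDG"] == 1.0

    def test_pairwise_complete_with_missing_cell(self, panel):
        wide = _wide(panel, {})
        long = _activation_from_wide(wide)
        # drop one animal x region observation entirely
        long = long[~((long["animal_id"] == "a0") & (long["region"] == "upDG"))]
        cm = pearson_matrix(long, "vehicle", "H1a", panel)
        sub = wide.drop(index="a0")
        expected = stats.pearsonr(sub["upDG"], sub["lowDG"]).statistic
        assert cm.matrix.at["upDG", "lowDG"] == pytest.approx(expected)

    def test_matrix_shape_and_symmetry(self, activation, panel):
        cm = pearson_matrix(activation, "iso", "Arc", panel)
        m = cm.matrix.to_numpy()
        assert m.shape == (14, 14)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert cm.n_animals == 10


def _ward_oracle(d):
    """Naive O(n^3) agglomerative Ward via the Lance-Williams update."""
    n = d.shape[0]
    d = d.astype(float).copy()
    active = {i: 1 for i in range(n)}  # cluster -> size
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(
            ((tuple(sorted(k)), v) for k, v in dist.items()
             if all(c in active for c in k)),
            key=lambda kv: kv[1],
        )
        heights.append(h)
        si, sj = active.pop(i), active.pop(j)
        for k, sk in list(active.items()):
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dij = h
            new = np.sqrt(
                ((sk + si) * dik**2 + (sk + sj) * djk**2 - sk * dij**2)
                / (si + sj + sk)
            )
            dist[frozenset((next_id, k))] = new
        dist.pop(frozenset((i, j)))
        active[next_id] = si + sj
        next_id += 1
    return np.array(heights)


def _corr_from_array(m, labels, group="vehicle", marker="H1a"):
    dfm = pd.DataFrame(m, index=labels, columns=labels)
    return CorrelationMatrix(group, marker, dfm, 10)


class TestWardCluster:
    def test_two_perfect_blocks_merge_within_first(self, panel):
        regions = panel.region_ids
        block = [0] * 7 + [1] * 7
        m = np.array([[1.0 if bi == bj else -1.0
                       for bj in block] for bi in block])
        np.fill_diagonal(m, 1.0)
        dendro = ward_cluster(_corr_from_array(m, regions))
        two = dendro.cut(2)
        left = {r for r, c in two.items() if c == two[regions[0]]}
        assert left == set(regions[:7])
        # final merge joins the blocks at the largest height
        assert np.argmax(dendro.merges[:, 2]) == 12

    def test_equal_offdiagonals_merge_at_equal_first_height(self, panel):
        m = np.full((14, 14), 0.4)
        np.fill_diagonal(m, 1.0)
        dendro = ward_cluster(_corr_from_array(m, panel.region_ids))
        first = dendro.merges[0, 2]
        # all singleton-singleton merges share the same dissimilarity
        singleton_merges = dendro.merges[
            (dendro.merges[:, 0] < 14) & (dendro.merges[:, 1] < 14), 2]
        assert singleton_merges[0] == pytest.approx(first)

    def test_merge_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(-0.5, 0.9, (5, 5))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        labels = list("abcde")
        dendro = ward_cluster(_corr_from_array(np.clip(m, -1, 1), labels))
        d = 1.0 - np.clip(m, -1, 1)
        np.fill_diagonal(d, 0.0)
        np.testing.assert_allclose(
            dendro.merges[:, 2], _ward_oracle(d), rtol=1e-9)

    def test_merge_heights_nondecreasing(self, activation, panel):
        cm = pearson_matrix(activation, "vehicle", "Arc", panel)
        dendro = ward_cluster(cm)
        heights = dendro.merges[:, 2]
        assert len(heights) == 13
        assert (np.diff(heights) >= -1e-12).all()

    def test_leaf_input_order_invariance(self, activation, panel):
        cm = pearson_matrix(activation, "vehicle", "H1a", panel)
        perm = list(reversed(cm.regions))
        cm_perm = CorrelationMatrix(
            "vehicle", "H1a", cm.matrix.loc[perm, perm], cm.n_animals)
        h1 = ward_cluster(cm).merges[:, 2]
        h2 = ward_cluster(cm_perm).merges[:, 2]
        np.testing.assert_allclose(h1, h2, rtol=1e-9)

    def test_undefined_entries_rejected(self, panel):
        m = np.eye(14)
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValidationError, match="undefined"):
            ward_cluster(_corr_from_array(m, panel.region_ids))


class TestMannWhitney:
    def test_complete_separation_gives_max_u(self):
        res = mann_whitney([5, 6, 7], [1, 2, 3, 4])
        assert res.statistic == 12  # n_x * n_y

    def test_u_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            ux = mann_whitney(x, y).statistic
            uy = mann_whitney(y, x).statistic
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_small_sample_enumeration_oracle(self):
        """x=(1,2,4), y=(3,5): U and exact p from all C(5,2) assignments."""
        x, y = [1, 2, 4], [3, 5]
        res = mann_whitney(x, y)
        pooled = np.array(x + y, float)
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        assert res.statistic == u_obs
        center = 3 * 2 / 2
        hits = total = 0
        for idx in combinations(range(5), 3):
            u = sum(ranks[i] for i in idx) - 3 * 4 / 2
            total += 1
            hits += abs(u - center) >= abs(u_obs - center) - 1e-9
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            res = mann_whitney(x, y)
            sp = stats.mannwhitneyu(x, y, method="exact")
            assert res.statistic == pytest.approx(sp.statistic)
            assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    def test_all_tied_gives_p_one(self):
        res = mann_whitney([3, 3, 3], [3, 3])
        assert res.p_value == 1.0
        assert res.direction == "none"
        # large-sample path too
        res = mann_whitney([3.0] * 25, [3.0] * 25)
        assert res.p_value == 1.0

    def test_asymptotic_path_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 30)  # n_x*n_y = 900 > exact limit
        res = mann_whitney(x, y)
        sp = stats.mannwhitneyu(x, y, method="asymptotic")
        assert res.statistic == pytest.approx(sp.statistic)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    @given(
        x=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        y=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_u_identity_and_p_range_hold_generally(self, x, y):
        """U_x + U_y = n_x * n_y and p in (0, 1] on arbitrary integer
        samples, ties included."""
        res_xy = mann_whitney(x, y)
        res_yx = mann_whitney(y, x)
        assert res_xy.statistic + res_yx.statistic == pytest.approx(
            len(x) * len(y))
        assert 0 < res_xy.p_value <= 1
        assert res_xy.p_value == pytest.approx(res_yx.p_value, abs=1e-12)


class TestRValueCompare:
    def test_pair_counts(self, panel):
        assert len(select_pairs(panel, "all")) == 91
        assert len(select_pairs(panel, "hippocampus")) == 63  # C(6,2) + 6*8
        assert len(select_pairs(panel, "RSC")) == 25
        assert len(select_pairs(panel, "PFC")) == 36
        assert len(select_pairs(panel, "thalamus")) == 36

    def test_identical_matrices_not_significant(self, activation, panel):
        cm = pearson_matrix(activation, "vehicle", "H1a", panel)
        res = rvalue_compare(cm, cm, "all", panel)
        assert res.p_value > 0.9
        assert res.direction == "none"
        assert res.arrow_code == "="

    def test_all_uses_91_values_per_group(self, activation, panel):
        a = pearson_matrix(activation, "vehicle", "H1a", panel)
        b = pearson_matrix(activation, "iso", "H1a", panel)
        res = rvalue_compare(a, b, "all", panel)
        assert 0 <= res.statistic <= 91 * 91

    def test_unknown_pair_set_rejected(self, activation, panel):
        cm = pearson_matrix(activation, "vehicle", "H1a", panel)
        with pytest.raises(ValidationError, match="empty pair set"):
            rvalue_compare(cm, cm, "cerebellum", panel)
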