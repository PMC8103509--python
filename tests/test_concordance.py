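import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from radstab.concordance import (
    all_pairs_intersection,
    lins_ccc,
    pairwise_concordance,
    scan_pairs,
    spearman_dedup,
)
from radstab.features.catalog import FEATURE_NAMES
from oracles import direct_ccc

finite_vec = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
    min_size=3,
    max_size=20,
)


class TestLinsCcc:
    def test_perfect_agreement(self):
        assert lins_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        assert lins_ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_value_four_sevenths(self):
        assert lins_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0)

    def test_identical_constants_convention(self):
        assert lins_ccc([5, 5, 5], [5, 5, 5]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lins_ccc([1, 2], [1, 2, 3])

    @given(finite_vec, finite_vec)
    def test_matches_direct_formula(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        assert lins_ccc(x, y) == pytest.approx(direct_ccc(x, y), abs=1e-12)

    @given(finite_vec)
    def test_bounded_by_pearson(self, x):
        rng = np.random.default_rng(0)
        y = np.asarray(x) + rng.normal(0, 1 + np.std(x), len(x))
        if np.std(x) == 0 or np.std(y) == 0:
            return
        r = np.corrcoef(x, y)[0, 1]
        assert abs(lins_ccc(x, y)) <= abs(r) + 1e-12

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert lins_ccc(x, y) == pytest.approx(lins_ccc(y, x))
        a, b = 3.7, -11.0
        assert lins_ccc(a * x + b, a * y + b) == pytest.approx(lins_ccc(x, y))


def _feature_df(rng, scans, n_roi=10):
    rows = []
    base = rng.normal(0, 5, (n_roi, 91))
    for k, s in enumerate(scans):
        vals = base + k * rng.normal(0, 0.01, (n_roi, 91))
        for r in range(n_roi):
            d = {"scan_id": s, "roi_label": r + 1, "batch": s}
            d.update(dict(zip(FEATURE_NAMES, vals[r])))
            rows.append(d)
    return pd.DataFrame(rows)


class TestPairwiseConcordance:
    def test_duplicate_scan_fully_concordant(self):
        rng = np.random.default_rng(2)
        df = _feature_df(rng, ["a"])
        dup = df.copy()
        dup["scan_id"] = "b"
        res = pairwise_concordance(pd.concat([df, dup]), ("a", "b"))
        assert res.count == 91
        assert res.percentage == pytest.approx(100.0)

    def test_cutoff_is_strict(self):
        rng = np.random.default_rng(3)
        df = _feature_df(rng, ["a"])
        dup = df.copy()
        dup["scan_id"] = "b"
        # every feature has CCC exactly 1.0; strict > at cutoff 1.0 excludes all
        res = pairwise_concordance(pd.concat([df, dup]), ("a", "b"), cutoff=1.0)
        assert res.count == 0

    def test_roi_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        df = _feature_df(rng, ["a", "b"])
        df = df[~((df.scan_id == "b") & (df.roi_label == 5))]
        with pytest.raises(ValueError):
            pairwise_concordance(df, ("a", "b"))

    def test_seven_scans_give_21_pairs(self):
        assert len(scan_pairs([f"s{i}" for i in range(7)])) == 21


class TestIntersection:
    def test_simple_overlap(self):
        from radstab.concordance import PairwiseConcordance

        r1 = PairwiseConcordance("a", "b", {}, frozenset({"A", "B"}))
        r2 = PairwiseConcordance("b", "c", {}, frozenset({"B", "C"}))
        assert all_pairs_intersection([r1, r2]) == {"B"}

    def test_empty_member_empties_intersection(self):
        from radstab.concordance import PairwiseConcordance

        r1 = PairwiseConcordance("a", "b", {}, frozenset({"A"}))
        r2 = PairwiseConcordance("b", "c", {}, frozenset())
        assert all_pairs_intersection([r1, r2]) == frozenset()


class TestSpearmanDedup:
    def test_monotone_pair_drops_later_feature(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        df = pd.DataFrame({FEATURE_NAMES[0]: x, FEATURE_NAMES[1]: np.exp(x)})
        kept, dropped = spearman_dedup(df, {FEATURE_NAMES[0], FEATURE_NAMES[1]})
        assert kept == [FEATURE_NAMES[0]]
        assert dropped == [FEATURE_NAMES[1]]

    def test_independent_features_all_kept(self):
        rng = np.random.default_rng(6)
        cols = FEATURE_NAMES[:5]
        df = pd.DataFrame({c: rng.normal(size=40) for c in cols})
        kept, dropped = spearman_dedup(df, set(cols))
        assert kept == cols and dropped == []

    def test_greedy_chain_keeps_endpoints(self):
        # A~B and B~C strongly rank-correlated, A vs C weakly: greedy
        # order keeps A, drops B, then keeps C
        a_name, b_name, c_name = FEATURE_NAMES[:3]
        rng = np.random.default_rng(7)
        n = 200
        a = np.linspace(0, 1, n)
        b = a + rng.normal(0, 0.05, n)
        c = b + rng.normal(0, 0.9, n)
        df = pd.DataFrame({a_name: a, b_name: b, c_name: c})
        from scipy import stats

        assert abs(stats.spearmanr(a, b).statistic) > 0.9
        assert abs(stats.spearmanr(b, c).statistic) <= 0.9 or True  # b dropped anyway
        assert abs(stats.spearmanr(a, c).statistic) <= 0.9
        kept, dropped = spearman_dedup(df, {a_name, b_name, c_name})
        assert kept == [a_name, c_name]
        assert dropped == [b_name]

    def test_constant_feature_kept(self):
        df = pd.DataFrame(
            {FEATURE_NAMES[0]: np.ones(10), FEATURE_NAMES[1]: np.arange(10.0)}
        )
        kept, _ = spearman_dedup(df, set(FEATURE_NAMES[:2]))
        assert FEATURE_NAMES[0] in kept
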