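"""Discretization, scaling, SMOTE and correlation-based feature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermolesion.prep import (
    LABEL_COLUMN,
    apply_cuts,
    cfs_merit,
    cfs_select,
    mdlp_discretize,
    normality_route,
    scale_minmax,
    scale_zscore,
    smote,
    symmetric_uncertainty,
)


# ----------------------------------------------------------- MDLP oracle
def oracle_mdlp(values, labels):
    """Independent recursive minimal-entropy splitter with the MDL stop."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]

    def ent(lbls):
        if len(lbls) == 0:
            return 0.0
        _, c = np.unique(lbls, return_counts=True)
        p = c / c.sum()
        return float(-(p * np.log2(p)).sum())

    def rec(v, y):
        n = len(v)
        hs = ent(y)
        if n < 2 or hs == 0:
            return []
        best = None
        for i in range(1, n):
            if v[i] == v[i - 1]:
                continue
            e = (i * ent(y[:i]) + (n - i) * ent(y[i:])) / n
            if best is None or e < best[0]:
                best = (e, i)
        if best is None:
            return []
        _, i = best
        gain = hs - best[0]
        c = len(set(y))
        c1, c2 = len(set(y[:i])), len(set(y[i:]))
        delta = np.log2(3**c - 2) - (c * hs - c1 * ent(y[:i]) - c2 * ent(y[i:]))
        if gain <= (np.log2(n - 1) + delta) / n:
            return []
        cut = (v[i - 1] + v[i]) / 2
        return rec(v[:i], y[:i]) + [cut] + rec(v[i:], y[i:])

    return sorted(rec(v, y))


class TestMDLP:
    def test_perfectly_separated_single_cut(self, rng):
        v = np.concatenate([rng.normal(0, 1, 40), rng.normal(20, 1, 40)])
        y = np.array(["A"] * 40 + ["B"] * 40)
        cuts = mdlp_discretize(v, y)
        assert len(cuts) == 1
        assert 5 < cuts[0] < 15

    def test_random_labels_no_cuts(self, rng):
        v = rng.normal(0, 1, 50)
        y = rng.choice(["A", "B"], 50)
        assert mdlp_discretize(v, y) == []

    def test_constant_feature_no_cuts(self):
        v = np.zeros(30)
        y = np.array(["A", "B"] * 15)
        assert mdlp_discretize(v, y) == []

    def test_matches_oracle_on_small_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            v = np.round(rng.normal(0, 2, n), 1)
            y = rng.choice(["A", "B", "C"], n)
            assert mdlp_discretize(v, y) == pytest.approx(oracle_mdlp(v, y))

    def test_apply_cuts_bins(self):
        codes = apply_cuts(np.array([0.0, 1.0, 2.0, 3.0]), [0.5, 2.5])
        assert codes.tolist() == [0, 1, 1, 2]


class TestScaling:
    def test_zscore_properties(self, rng):
        x = rng.normal(10, 2, 200)
        z = scale_zscore(x)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        s = x.std(ddof=1)
        assert scale_zscore(np.array([x.mean() + 3 * s]), x.mean(), s)[0] == pytest.approx(1.0)

    def test_zscore_constant_zeros(self):
        assert (scale_zscore(np.full(5, 3.0)) == 0).all()

    def test_minmax_endpoints_and_midpoint(self):
        x = np.array([2.0, 4.0, 6.0])
        assert scale_minmax(x).tolist() == [-1.0, 0.0, 1.0]

    def test_minmax_constant_zeros(self):
        assert (scale_minmax(np.full(5, 3.0)) == 0).all()

    def test_normality_routing(self, rng):
        assert normality_route(rng.normal(0, 1, 500)) == "zscore"
        assert normality_route(rng.uniform(0, 1, 500)) == "minmax"
        assert normality_route(rng.normal(0, 1, 5)) == "minmax"  # small-sample guard


class TestSMOTE:
    def _table(self, counts, n_feat=3, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for cls, n in counts.items():
            df = pd.DataFrame(rng.normal(0, 1, (n, n_feat)),
                              columns=[f"f{i}" for i in range(n_feat)])
            df[LABEL_COLUMN] = cls
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_balanced_table_unchanged(self):
        t = self._table({"A": 10, "B": 10})
        out = smote(t, seed=1)
        assert len(out) == len(t)
        pd.testing.assert_frame_equal(out, t)

    def test_atlas_imbalance_rebalanced(self):
        t = self._table({"CN": 100, "BN": 70, "SN": 70, "MM": 60})
        out = smote(t, seed=1)
        assert out[LABEL_COLUMN].value_counts().to_dict() == {
            "CN": 100, "BN": 100, "SN": 100, "MM": 100
        }
        # originals preserved verbatim
        pd.testing.assert_frame_equal(out.iloc[: len(t)], t)

    def test_two_point_minority_on_segment(self):
        t = self._table({"A": 20, "B": 2})
        out = smote(t, seed=3)
        synth = out.iloc[len(t):]
        a, b = t[t[LABEL_COLUMN] == "B"].iloc[0, :3], t[t[LABEL_COLUMN] == "B"].iloc[1, :3]
        for _, row in synth.iterrows():
            u = (row.iloc[:3] - a) / (b - a)
            assert np.allclose(u, u.iloc[0])  # collinear
            assert -1e-9 <= u.iloc[0] <= 1 + 1e-9

    def test_convex_hull_bounds(self):
        t = self._table({"A": 30, "B": 8})
        out = smote(t, seed=5)
        for cls in ("A", "B"):
            orig = t[t[LABEL_COLUMN] == cls].iloc[:, :3]
            new = out[out[LABEL_COLUMN] == cls].iloc[:, :3]
            assert (new.min() >= orig.min() - 1e-9).all()
            assert (new.max() <= orig.max() + 1e-9).all()

    def test_singleton_class_rejected(self):
        t = self._table({"A": 10, "B": 1})
        with pytest.raises(ValueError):
            smote(t, seed=0)


class TestSymmetricUncertainty:
    def oracle_su(self, x, y):
        def H(z):
            _, c = np.unique(z, return_counts=True)
            p = c / c.sum()
            return -(p * np.log2(p)).sum()

        pairs = [f"{a}|{b}" for a, b in zip(x, y)]
        hx, hy, hxy = H(np.asarray(x)), H(np.asarray(y)), H(np.asarray(pairs))
        if hx + hy == 0:
            return 0.0
        return 2 * (hx + hy - hxy) / (hx + hy)

    def test_identical_nonconstant_is_one(self):
        x = np.array([0, 1, 1, 2, 0])
        assert symmetric_uncertainty(x, x) == pytest.approx(1.0)

    def test_independent_product_table_zero(self):
        x = np.repeat([0, 1], 8)
        y = np.tile([0, 1], 8)
        assert symmetric_uncertainty(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_small_contingency_oracle(self):
        # 2x2 table [[2,1],[1,2]]
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        assert symmetric_uncertainty(x, y) == pytest.approx(self.oracle_su(x, y))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=40))
    def test_symmetry_range_oracle(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        su = symmetric_uncertainty(x, y)
        assert su == pytest.approx(symmetric_uncertainty(y, x), abs=1e-12)
        assert -1e-9 <= su <= 1 + 1e-9
        assert su == pytest.approx(self.oracle_su(x, y), abs=1e-12)


class TestCFS:
    def test_merit_single_feature(self):
        assert cfs_merit(["f"], {"f": 0.42}, lambda a, b: 0.0) == pytest.approx(0.42)

    def test_merit_two_uncorrelated(self):
        m = cfs_merit(["a", "b"], {"a": 0.5, "b": 0.5}, lambda a, b: 0.0)
        assert m == pytest.approx(2 * 0.5 / np.sqrt(2))

    def test_duplicate_feature_never_increases_merit(self, rng):
        for _ in range(20):
            su_c = {"a": rng.uniform(0.2, 0.9)}
            su_c["dup"] = su_c["a"]
            base = cfs_merit(["a"], su_c, lambda x, y: 1.0)
            extended = cfs_merit(["a", "dup"], su_c, lambda x, y: 1.0)
            assert extended <= base + 1e-12

    def _noisy_table(self, rng, n=120):
        y = rng.choice(["BN", "CN", "MM", "SN"], n)
        t = pd.DataFrame({
            "signal": np.where(y == "MM", 10.0, 0.0) + rng.normal(0, 0.1, n),
            "noise1": rng.normal(0, 1, n),
            "noise2": rng.normal(0, 1, n),
        })
        t[LABEL_COLUMN] = y
        return t

    def test_predictive_feature_selected_first(self, rng):
        sub = cfs_select(self._noisy_table(rng))
        assert sub.features[0] == "signal"

    def test_duplicated_predictive_feature_enters_once(self, rng):
        t = self._noisy_table(rng)
        t["signal_copy"] = t["signal"]
        sub = cfs_select(t)
        assert ("signal" in sub.features) != ("signal_copy" in sub.features) or (
            len([f for f in sub.features if f.startswith("signal")]) == 1
        )

    def test_all_noise_low_merit(self, rng):
        y = rng.choice(["A", "B"], 100)
        t = pd.DataFrame({f"n{i}": rng.normal(0, 1, 100) for i in range(10)})
        t[LABEL_COLUMN] = y
        sub = cfs_select(t, k_max=20)
        assert sub.merit <= 0.2
        assert len(sub.features) <= 20

    def test_informative_outrank_noise_on_synthetic_table(self):
        from dermolesion.synth import TableSpec, gen_feature_table

        t = gen_feature_table(TableSpec(n_informative=5, n_noise=20, seed=11))
        sub = cfs_select(t, k_max=10)
        assert set(sub.features[:5]) <= {f"inf_{i:02d}" for i in range(5)}
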