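"""Symmetric uncertainty, MDL discretization and the predominance rule."""

import collections
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csnbstack import LabeledDataset, fcbf_select, mdl_discretize, symmetric_uncertainty


def su_bruteforce(x, y):
    """Independent SU oracle built on plain Counter/math entropies."""

    def h(seq):
        n = len(seq)
        return -sum(
            c / n * math.log2(c / n) for c in collections.Counter(seq).values()
        )

    hx, hy = h(list(x)), h(list(y))
    hxy = h(list(zip(x, y)))
    if hx + hy == 0:
        return 0.0
    return 2.0 * (hx + hy - hxy) / (hx + hy)


class TestSymmetricUncertainty:
    def test_identical_sequences_give_one(self):
        assert symmetric_uncertainty([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_independent_sequences_give_zero(self):
        assert symmetric_uncertainty([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_hand_derived_joint(self):
        # joint counts {(0,0):2,(0,1):1,(1,0):1,(1,1):2} over 6 samples:
        # H(X)=H(Y)=1, H(X,Y)=1.9183 bits -> SU = 0.0817
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert symmetric_uncertainty(x, y) == pytest.approx(0.0817, abs=5e-5)
        assert symmetric_uncertainty(x, y) == pytest.approx(su_bruteforce(x, y))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            symmetric_uncertainty([0, 1], [0, 1, 0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=40),
        st.data(),
    )
    def test_symmetry_and_range(self, x, data):
        y = data.draw(st.lists(st.integers(0, 3), min_size=len(x), max_size=len(x)))
        a = symmetric_uncertainty(x, y)
        b = symmetric_uncertainty(y, x)
        assert abs(a - b) < 1e-12
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(su_bruteforce(x, y), abs=1e-9)


def mdl_oracle(values, labels):
    """Exhaustive-search MDL oracle: evaluates the acceptance rule at every
    boundary between distinct adjacent sorted values, recursively."""

    def ent(lab):
        n = len(lab)
        if n == 0:
            return 0.0
        return -sum(
            c / n * math.log2(c / n) for c in collections.Counter(lab).values()
        )

    def split(pairs):
        n = len(pairs)
        vals = sorted(set(v for v, _ in pairs))
        if len(vals) < 2:
            return None
        es = ent([l for _, l in pairs])
        best = None  # (gain, cut)
        for i in range(len(vals) - 1):
            cut = (vals[i] + vals[i + 1]) / 2.0
            left = [l for v, l in pairs if v <= cut]
            right = [l for v, l in pairs if v > cut]
            gain = es - (len(left) * ent(left) + len(right) * ent(right)) / n
            if best is None or gain > best[0] + 1e-12:
                best = (gain, cut, left, right)
        gain, cut, left, right = best
        k = len(set(l for _, l in pairs))
        k1, k2 = len(set(left)), len(set(right))
        delta = math.log2(3**k - 2) - (k * es - k1 * ent(left) - k2 * ent(right))
        if gain <= (math.log2(n - 1) + delta) / n or gain <= 0:
            return None
        return cut

    cuts = []

    def recurse(pairs):
        cut = split(pairs)
        if cut is None:
            return
        cuts.append(cut)
        recurse([(v, l) for v, l in pairs if v <= cut])
        recurse([(v, l) for v, l in pairs if v > cut])

    recurse(list(zip(values, labels)))
    return sorted(cuts)


class TestMdlDiscretize:
    def test_perfect_separation_with_gap(self):
        d = mdl_discretize([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert len(d.cut_points) == 1
        assert 3 < d.cut_points[0] < 10
        assert d.codes.tolist() == [0, 0, 0, 1, 1, 1]

    def test_label_independent_values_give_single_bin(self):
        d = mdl_discretize(list(range(8)), [0, 1, 0, 1, 0, 1, 0, 1])
        assert len(d.cut_points) == 0
        assert d.n_bins == 1

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 31))
            values = rng.choice(np.linspace(0, 5, 8), size=n)
            labels = rng.integers(0, 2, size=n)
            got = mdl_discretize(values, labels).cut_points.tolist()
            want = mdl_oracle(values.tolist(), labels.tolist())
            assert got == pytest.approx(want)


class TestFcbfSelect:
    def _fixture(self):
        """F1 = label copy, F2 = copy of F1, F3 = label-independent noise."""
        y = np.array([0, 1] * 8)
        f1 = y.astype(float)
        f2 = f1.copy()
        f3 = np.array([0.0, 0.0, 1.0, 1.0] * 4)
        labels = np.where(y == 1, "case", "control")
        return LabeledDataset(np.stack([f1, f2, f3], axis=1), labels)

    def test_predominance_trace(self):
        res = fcbf_select(self._fixture(), delta=0.0)
        assert res.selected == [0]
        assert res.removed_redundant == [1]
        assert res.removed_irrelevant == [2]
        assert res.predominant[1] == 0
        assert res.c_correlation == [pytest.approx(1.0)]

    def test_all_constant_features_select_nothing(self):
        d = LabeledDataset(
            np.ones((10, 4)), np.array(["a"] * 5 + ["b"] * 5)
        )
        res = fcbf_select(d)
        assert res.selected == []
        assert len(res.removed_irrelevant) == 4

    def test_two_independent_informative_features_both_kept(self, rng):
        n = 400
        y = rng.integers(0, 2, size=n)
        # both features carry class signal through independent noise channels;
        # conditional independence given the class keeps their mutual SU below
        # either C-correlation (Markov chain f1 - y - f2)
        f1 = y + 0.6 * rng.standard_normal(n)
        f2 = y + 0.6 * rng.standard_normal(n)
        d = LabeledDataset(
            np.stack([f1, f2], axis=1), np.where(y == 1, "a", "b")
        )
        res = fcbf_select(d)
        assert set(res.selected) == {0, 1}

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            fcbf_select(self._fixture(), delta=-0.1)

    def test_column_order_invariance(self, small_imbalanced):
        data, _ = small_imbalanced
        res = fcbf_select(data)
        perm = np.random.default_rng(0).permutation(data.n_features)
        permuted = LabeledDataset(
            data.matrix[:, perm], data.labels, None, data.positive_class
        )
        res_p = fcbf_select(permuted)
        # map permuted indices back to the originals
        back = {int(perm[i]): i for i in range(len(perm))}
        assert sorted(perm[res_p.selected]) == sorted(res.selected)
        assert back is not None

    def test_selected_set_much_smaller_than_p(self, small_imbalanced):
        data, _ = small_imbalanced
        res = fcbf_select(data)
        assert 0 < res.n_selected < data.n_features / 2
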