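"""The six masked (dis)similarity parameters against brute-force oracles."""

import math

import numpy as np
import pytest

import regqa as rq
from regqa.errors import (DegenerateInputError, EmptyMaskError,
                          ValidationError)
from tests.conftest import make_volume


# ---------------------------------------------------------------------------
# independent oracle: explicit loops over voxels and joint outcome table

def oracle_metrics(x, y, n_bins):
    def edges(v):
        lo, hi = min(v), max(v)
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return [lo + (hi - lo) * k / n_bins for k in range(n_bins + 1)], lo, hi

    def bin_of(v, lo, hi):
        if hi == lo:
            return 0
        k = int((v - lo) / (hi - lo) * n_bins)
        return min(k, n_bins - 1)

    _, lox, hix = edges(list(x))
    _, loy, hiy = edges(list(y))
    counts = [[0] * n_bins for _ in range(n_bins)]
    for xv, yv in zip(x, y):
        counts[bin_of(xv, lox, hix)][bin_of(yv, loy, hiy)] += 1
    n = len(x)
    p = [[c / n for c in row] for row in counts]
    pa = [sum(row) for row in p]
    pb = [sum(p[i][j] for i in range(n_bins)) for j in range(n_bins)]

    def entropy(q):
        return -sum(v * math.log(v) for v in q if v > 0)

    ha, hb = entropy(pa), entropy(pb)
    hab = entropy([v for row in p for v in row])
    mi = sum(p[i][j] * math.log(p[i][j] / (pa[i] * pb[j]))
             for i in range(n_bins) for j in range(n_bins) if p[i][j] > 0)
    nmi = (ha + hb) / hab if hab > 0 else 2.0
    hkl = sum(pa[i] * math.log(pa[i] / (pb[i] if pb[i] > 0 else 1e-12))
              for i in range(n_bins) if pa[i] > 0)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    pearson = num / den
    l1 = sum(abs(a - b) for a, b in zip(x, y))
    l2 = sum((a - b) ** 2 for a, b in zip(x, y))
    return dict(pearson=pearson, mi=max(mi, 0.0), nmi=nmi, hkl=max(hkl, 0.0),
                l1norm=l1, l2norm2=l2, ha=ha, hb=hb)


# ---------------------------------------------------------------------------
# joint histogram

def test_joint_histogram_identical_images_is_diagonal():
    a = make_volume([0, 0, 0, 0, 1, 1, 1, 1])
    counts, _, _ = rq.joint_histogram(a, a, n_bins=2)
    assert np.array_equal(counts, [[4, 0], [0, 4]])


def test_joint_histogram_balanced_design():
    a = make_volume([0, 0, 1, 1])
    b = make_volume([0, 1, 0, 1])
    counts, _, _ = rq.joint_histogram(a, b, n_bins=2)
    assert np.array_equal(counts, np.ones((2, 2)))


def test_joint_histogram_marginals_match_own_histograms():
    rng = np.random.default_rng(11)
    a = make_volume(rng.integers(0, 5, (4, 4, 4)))
    b = make_volume(rng.integers(0, 5, (4, 4, 4)))
    counts, ea, eb = rq.joint_histogram(a, b, n_bins=8)
    assert counts.sum() == a.values.size
    assert np.array_equal(counts.sum(axis=1),
                          np.histogram(a.values.ravel(), bins=ea)[0])
    assert np.array_equal(counts.sum(axis=0),
                          np.histogram(b.values.ravel(), bins=eb)[0])


def test_joint_histogram_constant_image_single_bin():
    a = make_volume(np.zeros((2, 2, 2)))
    b = make_volume(np.arange(8.0).reshape(2, 2, 2))
    counts, _, _ = rq.joint_histogram(a, b, n_bins=4)
    assert (counts.sum(axis=1) > 0).sum() == 1


def test_empty_mask_rejected():
    a = make_volume(np.zeros((2, 2, 2)))
    empty = rq.BinaryMask(np.zeros((2, 2, 2), bool))
    with pytest.raises(EmptyMaskError):
        rq.joint_histogram(a, a, empty, 2)


# ---------------------------------------------------------------------------
# similarity vector

def test_identity_pair():
    rng = np.random.default_rng(0)
    a = make_volume(rng.normal(size=(4, 4, 4)))
    vec = rq.similarity_vector(a, a, n_bins=8)
    assert vec.pearson == pytest.approx(1.0)
    assert vec.l1norm == 0.0 and vec.l2norm2 == 0.0
    assert vec.hkl == pytest.approx(0.0, abs=1e-12)
    assert vec.nmi == pytest.approx(2.0)


def test_independent_pair_has_zero_mi():
    a = make_volume([0, 0, 1, 1])
    b = make_volume([0, 1, 0, 1])
    vec = rq.similarity_vector(a, b, n_bins=2)
    assert vec.mi == pytest.approx(0.0, abs=1e-14)


def test_mi_of_two_balanced_levels_is_ln2():
    a = make_volume([0, 0, 0, 0, 1, 1, 1, 1])
    vec = rq.similarity_vector(a, a, n_bins=2)
    assert vec.mi == pytest.approx(math.log(2), abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_all_six_metrics_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, 6, 3))
    levels = rng.integers(2, 5)
    a = make_volume(rng.integers(0, levels, shape))
    b = make_volume(rng.integers(0, levels, shape))
    n_bins = int(rng.integers(2, 6))
    vec = rq.similarity_vector(a, b, n_bins=n_bins)
    ref = oracle_metrics(a.values.ravel().tolist(),
                         b.values.ravel().tolist(), n_bins)
    for name in rq.METRIC_NAMES:
        assert getattr(vec, name) == pytest.approx(ref[name], abs=1e-10), name


@pytest.mark.parametrize("seed", range(4))
def test_mi_bounded_by_marginal_entropies(seed):
    rng = np.random.default_rng(100 + seed)
    a = make_volume(rng.integers(0, 4, (4, 4, 4)))
    b = make_volume(rng.integers(0, 4, (4, 4, 4)))
    vec = rq.similarity_vector(a, b, n_bins=4)
    ref = oracle_metrics(a.values.ravel().tolist(),
                         b.values.ravel().tolist(), 4)
    assert vec.mi <= min(ref["ha"], ref["hb"]) + 1e-12


def test_symmetry_under_swap():
    rng = np.random.default_rng(5)
    a = make_volume(rng.normal(size=(4, 4, 4)))
    b = make_volume(rng.normal(1.0, 2.0, size=(4, 4, 4)))
    ab = rq.similarity_vector(a, b, n_bins=8)
    ba = rq.similarity_vector(b, a, n_bins=8)
    for name in ("pearson", "mi", "nmi", "l1norm", "l2norm2"):
        assert getattr(ab, name) == pytest.approx(getattr(ba, name), abs=1e-12)
    assert ab.hkl != pytest.approx(ba.hkl)   # directed divergence


def test_nonnegativity_and_nmi_range():
    rng = np.random.default_rng(9)
    a = make_volume(rng.normal(size=(5, 5, 5)))
    b = make_volume(rng.normal(size=(5, 5, 5)))
    vec = rq.similarity_vector(a, b, n_bins=16)
    assert vec.mi >= 0 and vec.hkl >= 0
    assert vec.l1norm >= 0 and vec.l2norm2 >= 0
    assert 1.0 <= vec.nmi <= 2.0


def test_degenerate_pearson_raises():
    a = make_volume(np.zeros((2, 2, 2)))
    b = make_volume(np.arange(8.0).reshape(2, 2, 2))
    with pytest.raises(DegenerateInputError):
        rq.similarity_vector(a, b, n_bins=2)


# ---------------------------------------------------------------------------
# masking modes

def test_masked_pair_modes():
    shape = (10, 10, 10)
    a = make_volume(np.random.default_rng(1).normal(size=shape))
    b = make_volume(np.random.default_rng(2).normal(size=shape))

    alpha = rq.masked_pair(a, b, "alpha")
    assert alpha.n_voxels == 1000

    m1 = np.zeros(shape, bool)
    m1[2:4] = True
    m2 = np.zeros(shape, bool)
    m2[6:8] = True
    gamma = rq.masked_pair(a, b, "gamma",
                           airway_ext_a=rq.BinaryMask(m1),
                           airway_ext_b=rq.BinaryMask(m2))
    assert gamma.n_voxels == m1.sum() + m2.sum()     # disjoint union
    assert gamma.n_voxels >= max(m1.sum(), m2.sum())

    beta = rq.masked_pair(a, b, "beta", functioning_lung=rq.BinaryMask(m1))
    assert beta.n_voxels == m1.sum()

    with pytest.raises(ValidationError):
        rq.masked_pair(a, b, "beta")
    with pytest.raises(ValidationError):
        rq.masked_pair(a, b, "gamma", airway_ext_a=rq.BinaryMask(m1))
    with pytest.raises(ValidationError):
        rq.masked_pair(a, b, "delta")
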