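"""Lesion-level matching and detection metrics."""

import itertools

import numpy as np
import pytest

from noisematch.core import LesionMask
from noisematch.evaluation import (
    detection_metrics,
    evaluate_testset,
    iou,
    iou_matrix,
    match_lesions,
)

from conftest import make_mask


def _mask_from_components(shape, components):
    labels = np.zeros(shape, dtype=np.int32)
    for k, comp in enumerate(components, start=1):
        for p in comp:
            labels[p] = k
    return LesionMask(labels)


def _brute_force_match(pred, gold):
    """Exhaustive search over one-to-one assignments maximizing total
    IoU; returns the best TP count (pairs with IoU > 0)."""
    mat = iou_matrix(pred, gold)
    n_p, n_g = mat.shape
    if n_p == 0 or n_g == 0:
        return 0, 0.0
    best_total, best_tp = 0.0, 0
    k = min(n_p, n_g)
    for rows in itertools.permutations(range(n_p), k):
        for cols in itertools.combinations(range(n_g), k):
            total = sum(mat[r, c] for r, c in zip(rows, cols))
            tp = sum(1 for r, c in zip(rows, cols) if mat[r, c] > 0)
            if total > best_total + 1e-12 or (
                abs(total - best_total) <= 1e-12 and tp > best_tp
            ):
                best_total, best_tp = total, tp
    return best_tp, best_total


def test_iou_examples():
    a = np.zeros((4, 4), bool)
    a[0, :3] = True
    assert iou(a, a) == 1.0
    b = np.zeros((4, 4), bool)
    b[2, :3] = True
    assert iou(a, b) == 0.0
    c = np.zeros((4, 4), bool)
    c[0, 1:4] = True  # overlap 2 of 3+3 -> 2/4
    assert iou(a, c) == pytest.approx(0.5)


def test_iou_empty_errors():
    a = np.zeros((4, 4), bool)
    b = np.ones((4, 4), bool)
    with pytest.raises(ValueError):
        iou(a, b)


def test_match_identical_masks():
    labels = np.zeros((16, 16), dtype=np.int32)
    labels[1:3, 1:3] = 1
    labels[6:9, 6:9] = 2
    labels[12:14, 2:5] = 3
    mask = make_mask(labels)
    records, (tp, fp, fn) = match_lesions(mask, mask)
    assert (tp, fp, fn) == (3, 0, 0)
    assert all(r.iou == 1.0 for r in records)


def test_one_prediction_two_golds():
    """One prediction overlapping two gold lesions: one-to-one matching
    forces a miss."""
    pred = _mask_from_components((8, 8), [[(2, c) for c in range(6)]])
    gold = _mask_from_components(
        (8, 8), [[(2, 0), (2, 1)], [(2, 4), (2, 5)]]
    )
    _, (tp, fp, fn) = match_lesions(pred, gold)
    assert (tp, fp, fn) == (1, 0, 1)
    bf_tp, _ = _brute_force_match(pred, gold)
    assert tp == bf_tp


def test_crossed_overlaps_match_brute_force():
    pred = _mask_from_components(
        (8, 8), [[(1, 1), (1, 2), (2, 1)], [(5, 5), (5, 6)]]
    )
    gold = _mask_from_components(
        (8, 8), [[(1, 2), (1, 3), (5, 5)], [(2, 1), (5, 6)]]
    )
    records, (tp, fp, fn) = match_lesions(pred, gold)
    bf_tp, bf_total = _brute_force_match(pred, gold)
    assert tp == bf_tp
    assert sum(r.iou for r in records) == pytest.approx(bf_total)


@pytest.mark.parametrize("seed", range(200))
def test_hungarian_equals_exhaustive(seed):
    """Hungarian matching equals exhaustive permutation search on
    random instances with up to 6 components per side."""
    rng = np.random.default_rng(seed)
    shape = (12, 12)

    def random_mask():
        n = rng.integers(0, 7)
        labels = np.zeros(shape, dtype=np.int32)
        for k in range(1, n + 1):
            i, j = rng.integers(0, 10, size=2)
            labels[i : i + 2, j : j + 2] = k
        # relabel contiguously (overwrites may erase a label)
        out = np.zeros_like(labels)
        for new, old in enumerate(
            [v for v in np.unique(labels) if v > 0], start=1
        ):
            out[labels == old] = new
        return LesionMask(out)

    pred, gold = random_mask(), random_mask()
    try:
        records, (tp, fp, fn) = match_lesions(pred, gold)
    except ValueError:
        pytest.skip("degenerate non-contiguous mask")
    bf_tp, bf_total = _brute_force_match(pred, gold)
    assert tp == bf_tp
    assert sum(r.iou for r in records) == pytest.approx(bf_total, abs=1e-9)
    assert tp + fp == pred.n_components
    assert tp + fn == gold.n_components


@pytest.mark.parametrize(
    "tp, fp, fn, ppv, sens, f1",
    [
        (3, 1, 2, 0.75, 0.6, 2 * 0.75 * 0.6 / 1.35),
        (0, 0, 0, 0.0, 0.0, 0.0),
        (5, 0, 0, 1.0, 1.0, 1.0),
        (0, 3, 4, 0.0, 0.0, 0.0),
    ],
)
def test_detection_metrics_formulas(tp, fp, fn, ppv, sens, f1):
    m = detection_metrics(tp, fp, fn)
    assert m.ppv == pytest.approx(ppv)
    assert m.sensitivity == pytest.approx(sens)
    assert m.f1 == pytest.approx(f1)


def test_f1_is_harmonic_mean(rng):
    for _ in range(50):
        tp, fp, fn = rng.integers(0, 20, size=3)
        m = detection_metrics(int(tp), int(fp), int(fn))
        if m.ppv + m.sensitivity > 0:
            assert m.f1 == pytest.approx(
                2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity)
            )
        assert min(m.ppv, m.sensitivity) - 1e-12 <= m.f1 <= max(m.ppv, m.sensitivity) + 1e-12


def test_extra_false_positive_never_helps():
    base = detection_metrics(4, 1, 2)
    worse = detection_metrics(4, 2, 2)
    assert worse.f1 <= base.f1
    better = detection_metrics(5, 1, 1)  # new TP on unmatched gold
    assert better.f1 >= base.f1


class _IdentityModel:
    """Predicts the gold mask (for pooling tests)."""

    def __init__(self, golds):
        self._golds = list(golds)

    def predict(self, X):
        return self._golds


def test_pooled_metrics_hand_example():
    """Two subjects with (TP,FP,FN) = (1,0,0) and (0,1,1) pool to
    PPV = sensitivity = F1 = 0.5."""
    g1 = _mask_from_components((8, 8), [[(1, 1), (1, 2)]])
    p1 = g1
    g2 = _mask_from_components((8, 8), [[(5, 5), (5, 6)]])
    p2 = _mask_from_components((8, 8), [[(1, 1), (1, 2)]])

    class Model:
        def predict(self, X):
            return [p1, p2]

    from noisematch.core import SUVImage

    imgs = [
        SUVImage(np.ones((8, 8)), (1.0, 1.0), subject_id=f"s{i}") for i in range(2)
    ]
    metrics, per_subject = evaluate_testset(Model(), list(zip(imgs, [g1, g2])))
    assert metrics.ppv == pytest.approx(0.5)
    assert metrics.sensitivity == pytest.approx(0.5)
    assert metrics.f1 == pytest.approx(0.5)
    assert len(per_subject) == 2


def test_pooled_metrics_order_invariant(tiny_cohort):
    _, cohort = tiny_cohort
    golds = [s.gold["Set1-QClear"] for s in cohort]
    imgs = [s.images["Set1-QClear"] for s in cohort]
    pairs = list(zip(imgs, golds))

    class Model:
        def __init__(self, perm):
            self.perm = perm

        def predict(self, X):
            return [golds[i] for i in self.perm]

    m1, _ = evaluate_testset(Model(list(range(len(pairs)))), pairs)
    rev = pairs[::-1]
    m2, _ = evaluate_testset(Model(list(range(len(pairs) - 1, -1, -1))), rev)
    assert m1 == m2


def test_empty_testset_errors():
    with pytest.raises(ValueError):
        evaluate_testset(_IdentityModel([]), [])
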