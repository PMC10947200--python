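import numpy as np
import pytest

from skinquant.evaluation import (
    bf_score,
    class_boundaries,
    confusion_matrix,
    evaluate_masks,
    partition_dataset,
    repeated_validation,
    seg_metrics,
)
from skinquant.types import (
    InvalidArgumentError,
    SplitSpec,
    TissueMask,
    ValidationError,
)

from _oracles import brute_metrics


class TestConfusionMatrix:
    def test_identical_masks_are_diagonal(self, rng):
        m = rng.integers(1, 5, size=(10, 10))
        cm = confusion_matrix(m, m, [1, 2, 3, 4])
        assert (cm == np.diag(np.diag(cm))).all()
        assert cm.sum() == 100

    def test_hand_worked_two_by_two(self):
        truth = np.array([[1, 1], [2, 2]])
        pred = np.array([[1, 2], [2, 2]])
        cm = confusion_matrix(truth, pred, [1, 2])
        assert cm.tolist() == [[1, 1], [0, 2]]

    def test_swapping_transposes(self, rng):
        a = rng.integers(1, 4, size=(8, 8))
        b = rng.integers(1, 4, size=(8, 8))
        classes = [1, 2, 3]
        assert (confusion_matrix(a, b, classes)
                == confusion_matrix(b, a, classes).T).all()

    def test_out_of_vocabulary_rejected(self):
        with pytest.raises(ValidationError, match="9"):
            confusion_matrix(np.array([[9]]), np.array([[1]]), [1, 2])


class TestSegMetrics:
    def test_identical_masks_score_100_on_all_five(self, rng):
        m = rng.integers(1, 5, size=(20, 20))
        out = evaluate_masks(m, m, [1, 2, 3, 4], tolerance=0)
        for v in vars(out).values():
            assert v == pytest.approx(100.0)

    def test_hand_worked_example_values(self):
        truth = np.array([[1, 1], [2, 2]])
        pred = np.array([[1, 2], [2, 2]])
        cm = confusion_matrix(truth, pred, [1, 2])
        out = seg_metrics(cm, bf_values=[1.0], classes=[1, 2])
        assert out.global_accuracy == pytest.approx(75.0)
        assert out.mean_accuracy == pytest.approx(75.0)
        # IoU_1 = 1/2, IoU_2 = 2/3; truth weights 1/2, 1/2
        assert out.mean_iou == pytest.approx(58.33, abs=0.005)
        assert out.weighted_iou == pytest.approx(58.33, abs=0.005)

    def test_total_disagreement_scores_zero_global(self):
        truth = np.ones((5, 5), dtype=int)
        pred = np.full((5, 5), 2)
        out = evaluate_masks(truth, pred, [1, 2], tolerance=0)
        assert out.global_accuracy == 0.0

    def test_matches_brute_force_on_random_pairs(self, rng):
        classes = [1, 2, 3, 4]
        for _ in range(200):
            truth = rng.integers(1, 5, size=(16, 16))
            pred = rng.integers(1, 5, size=(16, 16))
            tol = 2.0
            fast = evaluate_masks(truth, pred, classes, tolerance=tol)
            slow = brute_metrics(truth.tolist(), pred.tolist(), classes, tol)
            for key, want in slow.items():
                got = getattr(fast, key)
                assert got == pytest.approx(want, rel=1e-10, abs=1e-10), key

    def test_class_relabelling_invariance(self, rng):
        truth = rng.integers(1, 5, size=(12, 12))
        pred = rng.integers(1, 5, size=(12, 12))
        relabel = {1: 3, 2: 4, 3: 1, 4: 2}
        t2 = np.vectorize(relabel.get)(truth)
        p2 = np.vectorize(relabel.get)(pred)
        a = evaluate_masks(truth, pred, [1, 2, 3, 4], tolerance=2)
        b = evaluate_masks(t2, p2, [1, 2, 3, 4], tolerance=2)
        for key in vars(a):
            assert getattr(a, key) == pytest.approx(getattr(b, key))

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidArgumentError):
            seg_metrics(np.zeros((2, 2)), bf_values=[1.0])


class TestBFScore:
    def test_identical_boundaries(self):
        pts = np.array([[0, 0], [0, 1], [1, 0]])
        assert bf_score(pts, pts, tolerance=0) == 1.0

    def test_far_boundaries_score_zero(self):
        a = np.array([[0, 0]])
        b = np.array([[50, 50]])
        assert bf_score(a, b, tolerance=2) == 0.0

    def test_shifted_square_within_tolerance(self):
        # square boundary shifted 1 px; all pairwise nearest distances
        # <= sqrt(2) < 2
        m1 = np.zeros((12, 12), dtype=int)
        m1[3:8, 3:8] = 1
        m2 = np.zeros((12, 12), dtype=int)
        m2[4:9, 4:9] = 1
        b1 = class_boundaries(m1, [1])[1]
        b2 = class_boundaries(m2, [1])[1]
        assert bf_score(b1, b2, tolerance=2) == 1.0

    def test_both_empty_vacuously_perfect(self):
        empty = np.zeros((0, 2))
        assert bf_score(empty, empty, tolerance=1) == 1.0


class TestPartition:
    @pytest.mark.parametrize("n,fractions,expected", [
        (5009, (0.6, 0.2, 0.2), (3005, 1001, 1003)),
        (125, (0.6, 0.2, 0.2), (75, 25, 25)),
        (560, (0.7, 0.25, 0.05), (392, 140, 28)),
        (60, (0.7, 0.25, 0.05), (42, 15, 3)),
    ])
    def test_published_split_sizes(self, n, fractions, expected):
        train, test, leftout = partition_dataset(n, fractions, seed=0)
        assert (len(train), len(test), len(leftout)) == expected

    def test_sets_partition_index_range(self, rng):
        for n in rng.integers(3, 10000, size=25):
            n = int(n)
            for fr in [(0.6, 0.2, 0.2), (0.7, 0.25, 0.05), (0.5, 0.3, 0.2)]:
                a, b, c = partition_dataset(n, fr, seed=1)
                all_idx = np.concatenate([a, b, c])
                assert len(all_idx) == n
                assert (np.sort(all_idx) == np.arange(n)).all()
                assert len(a) == int(np.floor(n * fr[0] + 1e-6))
                assert len(b) == int(np.floor(n * fr[1] + 1e-6))

    def test_same_seed_reproduces(self):
        a = partition_dataset(100, (0.6, 0.2, 0.2), seed=7)
        b = partition_dataset(100, (0.6, 0.2, 0.2), seed=7)
        for x, y in zip(a, b):
            assert (x == y).all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            partition_dataset(10, (0.5, 0.2, 0.2), seed=0)
        with pytest.raises(InvalidArgumentError):
            partition_dataset(10, (0.8, 0.2, -0.0), seed=0)


class _PerfectModel:
    """Predicts the ground truth it is handed at construction."""

    def __init__(self, lookup):
        self.lookup = lookup

    def predict_tile(self, tile):
        return self.lookup[id(tile)]


class _ConstantModel:
    def __init__(self, code, shape):
        self.code = code
        self.shape = shape

    def predict_tile(self, tile):
        return TissueMask(np.full(self.shape, self.code))


def _toy_dataset(rng, n=12, shape=(16, 16)):
    dataset = []
    for _ in range(n):
        codes = rng.integers(1, 5, size=shape)
        tile = object()
        dataset.append((tile, TissueMask(codes)))
    return dataset


class TestRepeatedValidation:
    def test_perfect_predictor_scores_100_everywhere(self, rng):
        dataset = _toy_dataset(rng)
        lookup = {id(t): m for t, m in dataset}

        report = repeated_validation(
            dataset, lambda pairs, seed: _PerfectModel(lookup),
            SplitSpec(seed=0), k=3, classes=[1, 2, 3, 4], tolerance=0)
        for row in report.folds + [report.average]:
            for v in vars(row).values():
                assert v == pytest.approx(100.0)

    def test_constant_predictor_global_accuracy_is_class_share(self, rng):
        dataset = _toy_dataset(rng, n=10)
        spec = SplitSpec(seed=5)
        report = repeated_validation(
            dataset, lambda pairs, seed: _ConstantModel(4, (16, 16)),
            spec, k=1, classes=[1, 2, 3, 4])
        _, test_idx, _ = partition_dataset(10, spec.fractions, spec.seed)
        pooled = np.concatenate([dataset[i][1].codes.ravel()
                                 for i in test_idx])
        share = 100.0 * (pooled == 4).mean()
        assert report.folds[0].global_accuracy == pytest.approx(share)

    def test_average_row_is_arithmetic_mean(self, rng):
        dataset = _toy_dataset(rng)
        report = repeated_validation(
            dataset, lambda pairs, seed: _ConstantModel(1, (16, 16)),
            SplitSpec(seed=2), k=4, classes=[1, 2, 3, 4])
        for key in ("global_accuracy", "mean_accuracy", "mean_iou",
                    "weighted_iou", "mean_bf"):
            mean = np.mean([getattr(f, key) for f in report.folds])
            assert getattr(report.average, key) == pytest.approx(mean, abs=1e-9)

    def test_same_base_seed_reproduces_report(self, rng):
        dataset = _toy_dataset(rng)
        make = lambda pairs, seed: _ConstantModel(2, (16, 16))
        r1 = repeated_validation(dataset, make, SplitSpec(seed=3), k=2,
                                 classes=[1, 2, 3, 4])
        r2 = repeated_validation(dataset, make, SplitSpec(seed=3), k=2,
                                 classes=[1, 2, 3, 4])
        assert r1.as_table() == r2.as_table()
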