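import numpy as np
import pytest

from skinquant.postprocess import (
    binarize_tissue,
    extract_polarity,
    fuse_cell_masks,
    remove_small_objects,
    split_instances,
)
from skinquant.types import (
    BinaryMask,
    CellMask,
    CombinedCellMask,
    InvalidArgumentError,
    TissueMask,
)


class TestBinarizeTissue:
    def test_all_epidermis(self):
        out = binarize_tissue(TissueMask(np.full((5, 5), 1)))
        assert (out.values == 1).all()

    def test_no_epidermis(self):
        codes = np.array([[2, 3], [4, 2]])
        assert binarize_tissue(TissueMask(codes)).values.sum() == 0

    def test_foreground_union(self):
        codes = np.array([[1, 2], [3, 4]])
        out = binarize_tissue(TissueMask(codes), frozenset({1, 2}))
        assert (out.values == np.array([[1, 1], [0, 0]])).all()

    def test_empty_foreground_rejected(self):
        with pytest.raises(InvalidArgumentError):
            binarize_tissue(TissueMask(np.ones((2, 2))), frozenset())


class TestFusion:
    # (cell code, stain) -> combined value
    TRUTH_TABLE = [
        (1, 0, 1), (3, 0, 1),       # positives stay positive
        (1, 1, 1), (3, 1, 1),
        (2, 0, 2), (4, 0, 2),       # unstained negatives stay negative
        (2, 1, 1), (4, 1, 1),       # stained negatives promoted
        (5, 0, 0), (5, 1, 0),       # stain alone never creates a cell
    ]

    @pytest.mark.parametrize("cell_code,stain,expected", TRUTH_TABLE)
    def test_truth_table(self, cell_code, stain, expected):
        cells = CellMask(np.full((3, 3), cell_code))
        stain_mask = BinaryMask(np.full((3, 3), stain))
        out = fuse_cell_masks(cells, stain_mask)
        assert (out.values == expected).all()

    def test_fusion_never_demotes_positives(self, rng):
        codes = rng.integers(1, 6, size=(20, 20))
        stain = BinaryMask(rng.integers(0, 2, size=(20, 20)))
        out = fuse_cell_masks(CellMask(codes), stain)
        assert (out.values[np.isin(codes, (1, 3))] == 1).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fuse_cell_masks(CellMask(np.ones((3, 3))),
                            BinaryMask(np.zeros((2, 2))))


def blob_mask(shape, blobs):
    """Binary mask with discs given as (cy, cx, r)."""
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    out = np.zeros(shape, dtype=np.uint8)
    for cy, cx, r in blobs:
        out[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = 1
    return out


class TestRemoveSmallObjects:
    def square(self, area_side, pad=5):
        size = area_side + 2 * pad
        m = np.zeros((size, size), dtype=np.uint8)
        m[pad:pad + area_side, pad:pad + area_side] = 1
        return m

    def test_100_pixel_component_removed(self):
        m = self.square(10)  # exactly 100 px
        out = remove_small_objects(BinaryMask(m), 100)
        assert out.values.sum() == 0

    def test_101_pixel_component_kept_intact(self):
        m = self.square(10)
        m[4, 5] = 1  # 101 px, still one 8-connected component
        out = remove_small_objects(BinaryMask(m), 100)
        assert (out.values == m).all()

    def test_mixed_sizes_only_large_survives(self):
        m = np.zeros((40, 80), dtype=np.uint8)
        m[5:10, 5:15] = 1         # 50 px
        m[20:30, 40:60] = 1       # 200 px
        out = remove_small_objects(BinaryMask(m), 100)
        assert out.values[5:10, 5:15].sum() == 0
        assert out.values[20:30, 40:60].sum() == 200

    def test_combined_mask_filtered_per_class(self):
        m = np.zeros((40, 40), dtype=np.int64)
        m[2:7, 2:7] = 1           # 25 px positive -> removed
        m[15:30, 15:30] = 2       # 225 px negative -> kept
        out = remove_small_objects(CombinedCellMask(m), 100)
        assert (out.values == 1).sum() == 0
        assert (out.values == 2).sum() == 225

    def test_idempotent(self, rng):
        m = (rng.random((50, 50)) < 0.3).astype(np.uint8)
        once = remove_small_objects(BinaryMask(m), 20)
        twice = remove_small_objects(once, 20)
        assert (once.values == twice.values).all()

    def test_survivors_anti_monotone_in_threshold(self, rng):
        from scipy import ndimage
        m = (rng.random((60, 60)) < 0.25).astype(np.uint8)
        counts = []
        for thr in (0, 5, 20, 80, 300):
            out = remove_small_objects(BinaryMask(m), thr)
            _, n = ndimage.label(out.values, structure=np.ones((3, 3)))
            counts.append(n)
        assert counts == sorted(counts, reverse=True)


class TestSplitInstances:
    def test_empty_mask(self):
        out = split_instances(BinaryMask(np.zeros((10, 10))))
        assert out.n_instances == 0

    def test_single_disc_single_instance(self):
        m = blob_mask((40, 40), [(20, 20, 15)])
        out = split_instances(BinaryMask(m))
        assert out.n_instances == 1
        assert ((out.labels > 0) == m.astype(bool)).all()

    def test_two_overlapping_discs_split_evenly(self):
        m = blob_mask((60, 80), [(30, 30, 12), (30, 48, 12)])
        from scipy import ndimage
        _, n_components = ndimage.label(m, structure=np.ones((3, 3)))
        assert n_components == 1  # they genuinely overlap
        out = split_instances(BinaryMask(m))
        assert out.n_instances == 2
        a1 = (out.labels == 1).sum()
        a2 = (out.labels == 2).sum()
        assert abs(a1 - a2) / max(a1, a2) <= 0.15

    def test_foreground_conserved(self, rng):
        m = (rng.random((50, 50)) < 0.4).astype(np.uint8)
        out = split_instances(BinaryMask(m))
        assert ((out.labels > 0) == m.astype(bool)).all()

    def test_k_disjoint_blobs_give_k_instances(self):
        blobs = [(15, 15, 7), (15, 50, 7), (50, 15, 7), (50, 50, 7)]
        m = blob_mask((70, 70), blobs)
        cleaned = remove_small_objects(BinaryMask(m), 100)
        out = split_instances(cleaned)
        assert out.n_instances == len(blobs)

    def test_labels_contiguous(self, rng):
        m = (rng.random((40, 40)) < 0.35).astype(np.uint8)
        out = split_instances(BinaryMask(m))
        labels = np.unique(out.labels)
        assert (labels == np.arange(labels.size)).all()


class TestExtractPolarity:
    def test_all_positive(self):
        m = CombinedCellMask(np.ones((4, 4), dtype=int))
        assert (extract_polarity(m, 1).values == 1).all()
        assert extract_polarity(m, 2).values.sum() == 0

    def test_partition_property(self, rng):
        m = CombinedCellMask(rng.integers(0, 3, size=(20, 20)))
        pos = extract_polarity(m, 1).values
        neg = extract_polarity(m, 2).values
        assert not (pos & neg).any()
        assert ((pos | neg) == (m.values != 0)).all()

    def test_bad_polarity_rejected(self):
        with pytest.raises(InvalidArgumentError):
            extract_polarity(CombinedCellMask(np.zeros((2, 2), dtype=int)), 3)
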