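import numpy as np
import pytest

from skinquant.quantify import (
    aggregate_sections,
    assign_compartment,
    quantify_section,
)
from skinquant.types import (
    BinaryMask,
    InstanceLabels,
    InvalidArgumentError,
    SectionQuant,
    ValidationError,
)


def epidermis_top_half(h=20, w=20):
    m = np.zeros((h, w), dtype=np.uint8)
    m[:h // 2] = 1
    return BinaryMask(m, role="epidermis")


def one_instance(pixels, shape=(20, 20), label=1):
    arr = np.zeros(shape, dtype=np.int64)
    for y, x in pixels:
        arr[y, x] = label
    return InstanceLabels(arr)


class TestAssignCompartment:
    def test_fully_inside_epidermis(self):
        inst = one_instance([(2, 2), (2, 3), (3, 2)])
        assert assign_compartment(inst, epidermis_top_half()).tolist() == [True]

    def test_fully_outside(self):
        inst = one_instance([(15, 2), (15, 3)])
        assert assign_compartment(inst, epidermis_top_half()).tolist() == [False]

    def test_straddling_instance_follows_centroid(self):
        # 5 pixels in rows 8..12 at x=5: centroid row = 10 -> outside
        # (epidermis covers rows 0..9); adding two extra pixels at row 8
        # pulls the centroid to row 9.43 -> rounds to 9 -> inside
        straddle = [(y, 5) for y in range(8, 13)]
        inst = one_instance(straddle)
        assert assign_compartment(inst, epidermis_top_half()).tolist() == [False]
        inst2 = one_instance(straddle + [(8, 4), (8, 6)])
        assert assign_compartment(inst2, epidermis_top_half()).tolist() == [True]


def square_instances(positions, shape=(30, 30), side=3):
    arr = np.zeros(shape, dtype=np.int64)
    for i, (y, x) in enumerate(positions, start=1):
        arr[y:y + side, x:x + side] = i
    return InstanceLabels(arr)


class TestQuantifySection:
    def test_three_pos_one_neg_all_epidermal(self):
        epi = BinaryMask(np.ones((30, 30), dtype=np.uint8), role="epidermis")
        pos = square_instances([(2, 2), (2, 10), (2, 18)])
        neg = square_instances([(10, 2)])
        q = quantify_section(pos, neg, epi, np.full((30, 30), 100))
        assert (q.n_pos_epi, q.n_neg_epi) == (3, 1)
        assert q.pct_positive_epi == pytest.approx(75.0)
        assert q.pct_positive_derm is None

    def test_no_cells_percentages_missing_not_zero(self):
        epi = epidermis_top_half(30, 30)
        empty = InstanceLabels(np.zeros((30, 30), dtype=np.int64))
        q = quantify_section(empty, empty, epi, np.zeros((30, 30)))
        assert q.n_pos == 0 and q.n_neg == 0
        assert q.pct_positive_epi is None
        assert q.pct_positive_derm is None
        assert q.avg_signal is None

    def test_average_signal_over_uniform_gray(self):
        epi = epidermis_top_half(30, 30)
        pos = square_instances([(5, 5)])
        neg = InstanceLabels(np.zeros((30, 30), dtype=np.int64))
        q = quantify_section(pos, neg, epi, np.full((30, 30), 155))
        assert q.avg_signal == pytest.approx(100.0)  # 255 - 155

    def test_overlapping_instances_rejected(self):
        epi = epidermis_top_half(30, 30)
        pos = square_instances([(5, 5)])
        neg = square_instances([(6, 6)])
        with pytest.raises(ValidationError, match="overlap"):
            quantify_section(pos, neg, epi, np.zeros((30, 30)))

    def test_exclusion_mask_drops_instances(self):
        epi = BinaryMask(np.ones((30, 30), dtype=np.uint8), role="epidermis")
        pos = square_instances([(2, 2), (20, 20)])
        neg = InstanceLabels(np.zeros((30, 30), dtype=np.int64))
        excl = np.zeros((30, 30), dtype=np.uint8)
        excl[21, 21] = 1
        q = quantify_section(pos, neg, epi, np.zeros((30, 30)),
                             exclusion=BinaryMask(excl))
        assert q.n_pos == 1
        assert q.n_excluded == 1

    def test_count_conservation(self, rng):
        epi = epidermis_top_half(30, 30)
        pos = square_instances([(2, 2), (12, 12), (22, 4)])
        neg = square_instances([(2, 22), (22, 22)])
        q = quantify_section(pos, neg, epi, np.zeros((30, 30)))
        assert q.n_pos_epi + q.n_pos_derm == 3
        assert q.n_neg_epi + q.n_neg_derm == 2

    def test_scale_free_under_pixel_replication(self):
        epi = epidermis_top_half(30, 30)
        pos = square_instances([(2, 2), (20, 6)])
        neg = square_instances([(4, 12)])
        gray = np.full((30, 30), 120)
        q1 = quantify_section(pos, neg, epi, gray)

        def up(a):
            return np.kron(a, np.ones((2, 2), dtype=a.dtype))

        q2 = quantify_section(
            InstanceLabels(up(pos.labels)), InstanceLabels(up(neg.labels)),
            BinaryMask(up(epi.values), role="epidermis"), up(gray))
        assert (q1.n_pos_epi, q1.n_neg_epi, q1.n_pos_derm, q1.n_neg_derm) == \
               (q2.n_pos_epi, q2.n_neg_epi, q2.n_pos_derm, q2.n_neg_derm)
        assert q1.pct_positive_epi == pytest.approx(q2.pct_positive_epi)

    def test_avg_signal_invariant_to_label_permutation(self, rng):
        epi = epidermis_top_half(30, 30)
        pos = square_instances([(2, 2), (12, 12), (22, 4)])
        gray = rng.integers(0, 255, size=(30, 30))
        neg = InstanceLabels(np.zeros((30, 30), dtype=np.int64))
        q1 = quantify_section(pos, neg, epi, gray)
        permuted = pos.labels.copy()
        permuted[pos.labels == 1] = 3
        permuted[pos.labels == 3] = 1
        q2 = quantify_section(InstanceLabels(permuted), neg, epi, gray)
        assert q1.avg_signal == pytest.approx(q2.avg_signal)


class TestAggregateSections:
    def quants(self, pcts):
        return [SectionQuant(n_pos_epi=1, n_neg_epi=1, pct_positive_epi=p)
                for p in pcts]

    def test_median_and_iqr_with_linear_interpolation(self):
        table = aggregate_sections(self.quants([10, 20, 30]))
        row = table[table.endpoint == "pct_positive_epi"].iloc[0]
        assert row["median"] == pytest.approx(20.0)
        assert row["q25"] == pytest.approx(15.0)
        assert row["q75"] == pytest.approx(25.0)

    def test_single_section_degenerate_iqr(self):
        table = aggregate_sections(self.quants([42.0]))
        row = table[table.endpoint == "pct_positive_epi"].iloc[0]
        assert row["median"] == row["q25"] == row["q75"] == 42.0

    def test_all_undefined_endpoint_flagged(self):
        qs = [SectionQuant(), SectionQuant()]
        table = aggregate_sections(qs, ["g", "g"])
        row = table[table.endpoint == "avg_signal"].iloc[0]
        assert row["all_undefined"]
        assert row["n_excluded"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            aggregate_sections([])
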