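"""Hemispheric fold-ratio, similar/different classification and partition."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bihemi.bilateral import (
    classify_common,
    fold_ratio,
    partition,
    summarize,
)
from bihemi.diffexpr import FoldChangeRecord
from bihemi.reference_data import DIVERGENT_COMMON_GENES

signed_folds = st.one_of(
    st.floats(min_value=1.0, max_value=200.0, allow_nan=False),
    st.floats(min_value=-200.0, max_value=-1.0, allow_nan=False),
)


def _linear_oracle(fc: float) -> float:
    """Independent piecewise mapping to the linear expression scale."""
    if fc >= 1:
        return fc
    return 1.0 / abs(fc)


class TestFoldRatio:
    @pytest.mark.parametrize(
        "fc_ipsi,fc_contra,expected",
        [
            (4.22, -3.77, 15.91),  # up ipsi / down contra
            (-4.00, -7.97, 1.99),  # down both: larger remote decrease
            (2.31, -3.28, 7.58),
            (2.0, 2.0, 1.0),  # identical response
            (6.0, 2.0, 3.0),  # up both
        ],
    )
    def test_sign_cases(self, fc_ipsi, fc_contra, expected):
        assert round(fold_ratio(fc_ipsi, fc_contra), 2) == pytest.approx(expected)

    def test_fourth_sign_case_faithful_below_one(self):
        # down ipsi / up contra: faithful linear ratio is < 1
        assert fold_ratio(-3.0, 2.0) == pytest.approx((1 / 3) / 2)

    def test_fourth_sign_case_symmetric_flags_divergence(self):
        r = fold_ratio(-3.0, 2.0, mode="symmetric")
        assert r == pytest.approx(6.0)
        assert classify_common(r) == "different"

    def test_sub_unit_magnitude_rejected(self):
        with pytest.raises(ValueError):
            fold_ratio(0.5, 2.0)
        with pytest.raises(ValueError):
            fold_ratio(2.0, -0.9)

    @settings(derandomize=True, max_examples=300)
    @given(fi=signed_folds, fc=signed_folds)
    def test_equals_linear_scale_oracle(self, fi, fc):
        assert fold_ratio(fi, fc) == pytest.approx(
            _linear_oracle(fi) / _linear_oracle(fc)
        )

    def test_published_divergent_table_reproduced(self):
        """Recomputing every printed ratio from its printed fold changes
        lands within +/-0.03 (printed ratios carry rounding drift)."""
        for symbol, fi, fc, printed, _comp, _mtype in DIVERGENT_COMMON_GENES:
            recomputed = fold_ratio(fi, fc)
            assert recomputed == pytest.approx(printed, abs=0.03), symbol


class TestClassifyCommon:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(15.91, "different"), (1.76, "different"), (1.75, "similar"), (1.0, "similar")],
    )
    def test_strict_threshold(self, ratio, expected):
        assert classify_common(ratio) == expected

    def test_monotone_in_ratio(self):
        labels = [classify_common(r) for r in (1.0, 1.5, 1.75, 1.76, 3.0, 50.0)]
        # once "different", always "different"
        first_diff = labels.index("different")
        assert all(lab == "different" for lab in labels[first_diff:])
        assert all(lab == "similar" for lab in labels[:first_diff])


def _rec(gene, fc_i, fc_c, changed_i, changed_c):
    return FoldChangeRecord(
        gene_id=gene,
        fc_ipsi=fc_i,
        fc_contra=fc_c,
        present_ipsi=True,
        present_contra=True,
        changed_ipsi=changed_i,
        changed_contra=changed_c,
    )


class TestPartition:
    def test_common_similar_up(self):
        [c] = partition([_rec("g", 2.4, 2.0, True, True)])
        assert c.category == "common-similar-up"
        assert c.ratio == pytest.approx(1.2)

    def test_common_different_by_ratio(self):
        [c] = partition([_rec("g", 8.0, 2.0, True, True)])
        assert c.category == "common-different"

    def test_ipsi_unique_up(self):
        [c] = partition([_rec("g", 3.0, 1.2, True, False)])
        assert c.category == "ipsi-unique-up"
        assert c.ratio is None

    def test_contra_unique_down(self):
        [c] = partition([_rec("g", -1.2, -3.0, False, True)])
        assert c.category == "contra-unique-down"

    def test_unchanged(self):
        [c] = partition([_rec("g", 1.1, -1.2, False, False)])
        assert c.category == "unchanged"

    def test_restriction_to_gene_set(self):
        records = [_rec("in", 3.0, 1.0, True, False), _rec("out", 3.0, 1.0, True, False)]
        cls = partition(records, restrict_to={"in"})
        assert [c.gene_id for c in cls] == ["in"]

    def test_every_changed_gene_in_exactly_one_category(self):
        from bihemi.simulate import SimulationConfig, generate_expression
        from bihemi.diffexpr import fold_change_records

        ds, _ = generate_expression(SimulationConfig(n_genes=400, seed=5))
        records = fold_change_records(ds)
        cls = partition(records)
        assert len(cls) == len(records)
        assert len({c.gene_id for c in cls}) == len(records)


class TestSummarize:
    def test_published_breakdown_percentages(self):
        """Counts 79/30/37 common, 179/9 ipsi-unique, 10/28 contra-unique
        give the published 75/25/54/21/95/74 percentages."""
        cls = []
        sizes = {
            "common-similar-up": 79,
            "common-similar-down": 30,
            "common-different": 37,
            "ipsi-unique-up": 179,
            "ipsi-unique-down": 9,
            "contra-unique-up": 10,
            "contra-unique-down": 28,
        }
        from bihemi.bilateral import BilateralClassification

        for cat, n in sizes.items():
            cls += [BilateralClassification(f"{cat}{i}", cat) for i in range(n)]
        s = summarize(cls)
        assert s.common == 146
        assert s.ipsi_unique == 188
        assert s.contra_unique == 38
        assert s.total_changed == 372
        assert s.percent["similar"] == 75
        assert s.percent["different"] == 25
        assert s.percent["similar-up"] == 54
        assert s.percent["similar-down"] == 21
        assert s.percent["ipsi-unique-up"] == 95
        assert s.percent["contra-unique-down"] == 74

    def test_zero_denominator_marked_undefined(self):
        s = summarize([])
        assert s.percent["similar"] == "undefined"
        assert s.common == 0
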