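"""Cohort filters: thresholds, boundaries, commutation, concordance."""

from __future__ import annotations

import pytest

from famprior.filters import (
    FilterConfig,
    apply_depth_mask,
    fill_local_freq,
    filter_category,
    filter_frequency,
    pairwise_concordance,
)
from famprior.types import Category, Genotype


class TestFrequency:
    @pytest.mark.parametrize(
        "af_ex,af_ge,local,kept",
        [
            (0.0005, 0.0002, 0.01, True),
            (0.001, 0.0, 0.0, False),  # MAF comparator is strict
            (0.0, 0.001, 0.0, False),
            (None, None, None, True),  # absent frequencies count as rare
            (0.0005, 0.0002, 0.02, True),  # local cutoff is inclusive
            (0.0005, 0.0002, 0.021, False),
        ],
    )
    def test_boundaries(self, make_variant, af_ex, af_ge, local, kept):
        v = make_variant(
            af_gnomad_exome=af_ex, af_gnomad_genome=af_ge, local_freq=local
        )
        assert (len(filter_frequency([v])) == 1) is kept


class TestDepthMask:
    @pytest.mark.parametrize("depth,masked", [(11, False), (10, True), (None, True)])
    def test_trust_threshold(self, make_variant, depth, masked):
        v = make_variant(genotypes={"s1": Genotype(1, depth)})
        out = apply_depth_mask(v)
        assert out.genotypes["s1"].missing is masked
        if not masked:
            assert out.genotypes["s1"].alt_count == 1

    def test_original_record_untouched(self, make_variant):
        v = make_variant(genotypes={"s1": Genotype(1, 5)})
        apply_depth_mask(v)
        assert not v.genotypes["s1"].missing


class TestCategory:
    def test_regulatory_categories_kept(self, make_variant):
        kept = filter_category(
            [
                make_variant(category=Category.UTR5),
                make_variant(pos=101, category=Category.INTRONIC),
                make_variant(pos=102, category=Category.UPSTREAM_DOWNSTREAM),
            ]
        )
        assert [v.category for v in kept] == [
            Category.UTR5,
            Category.UPSTREAM_DOWNSTREAM,
        ]


def test_frequency_and_category_filters_commute(make_variant):
    variants = [
        make_variant(pos=100, category=Category.UTR5, af_gnomad_exome=0.0001),
        make_variant(pos=101, category=Category.INTRONIC, af_gnomad_exome=0.0001),
        make_variant(pos=102, category=Category.UTR3, af_gnomad_exome=0.5),
        make_variant(pos=103, category=Category.EXONIC, af_gnomad_exome=0.5),
    ]
    a = filter_category(filter_frequency(variants))
    b = filter_frequency(filter_category(variants))
    assert [v.key for v in a] == [v.key for v in b] == [variants[0].key]


class TestLocalFreq:
    def test_carrier_fraction_over_genotyped_samples(self, make_variant, gt):
        v = make_variant(
            genotypes={"a": gt(1), "b": gt(0), "c": gt(None), "d": gt(1)}
        )
        (out,) = fill_local_freq([v])
        assert out.local_freq == pytest.approx(2 / 3)  # c is missing

    def test_external_value_not_overwritten(self, make_variant, gt):
        v = make_variant(genotypes={"a": gt(1)}, local_freq=0.004)
        (out,) = fill_local_freq([v])
        assert out.local_freq == 0.004


class TestPairwiseConcordance:
    def test_identical_and_disjoint(self, make_variant, gt):
        variants = [
            make_variant(pos=100 + i, genotypes={"a": gt(1), "b": gt(1), "c": gt(0)})
            for i in range(3)
        ]
        m = pairwise_concordance(variants, ["a", "b", "c"])
        assert m.loc["a", "b"] == 1.0
        assert m.loc["a", "c"] == 0.0
        assert m.loc["a", "a"] == 1.0

    def test_three_shared_of_six_union(self, make_variant, gt):
        # a carries v1..v5, b carries v3..v6: shared {v3,v4,v5}, union 6
        variants = []
        for i in range(1, 7):
            variants.append(
                make_variant(
                    pos=100 + i,
                    genotypes={"a": gt(1 if i <= 5 else 0), "b": gt(1 if i >= 3 else 0)},
                )
            )
        m = pairwise_concordance(variants, ["a", "b"])
        assert m.loc["a", "b"] == pytest.approx(0.5)

    def test_zero_carrier_pair_defined_as_zero(self, make_variant, gt, caplog):
        variants = [make_variant(genotypes={"a": gt(0), "b": gt(0)})]
        with caplog.at_level("WARNING"):
            m = pairwise_concordance(variants, ["a", "b"])
        assert m.loc["a", "b"] == 0.0
        assert any("no variants" in r.message for r in caplog.records)
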