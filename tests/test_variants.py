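"""Variant normalization, matching, powered cross-validation, breakdowns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordkit.power import PowerParams, TumorContext
from concordkit.variants import (
    VariantCall,
    classify_discordant,
    match_callsets,
    normalize_variant,
    panel_concordance,
    powered_cross_validation,
)


def snv(chrom="chr1", pos=100, ref="A", alt="T", **kw):
    kw.setdefault("alt_reads", 40)
    kw.setdefault("depth", 100)
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


class TestVariantCall:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            VariantCall(chrom="chr1", pos=100, ref="A", alt="A")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            VariantCall(chrom="chr1", pos=100, ref="A", alt="N")

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "T", "SNV"), ("A", "AT", "insertion"), ("AT", "A", "deletion"),
         ("AC", "TG", "MNV")],
    )
    def test_class_inference(self, ref, alt, expected):
        assert snv(ref=ref, alt=alt).var_class == expected


class TestNormalize:
    def test_shared_prefix_trim(self):
        v = normalize_variant(snv(pos=100, ref="CT", alt="CA"))
        assert (v.pos, v.ref, v.alt) == (101, "T", "A")

    def test_shared_suffix_trim(self):
        v = normalize_variant(snv(pos=100, ref="TG", alt="AG"))
        assert (v.pos, v.ref, v.alt) == (100, "T", "A")

    def test_left_alignment_in_repeat(self):
        # context: positions 1..10 = GAAAATCGCG; deletion of one A written
        # rightmost (pos 4, AA->A) must shift to pos 1 (GA->G)
        ctx = "GAAAATCGCG"
        v = normalize_variant(
            snv(pos=4, ref="AA", alt="A"), ref_context=ctx, context_start=1
        )
        assert (v.pos, v.ref, v.alt) == (1, "GA", "G")

    @settings(derandomize=True, max_examples=300)
    @given(
        ref=st.text(alphabet="ACGT", min_size=1, max_size=6),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
        pos=st.integers(min_value=1, max_value=10_000),
    )
    def test_idempotence_property(self, ref, alt, pos):
        """normalize(normalize(v)) == normalize(v) for any allele pair."""
        if ref == alt:
            return
        v = snv(pos=pos, ref=ref, alt=alt)
        try:
            once = normalize_variant(v)
        except ValueError:
            return  # degenerates to ref==alt after trimming
        twice = normalize_variant(once)
        assert (once.pos, once.ref, once.alt) == (twice.pos, twice.ref, twice.alt)

    def test_idempotence_random_indels(self, rng):
        bases = "ACGT"
        for _ in range(1000):
            pos = int(rng.integers(5, 500))
            ref = "".join(bases[i] for i in rng.integers(0, 4, rng.integers(1, 5)))
            alt = "".join(bases[i] for i in rng.integers(0, 4, rng.integers(1, 5)))
            if ref == alt:
                continue
            v = snv(pos=pos, ref=ref, alt=alt)
            try:
                once = normalize_variant(v)
            except ValueError:
                continue  # degenerates to ref==alt after trimming
            twice = normalize_variant(once)
            assert (once.pos, once.ref, once.alt) == (twice.pos, twice.ref, twice.alt)


class TestMatch:
    def test_identical_sets_all_concordant(self):
        calls = [snv(pos=p) for p in range(100, 110)]
        table = match_callsets(calls, list(calls))
        assert table.n_concordant == 10
        assert not table.a_private and not table.b_private

    def test_disjoint_sets(self):
        a = [snv(pos=p) for p in range(100, 110)]
        b = [snv(pos=p) for p in range(200, 210)]
        table = match_callsets(a, b)
        assert table.n_concordant == 0
        assert len(table.a_private) == len(table.b_private) == 10

    def test_planted_split_counts(self, rng):
        shared = [snv(pos=int(p)) for p in rng.choice(10_000, 50, replace=False)]
        a_only = [snv(chrom="chr2", pos=p) for p in range(1, 21)]
        b_only = [snv(chrom="chr3", pos=p) for p in range(1, 31)]
        table = match_callsets(shared + a_only, shared + b_only)
        assert table.n_concordant == 50
        assert len(table.a_private) == 20
        assert len(table.b_private) == 30
        # partition invariants
        assert table.n_concordant + len(table.a_private) == 70
        assert table.n_concordant + len(table.b_private) == 80

    def test_duplicates_counted_once_with_warning(self):
        a = [snv(pos=100), snv(pos=100)]
        with pytest.warns(UserWarning):
            table = match_callsets(a, [snv(pos=100)])
        assert table.n_concordant == 1


class TestPoweredCrossValidation:
    def test_identical_sets_rate_one(self):
        calls = [snv(pos=p) for p in range(100, 120)]
        res = powered_cross_validation(
            calls, list(calls), {}, TumorContext(purity=0.8)
        )
        assert res.cross_validation_rate == 1.0
        assert res.n_total == 20

    def test_one_missed_at_saturating_depth(self):
        origin = [snv(pos=p) for p in range(100, 110)]
        other = origin[:-1]
        coverage = {("chr1", p): 10_000 for p in range(100, 110)}
        res = powered_cross_validation(origin, other, coverage, TumorContext(0.9))
        assert res.n_concordant == 9
        assert res.n_powered_missed == 1
        assert res.cross_validation_rate == pytest.approx(0.9)

    def test_planted_partition(self):
        """100 shared + 10 missed at saturation + 20 missed at depth 5."""
        shared = [snv(pos=p) for p in range(1, 101)]
        hi_missed = [snv(chrom="chr2", pos=p) for p in range(1, 11)]
        lo_missed = [snv(chrom="chr3", pos=p) for p in range(1, 21)]
        coverage = {("chr2", p): 10_000 for p in range(1, 11)}
        coverage.update({("chr3", p): 5 for p in range(1, 21)})
        res = powered_cross_validation(
            shared + hi_missed + lo_missed, shared, coverage, TumorContext(0.8)
        )
        assert (res.n_concordant, res.n_powered_missed, res.n_underpowered) == (
            100, 10, 20,
        )
        assert res.n_unassessable == 0
        assert res.cross_validation_rate == pytest.approx(100 / 110)

    def test_missing_depth_is_unassessable_not_false(self):
        origin = [snv(pos=100), snv(pos=200)]
        res = powered_cross_validation(origin, [], {}, TumorContext(0.8))
        assert res.n_unassessable == 2
        assert res.cross_validation_rate is None

    def test_empty_origin_rate_undefined(self):
        res = powered_cross_validation([], [snv()], {}, TumorContext(0.8))
        assert res.n_total == 0
        assert res.cross_validation_rate is None

    def test_symmetry_on_equal_sets(self):
        calls = [snv(pos=p) for p in range(50, 70)]
        for origin, other in ((calls, calls), (calls, calls)):
            res = powered_cross_validation(origin, other, {}, TumorContext(0.7))
            assert res.cross_validation_rate == 1.0


class TestClassifyDiscordant:
    def _calls(self, n_indel, n_snv, depth=100, af=0.4):
        alt = int(depth * af)
        calls = [
            snv(pos=1000 + i, ref="A", alt="AT", alt_reads=alt, depth=depth)
            for i in range(n_indel)
        ]
        calls += [
            snv(pos=5000 + i, alt_reads=alt, depth=depth) for i in range(n_snv)
        ]
        return calls

    def test_indel_fraction_61_percent(self):
        """374 indels of 613 well-supported private calls -> 61%."""
        out = classify_discordant(self._calls(374, 613 - 374))
        assert out["n_filtered"] == 613
        assert out["n_indel"] == 374
        assert out["indel_percent"] == 61

    def test_indel_fraction_70_percent(self):
        """206 indels of 294 well-supported private calls -> 70%."""
        out = classify_discordant(self._calls(206, 294 - 206))
        assert out["indel_percent"] == 70

    def test_all_snv_zero_percent(self):
        out = classify_discordant(self._calls(0, 40))
        assert out["indel_percent"] == 0

    def test_filters_depth_and_af(self):
        calls = [
            snv(pos=1, alt_reads=12, depth=29),   # depth too low
            snv(pos=2, alt_reads=2, depth=40),    # AF too low
            snv(pos=3, alt_reads=4, depth=40),    # passes (AF 0.1 inclusive)
        ]
        out = classify_discordant(calls)
        assert out["n_filtered"] == 1

    def test_empty_after_filter_flagged(self):
        out = classify_discordant([snv(alt_reads=1, depth=100)])
        assert out["n_filtered"] == 0
        assert out["indel_fraction"] is None


class TestPanelConcordance:
    def test_vacuous_agreement(self):
        table = match_callsets([snv(gene="OTHER")], [snv(gene="OTHER")])
        out = panel_concordance(table, ["TP53", "PTEN"])
        assert out["agreement"] == 1.0
        assert out["vacuous"]

    def test_identical_panel_calls(self):
        calls = [snv(pos=p, gene="TP53") for p in (10, 20)]
        out = panel_concordance(match_callsets(calls, list(calls)), ["TP53"])
        assert out["agreement"] == 1.0
        assert out["n_panel_calls"] == 2

    def test_one_private_of_five(self):
        genes = ["G1", "G2", "G3", "G4", "G5"]
        a = [snv(pos=i * 10, gene=g) for i, g in enumerate(genes, 1)]
        b = a[:4]  # G5 private to A
        out = panel_concordance(match_callsets(a, b), genes)
        assert out["agreement"] == pytest.approx(0.8)
        assert out["per_gene"]["G5"]["a_private"] == 1
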