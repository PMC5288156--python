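"""Generator contracts: determinism, planted structure, closed-form checks."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from concordkit.synthetic import (
    TruthConfig,
    attenuation_noise_sd,
    simulate_center_observation,
    simulate_expression_pair,
    simulate_fusion_calls,
    simulate_truth,
)


def binom_99_interval(n, p):
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    return lo, hi


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            TruthConfig(purity=0.0)
        with pytest.raises(ValueError):
            TruthConfig(indel_proportion=1.5)

    def test_overlapping_cn_segments_rejected(self):
        with pytest.raises(ValueError):
            TruthConfig(cn_segments=(("chr1", 0, 100, 4), ("chr1", 50, 200, 1)))

    def test_non_integer_copy_number_rejected(self):
        with pytest.raises(ValueError):
            TruthConfig(cn_segments=(("chr1", 0, 100, 2.5),))


class TestSimulateTruth:
    def test_counts_forced_by_config(self):
        cfg = TruthConfig(n_clonal_mutations=50, n_subclonal_mutations=0, seed=1)
        truth = simulate_truth(cfg)
        assert len(truth.mutations) == 50
        assert all(m.ccf == 1.0 for m in truth.mutations)

    def test_determinism_same_seed(self):
        cfg = TruthConfig(n_clonal_mutations=80, seed=1)
        t1, t2 = simulate_truth(cfg), simulate_truth(cfg)
        assert [(m.chrom, m.pos, m.ref, m.alt) for m in t1.mutations] == [
            (m.chrom, m.pos, m.ref, m.alt) for m in t2.mutations
        ]
        assert np.array_equal(t1.expression_log2_means, t2.expression_log2_means)

    def test_different_seed_differs(self):
        t1 = simulate_truth(TruthConfig(n_clonal_mutations=80, seed=1))
        t2 = simulate_truth(TruthConfig(n_clonal_mutations=80, seed=2))
        assert [m.pos for m in t1.mutations] != [m.pos for m in t2.mutations]

    def test_loci_unique(self):
        truth = simulate_truth(TruthConfig(n_clonal_mutations=500, seed=3))
        keys = [(m.chrom, m.pos) for m in truth.mutations]
        assert len(set(keys)) == len(keys)

    def test_indel_count_within_binomial_interval(self):
        """indel_proportion 0.3 with 1000 mutations: count in the 99% band."""
        cfg = TruthConfig(
            n_clonal_mutations=1000, indel_proportion=0.3, seed=7,
            targets_per_chromosome=600,
        )
        truth = simulate_truth(cfg)
        n_indel = sum(1 for m in truth.mutations if m.var_class != "SNV")
        lo, hi = binom_99_interval(1000, 0.3)
        assert lo <= n_indel <= hi


class TestCenterObservation:
    def test_saturation_emits_every_mutation(self):
        cfg = TruthConfig(
            n_clonal_mutations=100,
            mean_depth_center_A=10_000, mean_depth_center_B=10_000,
            caller_sensitivity_per_center={"A": 1.0, "B": 1.0},
            indel_sensitivity_per_center={"A": 1.0, "B": 1.0},
            caller_floor_alt_reads=1,
            seed=2,
        )
        truth = simulate_truth(cfg)
        calls, _ = simulate_center_observation(truth, "A", cfg)
        assert len(calls) == 100

    def test_zero_sensitivity_empty_call_set(self):
        cfg = TruthConfig(
            n_clonal_mutations=50,
            caller_sensitivity_per_center={"A": 0.0, "B": 0.0},
            indel_sensitivity_per_center={"A": 0.0, "B": 0.0},
            seed=2,
        )
        truth = simulate_truth(cfg)
        calls, _ = simulate_center_observation(truth, "A", cfg)
        assert calls == []

    def test_unknown_center_rejected(self, small_config):
        truth = simulate_truth(small_config)
        with pytest.raises(ValueError):
            simulate_center_observation(truth, "C", small_config)

    def test_observed_af_matches_closed_form(self):
        """purity 0.86, CN 2, multiplicity 1: mean AF of clonal SNVs near
        a*m / (2(1-a) + a*C) = 0.43 within Monte-Carlo error at n=500."""
        cfg = TruthConfig(
            purity=0.86, n_clonal_mutations=500, indel_proportion=0.0,
            mean_depth_center_A=300, seed=5, targets_per_chromosome=600,
        )
        truth = simulate_truth(cfg)
        calls, _ = simulate_center_observation(truth, "A", cfg)
        afs = [c.allele_fraction for c in calls]
        expected = 0.86 / (2 * 0.14 + 0.86 * 2)
        # MC error of the mean at n=500, per-site binomial sd ~ 0.03
        assert np.mean(afs) == pytest.approx(expected, abs=0.01)

    def test_mean_depth_within_5_percent(self):
        cfg = TruthConfig(
            n_clonal_mutations=10, targets_per_chromosome=600, seed=9,
        )
        truth = simulate_truth(cfg)
        for center, mean in (("A", cfg.mean_depth_center_A),
                             ("B", cfg.mean_depth_center_B)):
            _, profile = simulate_center_observation(truth, center, cfg)
            assert len(profile) >= 1000
            assert profile.depths.mean() == pytest.approx(mean, rel=0.05)

    def test_every_call_matches_a_truth_mutation(self, small_config):
        truth = simulate_truth(small_config)
        truth_keys = {(m.chrom, m.pos, m.ref, m.alt) for m in truth.mutations}
        for center in ("A", "B"):
            calls, _ = simulate_center_observation(truth, center, small_config)
            assert all(
                (c.chrom, c.pos, c.ref, c.alt) in truth_keys for c in calls
            )

    def test_coverage_covers_all_truth_loci(self, small_config):
        truth = simulate_truth(small_config)
        _, profile = simulate_center_observation(truth, "A", small_config)
        for m in truth.mutations:
            assert profile.depth_at(m.chrom, m.pos) is not None

    def test_private_mutations_only_in_their_center(self):
        cfg = TruthConfig(
            n_clonal_mutations=300,
            private_fraction_per_center={"A": 0.2, "B": 0.2},
            caller_sensitivity_per_center={"A": 1.0, "B": 1.0},
            indel_sensitivity_per_center={"A": 1.0, "B": 1.0},
            mean_depth_center_A=5000, mean_depth_center_B=5000,
            caller_floor_alt_reads=1, seed=13,
        )
        truth = simulate_truth(cfg)
        calls_b, _ = simulate_center_observation(truth, "B", cfg)
        keys_b = {(c.chrom, c.pos) for c in calls_b}
        a_private = [m for m in truth.mutations if m.private_to == "A"]
        assert a_private  # the fraction did plant some
        assert all((m.chrom, m.pos) not in keys_b for m in a_private)


class TestExpressionPair:
    def test_zero_noise_perfect_concordance(self, small_config):
        from concordkit.transcriptome import compute_rpkm, expression_concordance

        cfg = dataclasses.replace(small_config, expression_noise_sd=0.0)
        truth = simulate_truth(cfg)
        a, b = simulate_expression_pair(truth, cfg)
        out = expression_concordance(compute_rpkm(a), compute_rpkm(b))
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-6)

    def test_tuned_noise_gives_r2_080(self):
        from concordkit.transcriptome import compute_rpkm, expression_concordance

        cfg = TruthConfig(n_clonal_mutations=10, expression_n_genes=5000, seed=21)
        truth = simulate_truth(cfg)
        a, b = simulate_expression_pair(truth, cfg)
        out = expression_concordance(compute_rpkm(a), compute_rpkm(b))
        assert out["r_squared"] == pytest.approx(0.80, abs=0.02)

    def test_zero_genes_degenerate(self, small_config):
        from concordkit.transcriptome import compute_rpkm

        cfg = dataclasses.replace(small_config, expression_n_genes=0)
        truth = simulate_truth(cfg)
        a, b = simulate_expression_pair(truth, cfg)
        assert len(a) == 0 and len(b) == 0
        with pytest.raises(ValueError):
            compute_rpkm(a)  # empty table has no reads to normalize by

    def test_attenuation_helper_bounds(self):
        with pytest.raises(ValueError):
            attenuation_noise_sd(2.0, 0.0)
        assert attenuation_noise_sd(2.0, 1.0) == 0.0


class TestFusionCalls:
    def _cfg(self, n_fusions, sens, fp=0.0, seed=1):
        return TruthConfig(
            n_clonal_mutations=10,
            fusion_truth=tuple((f"F{i}A", f"F{i}B") for i in range(n_fusions)),
            fusion_caller_sensitivity={"caller1": sens, "caller2": sens},
            fusion_fp_rate=fp,
            seed=seed,
        )

    def test_perfect_sensitivity_dual_set_equals_truth(self):
        from concordkit.transcriptome import dual_caller_fusions, fusion_cross_validation

        cfg = self._cfg(10, 1.0)
        truth = simulate_truth(cfg)
        tables = simulate_fusion_calls(truth, cfg)
        for center in ("A", "B"):
            dual = dual_caller_fusions(tables[(center, "caller1")],
                                       tables[(center, "caller2")])
            assert sorted(f.pair for f in dual) == sorted(truth.fusion_truth)
        other = tables[("B", "caller1")] + tables[("B", "caller2")]
        dual_a = dual_caller_fusions(tables[("A", "caller1")],
                                     tables[("A", "caller2")])
        assert fusion_cross_validation(dual_a, other)["rate_percent"] == 100.0

    def test_zero_sensitivity_all_empty(self):
        cfg = self._cfg(10, 0.0)
        truth = simulate_truth(cfg)
        tables = simulate_fusion_calls(truth, cfg)
        assert all(v == [] for v in tables.values())

    def test_dual_set_size_within_binomial_interval(self):
        """20 true fusions, sensitivity 0.7 per caller: dual-set size is
        Binomial(20, 0.49); pooled over seeds it stays in the 99% band."""
        from concordkit.transcriptome import dual_caller_fusions

        total = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = self._cfg(20, 0.7, seed=seed)
            truth = simulate_truth(cfg)
            tables = simulate_fusion_calls(truth, cfg)
            dual = dual_caller_fusions(tables[("A", "caller1")],
                                       tables[("A", "caller2")])
            total += len(dual)
        lo, hi = binom_99_interval(20 * n_rep, 0.49)
        assert lo <= total <= hi

    def test_false_positives_are_novel_pairs(self):
        cfg = self._cfg(5, 1.0, fp=2.0)
        truth = simulate_truth(cfg)
        tables = simulate_fusion_calls(truth, cfg)
        truth_pairs = set(truth.fusion_truth)
        some_fp = False
        for calls in tables.values():
            for c in calls:
                if c.pair not in truth_pairs:
                    some_fp = True
        assert some_fp
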