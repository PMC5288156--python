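"""Synthetic paired-center tumor datasets with known ground truth.

The generator builds a small artificial exome — configurable chromosomes
and capture targets — plants a tumor truth set on it (somatic mutations
with cancer-cell fractions, an integer copy-number profile, log-normal
expression means, fusion transcripts), and then simulates what each of two
sequencing centers would observe:

* per-target depth, negative-binomially overdispersed around each center's
  mean target coverage (the centers differ, as real centers do);
* alt-read counts, binomial at the purity- and copy-number-adjusted allele
  fraction; a mutation is emitted as a call only when its alt reads reach
  the caller floor and a per-call sensitivity coin succeeds;
* sample heterogeneity: a configurable fraction of mutations private to
  each center's tumor piece (two pieces of one metastasis are not clonally
  identical);
* expression tables sharing truth means plus independent center noise;
* fusion call tables per (center, caller) with per-caller sensitivity and
  optional novel-pair false positives.

Every quantity the downstream concordance analyses estimate is therefore
known exactly, and all randomness flows from one master seed through named
substreams, so identical configs reproduce identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cnv import TargetInterval
from .coverage import CoverageProfile
from .transcriptome import FusionCall
from .variants import VariantCall

__all__ = [
    "TruthConfig",
    "TruthMutation",
    "TruthSet",
    "simulate_truth",
    "simulate_center_observation",
    "simulate_expression_pair",
    "simulate_fusion_calls",
    "build_genome",
    "attenuation_noise_sd",
]

_BASES = "ACGT"


def attenuation_noise_sd(signal_sd: float, target_r2: float) -> float:
    """Center noise sd that attenuates replicate correlation to sqrt(target_r2).

    Two centers observing the same truth with independent noise have
    Pearson r = s^2 / (s^2 + n^2); solving for the noise variance gives
    n^2 = s^2 * (1 - r) / r with r = sqrt(target_r2).
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError("target_r2 must be in (0, 1]")
    r = float(np.sqrt(target_r2))
    return float(signal_sd * np.sqrt((1.0 - r) / r))


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions for one synthetic tumor observed at two centers.

    Defaults describe a desk-scale version of a metastatic prostate tumor
    assayed at two experienced centers: high purity, a few hundred coding
    mutations with an indel minority, mean target coverage differing by
    center within the 120-270X range, shared copy-number events, expression
    concordance near r^2 = 0.8, and two fusion callers of imperfect
    sensitivity per center.
    """

    purity: float = 0.76
    n_clonal_mutations: int = 300
    n_subclonal_mutations: int = 0
    subclonal_fraction: float = 0.4
    indel_proportion: float = 0.15
    mean_depth_center_A: float = 265.0
    mean_depth_center_B: float = 150.0
    depth_dispersion: float = 8.0
    caller_sensitivity_per_center: dict = field(
        default_factory=lambda: {"A": 0.97, "B": 0.97}
    )
    indel_sensitivity_per_center: dict = field(
        default_factory=lambda: {"A": 0.80, "B": 0.80}
    )
    caller_floor_alt_reads: int = 3
    private_fraction_per_center: dict = field(
        default_factory=lambda: {"A": 0.0, "B": 0.0}
    )
    cn_segments: tuple = ()
    n_chromosomes: int = 2
    targets_per_chromosome: int = 1000
    target_length: int = 150
    target_spacing: int = 300
    expression_n_genes: int = 5000
    expression_log2_mean: float = 5.0
    expression_log2_sd: float = 2.0
    expression_noise_sd: float | None = None
    expression_target_r2: float = 0.8
    fusion_truth: tuple = (("TMPRSS2", "ERG"),)
    fusion_caller_sensitivity: dict = field(
        default_factory=lambda: {"caller1": 0.8, "caller2": 0.8}
    )
    fusion_fp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("purity", "subclonal_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.indel_proportion <= 1.0:
            raise ValueError(
                f"indel_proportion must be in [0, 1], got {self.indel_proportion}"
            )
        if self.fusion_fp_rate < 0:
            raise ValueError("fusion_fp_rate must be non-negative")
        if self.mean_depth_center_A <= 0 or self.mean_depth_center_B <= 0:
            raise ValueError("center mean depths must be positive")
        for d in (self.caller_sensitivity_per_center, self.indel_sensitivity_per_center):
            for c, s in d.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"sensitivity for center {c} must be in [0, 1]")
        for c, f in self.private_fraction_per_center.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"private fraction for center {c} must be in [0, 1]")
        _validate_cn_segments(self.cn_segments)

    @property
    def noise_sd(self) -> float:
        if self.expression_noise_sd is not None:
            return self.expression_noise_sd
        return attenuation_noise_sd(self.expression_log2_sd, self.expression_target_r2)

    def rng(self, stream: str) -> np.random.Generator:
        """Named, seed-derived substream: independent yet reproducible."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=tuple(ord(ch) for ch in stream)
        )
        return np.random.default_rng(ss)


def _validate_cn_segments(segments) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        chrom, start, end, cn = seg
        if start >= end:
            raise ValueError(f"empty CN segment {seg}")
        if int(cn) != cn or cn < 0:
            raise ValueError(f"copy number must be a non-negative integer, got {cn}")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CN segments on {chrom}")


@dataclass(frozen=True)
class TruthMutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str  # SNV | insertion | deletion
    ccf: float  # cancer-cell fraction
    gene: str
    copy_number: int = 2
    multiplicity: int = 1
    private_to: str | None = None  # center label, or None = present in both pieces


@dataclass
class TruthSet:
    """Ground truth for one tumor."""

    mutations: list[TruthMutation]
    purity: float
    genome: list[TargetInterval]
    gene_of_target: list[str]
    cn_segments: list[tuple]  # (chrom, start, end, int copy number)
    expression_log2_means: np.ndarray
    expression_genes: list[str]
    fusion_truth: list[tuple[str, str]]
    config: TruthConfig

    def copy_number_at(self, chrom: str, pos: int) -> int:
        for c, s, e, cn in self.cn_segments:
            if c == chrom and s < pos <= e:
                return int(cn)
        return 2

    @property
    def gene_targets(self) -> dict[str, list[TargetInterval]]:
        out: dict[str, list[TargetInterval]] = {}
        for iv, g in zip(self.genome, self.gene_of_target):
            out.setdefault(g, []).append(iv)
        return out


def build_genome(config: TruthConfig) -> tuple[list[TargetInterval], list[str]]:
    """The artificial exome: evenly spaced targets, ten targets per gene.

    Gene symbols are synthetic (``G<chrom>_<block>``); callers needing real
    symbols (panel audits) can rename blocks via the gene model they pass
    downstream.
    """
    intervals: list[TargetInterval] = []
    genes: list[str] = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        for t in range(config.targets_per_chromosome):
            start = t * config.target_spacing
            intervals.append(
                TargetInterval(
                    chrom=chrom,
                    start=start,
                    end=start + config.target_length,
                    id=f"{chrom}_t{t:05d}",
                )
            )
            genes.append(f"G{c}_{t // 10:04d}")
    return intervals, genes


def simulate_truth(config: TruthConfig) -> TruthSet:
    """Draw a tumor truth set under the configured study conditions."""
    rng = config.rng("truth")
    intervals, gene_of_target = build_genome(config)
    n_total = config.n_clonal_mutations + config.n_subclonal_mutations
    if n_total > len(intervals):
        raise ValueError("more mutations requested than targets available")

    # one mutation per target at most, so loci are unique after normalization
    target_idx = rng.choice(len(intervals), size=n_total, replace=False)
    is_indel = rng.random(n_total) < config.indel_proportion
    is_subclonal = np.zeros(n_total, dtype=bool)
    is_subclonal[config.n_clonal_mutations :] = True

    private_labels = _assign_private(rng, n_total, config)

    mutations: list[TruthMutation] = []
    for i, ti in enumerate(target_idx):
        iv = intervals[ti]
        pos = int(rng.integers(iv.start + 2, iv.end)) + 1  # 1-based, inside target
        ref = _BASES[rng.integers(4)]
        if is_indel[i]:
            if rng.random() < 0.5:
                ins = "".join(_BASES[b] for b in rng.integers(0, 4, rng.integers(1, 4)))
                alt = ref + ins
                var_class = "insertion"
            else:
                tail = "".join(_BASES[b] for b in rng.integers(0, 4, rng.integers(1, 4)))
                ref, alt, var_class = ref + tail, ref, "deletion"
        else:
            alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
            var_class = "SNV"
        cn = _cn_at(config.cn_segments, iv.chrom, pos)
        mutations.append(
            TruthMutation(
                chrom=iv.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                var_class=var_class,
                ccf=config.subclonal_fraction if is_subclonal[i] else 1.0,
                gene=gene_of_target[ti],
                copy_number=cn,
                multiplicity=1,
                private_to=private_labels[i],
            )
        )

    n_genes = config.expression_n_genes
    expr_rng = config.rng("expression_truth")
    log2_means = expr_rng.normal(
        config.expression_log2_mean, config.expression_log2_sd, n_genes
    )
    expr_genes = [f"EXPR_{i:05d}" for i in range(n_genes)]

    return TruthSet(
        mutations=mutations,
        purity=config.purity,
        genome=intervals,
        gene_of_target=gene_of_target,
        cn_segments=list(config.cn_segments),
        expression_log2_means=log2_means,
        expression_genes=expr_genes,
        fusion_truth=list(config.fusion_truth),
        config=config,
    )


def _assign_private(rng, n_total: int, config: TruthConfig) -> list[str | None]:
    labels: list[str | None] = [None] * n_total
    centers = sorted(config.private_fraction_per_center)
    u = rng.random(n_total)
    lo = 0.0
    for c in centers:
        f = config.private_fraction_per_center[c]
        hi = lo + f
        for i in range(n_total):
            if lo <= u[i] < hi:
                labels[i] = c
        lo = hi
    if lo > 1.0:
        raise ValueError("private fractions sum above 1")
    return labels


def _cn_at(segments, chrom: str, pos: int) -> int:
    for c, s, e, cn in segments:
        if c == chrom and s < pos <= e:
            return int(cn)
    return 2


def expected_allele_fraction(truth: TruthSet, mut: TruthMutation) -> float:
    """Purity/CN-adjusted expected AF of a truth mutation in the bulk sample.

    A mutation in a homozygously deleted region sits on zero retained
    copies and contributes no alt reads.
    """
    if mut.copy_number < 1:
        return 0.0
    a = truth.purity
    tumor_copies = 2.0 * (1.0 - a) + a * mut.copy_number
    return min(a * mut.multiplicity * mut.ccf / tumor_copies, 1.0)


def simulate_center_observation(
    truth: TruthSet, center: str, config: TruthConfig | None = None
) -> tuple[list[VariantCall], CoverageProfile]:
    """One center's somatic call set and coverage profile.

    Per-target depth ~ NegBin(mean = that center's MTC scaled by the local
    copy state, dispersion = config); alt reads ~ Binomial(depth, expected
    AF); a truth mutation is emitted iff it exists in this center's tumor
    piece, its alt reads reach the caller floor, and an independent
    sensitivity coin succeeds.  The coverage profile spans the full genome
    and hence every truth locus.
    """
    if config is None:
        config = truth.config
    if center not in config.caller_sensitivity_per_center:
        raise ValueError(
            f"unknown center {center!r}; known: "
            f"{sorted(config.caller_sensitivity_per_center)}"
        )
    rng = config.rng(f"observe_{center}")
    mean_depth = (
        config.mean_depth_center_A if center == "A" else config.mean_depth_center_B
    )
    a = truth.purity

    # depth per target, scaled by the bulk copy state of the target
    n_targets = len(truth.genome)
    scale = np.ones(n_targets)
    for i, iv in enumerate(truth.genome):
        cn = truth.copy_number_at(iv.chrom, iv.start + 1)
        scale[i] = (2.0 * (1.0 - a) + a * cn) / 2.0
    r = config.depth_dispersion
    mu = mean_depth * scale
    p = r / (r + mu)
    depths = rng.negative_binomial(r, p).astype(float)
    profile = CoverageProfile(intervals=list(truth.genome), depths=depths)

    sensitivity = config.caller_sensitivity_per_center[center]
    indel_sensitivity = config.indel_sensitivity_per_center.get(center, sensitivity)
    floor = config.caller_floor_alt_reads
    # index targets by locus for depth lookup
    calls: list[VariantCall] = []
    for mut in truth.mutations:
        if mut.private_to is not None and mut.private_to != center:
            continue
        depth = profile.depth_at(mut.chrom, mut.pos)
        if depth is None or depth == 0:
            continue
        f = expected_allele_fraction(truth, mut)
        alt_reads = int(rng.binomial(int(depth), min(f, 1.0)))
        if alt_reads < floor:
            continue
        # indels are harder to call reproducibly; separate sensitivity
        sens = indel_sensitivity if mut.var_class != "SNV" else sensitivity
        if rng.random() >= sens:
            continue
        calls.append(
            VariantCall(
                chrom=mut.chrom,
                pos=mut.pos,
                ref=mut.ref,
                alt=mut.alt,
                alt_reads=alt_reads,
                depth=int(depth),
                gene=mut.gene,
                nonsynonymous=True,
                var_class=mut.var_class,
            )
        )
    return calls, profile


def simulate_expression_pair(
    truth: TruthSet, config: TruthConfig | None = None
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Two centers' expression tables sharing truth means.

    Each center observes log2-rpkm = truth mean + Normal(0, noise_sd)
    independently; tables carry (gene, length_bp, count) with counts derived
    from the observed rpkm at a nominal 50M mapped reads, so recomputing
    RPKM downstream reproduces the intended concordance structure.
    """
    import pandas as pd

    if config is None:
        config = truth.config
    n = len(truth.expression_genes)
    if n == 0:
        empty = pd.DataFrame(columns=["gene", "length_bp", "count"])
        return empty.copy(), empty.copy()
    sd = config.noise_sd
    total = 50_000_000
    rng_len = config.rng("expression_lengths")
    lengths = rng_len.integers(500, 5001, n)
    tables = []
    for center in ("A", "B"):
        rng = config.rng(f"expression_{center}")
        log2_obs = truth.expression_log2_means + rng.normal(0.0, sd, n)
        rpkm = np.power(2.0, log2_obs)
        counts = np.rint(rpkm * lengths * total / 1e9).astype(np.int64)
        tables.append(
            pd.DataFrame(
                {
                    "gene": truth.expression_genes,
                    "length_bp": lengths,
                    "count": counts,
                }
            )
        )
    return tables[0], tables[1]


def simulate_fusion_calls(
    truth: TruthSet,
    config: TruthConfig | None = None,
    centers: Sequence[str] = ("A", "B"),
) -> dict[tuple[str, str], list[FusionCall]]:
    """Fusion call tables per (center, caller).

    Each caller at each center detects each true fusion independently with
    its configured sensitivity; false positives (novel synthetic gene
    pairs, unique per table) are added at rate ``fusion_fp_rate`` per true
    fusion slot.
    """
    if config is None:
        config = truth.config
    out: dict[tuple[str, str], list[FusionCall]] = {}
    for center in centers:
        for caller, sens in config.fusion_caller_sensitivity.items():
            rng = config.rng(f"fusion_{center}_{caller}")
            calls = []
            for g5, g3 in truth.fusion_truth:
                if rng.random() < sens:
                    calls.append(
                        FusionCall(
                            gene5=g5,
                            gene3=g3,
                            caller=caller,
                            center=center,
                            junction_reads=int(rng.integers(3, 50)),
                        )
                    )
            if config.fusion_fp_rate > 0:
                n_fp = rng.poisson(config.fusion_fp_rate * max(len(truth.fusion_truth), 1))
                for k in range(n_fp):
                    calls.append(
                        FusionCall(
                            gene5=f"FP{center}{caller}_{k}A",
                            gene3=f"FP{center}{caller}_{k}B",
                            caller=caller,
                            center=center,
                            junction_reads=int(rng.integers(2, 10)),
                        )
                    )
            out[(center, caller)] = calls
    return out
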