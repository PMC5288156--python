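"""Exome copy-number analysis: copy ratios, CBS segmentation, gene calls.

Copy ratios are formed per capture target by dividing tumor depth by the
median depth of a panel of normal samples at the same target, log2
transforming, and median-centering the tumor track to remove library-size
effects.  The ordered per-target track is then segmented with circular
binary segmentation (CBS): recursively find the arc (i, j] of the target
sequence that maximizes a two-sample t-like statistic between the arc and
its complement, accept the split when a permutation test deems it
significant, and recurse into the pieces.  Genes are called from the
n_target-weighted mean of the segments they overlap: amplification above
log2(4) = 2, deletion below log2(0.5) = -1, with shallower configurable
gain/loss thresholds for reporting single-copy events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TargetInterval",
    "CopyRatioTrack",
    "CopySegment",
    "GeneCnaCall",
    "CnaThresholds",
    "copy_ratio",
    "cbs_segment",
    "call_gene_cna",
    "cna_concordance",
    "best_split",
]


@dataclass(frozen=True)
class TargetInterval:
    """A capture target: 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyRatioTrack:
    """Per-target log2 copy ratios aligned to an ordered interval list."""

    intervals: list[TargetInterval]
    log2_ratios: np.ndarray

    def __post_init__(self) -> None:
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        if len(self.intervals) != self.log2_ratios.size:
            raise ValueError("intervals and ratios must align")
        if not np.all(np.isfinite(self.log2_ratios)):
            raise ValueError("log2 ratios must be finite")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class CopySegment:
    chrom: str
    start: int
    end: int
    n_targets: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("segment must cover >= 1 target")


@dataclass(frozen=True)
class CnaThresholds:
    """Gene-call cutoffs on segment mean log2 copy ratio.

    Amplification/deletion follow the focal-event convention
    (log2(4) = 2.0 and log2(0.5) = -1.0); gain/loss are shallower
    reporting thresholds with no canonical value.
    """

    amplification: float = 2.0
    deletion: float = -1.0
    gain: float = 0.3
    loss: float = -0.3


@dataclass(frozen=True)
class GeneCnaCall:
    gene: str
    call: str  # amplification | gain | neutral | loss | deletion | not_assessable
    seg_mean: float | None


def copy_ratio(
    tumor_depth: np.ndarray,
    normal_depths: Sequence[np.ndarray],
    intervals: Sequence[TargetInterval],
    min_normal_median: float = 10.0,
) -> CopyRatioTrack:
    """Per-target log2(tumor / median normal), median-centered.

    Targets whose median normal depth falls below ``min_normal_median`` are
    masked (dropped from the output track) — they carry no reliable ratio
    and would otherwise divide by ~zero.
    """
    if len(normal_depths) < 1:
        raise ValueError("need at least one normal depth track")
    tumor = np.asarray(tumor_depth, dtype=float)
    normals = np.vstack([np.asarray(d, dtype=float) for d in normal_depths])
    if normals.shape[1] != tumor.size or tumor.size != len(intervals):
        raise ValueError("all tracks must align to the same intervals")
    med = np.median(normals, axis=0)
    keep = med >= min_normal_median
    ratio = np.log2(np.maximum(tumor[keep], 0.5) / med[keep])
    ratio = ratio - np.median(ratio)
    kept_intervals = [iv for iv, k in zip(intervals, keep) if k]
    return CopyRatioTrack(intervals=kept_intervals, log2_ratios=ratio)


# ---------------------------------------------------------------------------
# circular binary segmentation


_ARC_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}


def _arc_aux(n: int, min_width: int):
    """Cached per-length matrices for the arc statistic (see _arc_stats)."""
    key = (n, min_width)
    if key not in _ARC_CACHE:
        if len(_ARC_CACHE) > 64:
            _ARC_CACHE.clear()
        idx = np.arange(n + 1)
        k = idx[None, :] - idx[:, None]  # arc length j - i
        valid = (k >= min_width) & ((n - k) >= min_width)
        kf = np.where(valid, k, 1).astype(float)
        nkf = np.where(valid, n - k, 1).astype(float)
        ab = 1.0 / kf + 1.0 / nkf
        b = 1.0 / nkf
        denom = 1.0 / np.sqrt(ab)
        _ARC_CACHE[key] = (valid, ab, b, denom)
    return _ARC_CACHE[key]


def _arc_stats(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Best arc (i, j] of x by the two-sample t-like statistic.

    For arc sum S over k targets out of n with total T, the statistic is
        |S/k - (T-S)/(n-k)| / sqrt(1/k + 1/(n-k))
    i.e. the mean difference between arc and complement on a pooled unit
    scale (the global variance is a common factor and is omitted).  Returns
    (statistic, i, j); (nan, -1, -1) when no admissible arc exists.
    """
    n = x.size
    if n < 2 * min_width:
        return float("nan"), -1, -1
    valid, ab, b, denom = _arc_aux(n, min_width)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    S = cs[None, :] - cs[:, None]  # S[i, j] = sum of x[i:j]
    stat = np.abs(S * ab - total * b) * denom
    stat[~valid] = -np.inf
    flat = int(np.argmax(stat))
    i, j = divmod(flat, n + 1)
    if not np.isfinite(stat[i, j]):
        return float("nan"), -1, -1
    return float(stat[i, j]), i, j


def best_split(x: np.ndarray, min_width: int = 2) -> tuple[float, int, int]:
    """Exposed for oracle comparison: the maximal arc statistic and (i, j]."""
    return _arc_stats(np.asarray(x, dtype=float), min_width)


def _permutation_p(
    x: np.ndarray,
    observed: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    alpha: float,
) -> float:
    """Permutation p-value of the observed max arc statistic.

    Target order within the piece is permuted; early-stops once enough
    exceedances accumulate to rule out significance at ``alpha``.
    """
    stop_after = int(np.ceil(alpha * n_perm)) + 1
    exceed = 0
    for b in range(n_perm):
        perm = rng.permutation(x)
        s, _, _ = _arc_stats(perm, min_width)
        if np.isnan(s):
            continue
        if s >= observed:
            exceed += 1
            if exceed >= stop_after:
                # p-value already > alpha; report a conservative estimate
                return (exceed + 1) / (b + 2)
    return (exceed + 1) / (n_perm + 1)


def _segment_piece(
    x: np.ndarray,
    offset: int,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    breaks: list[int],
) -> None:
    """Recursively collect internal breakpoints (as global indices)."""
    n = x.size
    if n < 2 * min_width:
        return
    if np.allclose(x, x[0]):
        return  # constant piece can never split
    stat, i, j = _arc_stats(x, min_width)
    if not np.isfinite(stat) or i < 0:
        return
    p = _permutation_p(x, stat, n_perm, min_width, rng, alpha)
    if p >= alpha:
        return
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    if not cuts:
        return
    for c in cuts:
        breaks.append(offset + c)
    pieces = np.split(x, cuts)
    starts = [0] + cuts
    for piece, s in zip(pieces, starts):
        _segment_piece(piece, offset + s, alpha, n_perm, min_width, rng, breaks)


def cbs_segment(
    track: CopyRatioTrack,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> list[CopySegment]:
    """Segment a copy-ratio track by circular binary segmentation.

    Each chromosome is segmented independently.  The best circular arc is
    accepted as a change when its max statistic beats ``alpha`` under
    within-chromosome permutation of target order (seeded, hence
    reproducible); accepted cuts are recursed.  Segments carry the mean
    log2 ratio and target count; together they tile the track exactly.
    """
    if len(track) == 0:
        return []
    rng = np.random.default_rng(seed)
    segments: list[CopySegment] = []
    # group consecutive targets by chromosome, preserving order
    chroms: list[tuple[str, int, int]] = []
    start = 0
    for idx in range(1, len(track) + 1):
        if idx == len(track) or track.intervals[idx].chrom != track.intervals[start].chrom:
            chroms.append((track.intervals[start].chrom, start, idx))
            start = idx
    for chrom, lo, hi in chroms:
        x = track.log2_ratios[lo:hi]
        breaks: list[int] = []
        _segment_piece(x, 0, alpha, n_perm, min_width, rng, breaks)
        bounds = [0] + sorted(set(breaks)) + [hi - lo]
        for a, b in zip(bounds[:-1], bounds[1:]):
            ivs = track.intervals[lo + a : lo + b]
            segments.append(
                CopySegment(
                    chrom=chrom,
                    start=ivs[0].start,
                    end=ivs[-1].end,
                    n_targets=b - a,
                    seg_mean=float(np.mean(x[a:b])),
                )
            )
    return segments


def call_gene_cna(
    segments: Sequence[CopySegment],
    gene_targets: dict[str, list[TargetInterval]],
    thresholds: CnaThresholds | None = None,
) -> list[GeneCnaCall]:
    """Call per-gene copy-number events from segment means.

    A gene's value is the n_target-weighted mean of the segments
    overlapping its target intervals; genes overlapping no segment are
    returned as ``not_assessable``.
    """
    if thresholds is None:
        thresholds = CnaThresholds()
    calls = []
    for gene, targets in gene_targets.items():
        w_sum = 0.0
        v_sum = 0.0
        for seg in segments:
            n_overlap = sum(
                1
                for t in targets
                if t.chrom == seg.chrom and t.start < seg.end and t.end > seg.start
            )
            if n_overlap:
                w_sum += n_overlap
                v_sum += n_overlap * seg.seg_mean
        if w_sum == 0:
            calls.append(GeneCnaCall(gene=gene, call="not_assessable", seg_mean=None))
            continue
        m = v_sum / w_sum
        if m > thresholds.amplification:
            call = "amplification"
        elif m < thresholds.deletion:
            call = "deletion"
        elif m > thresholds.gain:
            call = "gain"
        elif m < thresholds.loss:
            call = "loss"
        else:
            call = "neutral"
        calls.append(GeneCnaCall(gene=gene, call=call, seg_mean=float(m)))
    return calls


def cna_concordance(
    calls_a: Sequence[GeneCnaCall],
    calls_b: Sequence[GeneCnaCall],
    track_a: CopyRatioTrack | None = None,
    track_b: CopyRatioTrack | None = None,
) -> dict:
    """Cross-center agreement of gene calls and per-target ratio correlation.

    Gene agreement is computed over genes assessable at both centers; the
    Pearson correlation uses targets shared (by coordinate) between the two
    tracks and is None when no targets are shared or a track is absent.
    """
    a_map = {c.gene: c.call for c in calls_a}
    b_map = {c.gene: c.call for c in calls_b}
    shared = [
        g
        for g in a_map
        if g in b_map and a_map[g] != "not_assessable" and b_map[g] != "not_assessable"
    ]
    n_agree = sum(1 for g in shared if a_map[g] == b_map[g])
    agreement = n_agree / len(shared) if shared else None

    correlation = None
    if track_a is not None and track_b is not None:
        key = lambda iv: (iv.chrom, iv.start, iv.end)
        pos_b = {key(iv): i for i, iv in enumerate(track_b.intervals)}
        pairs = [
            (track_a.log2_ratios[i], track_b.log2_ratios[pos_b[key(iv)]])
            for i, iv in enumerate(track_a.intervals)
            if key(iv) in pos_b
        ]
        if len(pairs) >= 3:
            xa, xb = np.array(pairs).T
            if xa.std() > 0 and xb.std() > 0:
                correlation = float(np.corrcoef(xa, xb)[0, 1])
    return {
        "n_genes_compared": len(shared),
        "n_agree": n_agree,
        "gene_agreement": agreement,
        "discordant_genes": sorted(g for g in shared if a_map[g] != b_map[g]),
        "target_correlation": correlation,
    }
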