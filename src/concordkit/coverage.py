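"""Targeted-sequencing coverage audits over gene panels.

A coverage profile is a list of capture targets (0-based half-open
intervals) with a mean depth per target.  Per-gene mean target coverage
(MTC) is the base-weighted mean depth over the gene's targeted bases — the
standard hybrid-selection metric — and threshold audits report the fraction
of targeted bases at or above a depth cutoff.  The packaged ACMG-56 panel
(the ACMG list of genes in which incidental germline findings should be
reported) can be audited for the conventional 30X floor and 50X MTC flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .cnv import TargetInterval

__all__ = [
    "CoverageProfile",
    "PanelAuditReport",
    "gene_mean_target_coverage",
    "threshold_coverage_fraction",
    "flag_low_coverage_genes",
    "acmg_audit",
    "load_acmg56",
]


def load_acmg56() -> list[str]:
    """The packaged ACMG-56 gene symbol list."""
    text = resources.files("concordkit.data").joinpath("acmg56.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class CoverageProfile:
    """Per-target mean depth over an ordered interval list."""

    intervals: list[TargetInterval]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.intervals) != self.depths.size:
            raise ValueError("intervals and depths must align")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        self._by_pos: dict[tuple[str, int], float] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_targets(self) -> int:
        return len(self.intervals)

    @property
    def zero_coverage_targets(self) -> int:
        return int((self.depths == 0).sum())

    @property
    def mean_target_coverage(self) -> float:
        """Base-weighted mean depth over all targets."""
        lengths = np.array([iv.length for iv in self.intervals], dtype=float)
        return float((self.depths * lengths).sum() / lengths.sum())

    def depth_at(self, chrom: str, pos: int) -> float | None:
        """Depth of the target containing 1-based position ``pos``, else None."""
        if self._by_pos is None:
            self._by_pos = {}
            for iv, d in zip(self.intervals, self.depths):
                for p in range(iv.start + 1, iv.end + 1):  # 1-based positions
                    self._by_pos[(iv.chrom, p)] = float(d)
        return self._by_pos.get((chrom, pos))


@dataclass
class PanelAuditReport:
    """Panel-wide coverage audit."""

    per_gene_mtc: dict[str, float | None]
    per_gene_fraction_ge_threshold: dict[str, float | None]
    threshold: float
    mtc_flag_threshold: float
    missing_genes: list[str] = field(default_factory=list)

    @property
    def genes_below_mtc_flag(self) -> list[str]:
        return flag_low_coverage_genes(self.per_gene_mtc, self.mtc_flag_threshold)

    @property
    def all_genes_ge_threshold(self) -> bool:
        vals = [v for v in self.per_gene_fraction_ge_threshold.values() if v is not None]
        return bool(vals) and all(v >= 1.0 for v in vals)

    @property
    def percent_genes_passing_threshold(self) -> float | None:
        vals = [v for v in self.per_gene_fraction_ge_threshold.values() if v is not None]
        if not vals:
            return None
        return 100.0 * sum(1 for v in vals if v >= 1.0) / len(vals)


def _gene_base_depths(
    profile: CoverageProfile, targets: Sequence[TargetInterval]
) -> tuple[float, float]:
    """(total bases, depth*bases) of a gene's targets intersected with the profile."""
    bases = 0.0
    weighted = 0.0
    for t in targets:
        for iv, d in zip(profile.intervals, profile.depths):
            if iv.chrom != t.chrom:
                continue
            lo = max(iv.start, t.start)
            hi = min(iv.end, t.end)
            if lo < hi:
                bases += hi - lo
                weighted += (hi - lo) * d
    return bases, weighted


def gene_mean_target_coverage(
    profile: CoverageProfile,
    gene_targets: Mapping[str, Sequence[TargetInterval]],
) -> dict[str, float | None]:
    """Base-weighted mean depth per gene; None when no targets intersect."""
    out: dict[str, float | None] = {}
    for gene, targets in gene_targets.items():
        bases, weighted = _gene_base_depths(profile, targets)
        out[gene] = weighted / bases if bases else None
    return out


def threshold_coverage_fraction(
    profile: CoverageProfile,
    gene_targets: Mapping[str, Sequence[TargetInterval]],
    threshold: float = 30.0,
) -> tuple[dict[str, float | None], float | None]:
    """Fraction of targeted bases with depth >= threshold, per gene and panel-wide.

    Depth is the target's mean depth applied to each of its bases (the
    profile's resolution); panel-wide is the base-weighted aggregate, which
    equals the base-weighted mean of per-gene fractions.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    per_gene: dict[str, float | None] = {}
    tot_bases = 0.0
    tot_ok = 0.0
    for gene, targets in gene_targets.items():
        bases = 0.0
        ok = 0.0
        for t in targets:
            for iv, d in zip(profile.intervals, profile.depths):
                if iv.chrom != t.chrom:
                    continue
                lo = max(iv.start, t.start)
                hi = min(iv.end, t.end)
                if lo < hi:
                    bases += hi - lo
                    if d >= threshold:
                        ok += hi - lo
        per_gene[gene] = ok / bases if bases else None
        tot_bases += bases
        tot_ok += ok
    panel = tot_ok / tot_bases if tot_bases else None
    return per_gene, panel


def flag_low_coverage_genes(
    per_gene_mtc: Mapping[str, float | None], flag_threshold: float = 50.0
) -> list[str]:
    """Genes with MTC strictly below the flag threshold, lowest first.

    A gene at exactly the threshold is not flagged; genes without coverage
    data (None) are excluded here and surfaced as missing elsewhere.
    """
    if flag_threshold <= 0:
        raise ValueError("flag_threshold must be positive")
    flagged = [
        (mtc, g)
        for g, mtc in per_gene_mtc.items()
        if mtc is not None and mtc < flag_threshold
    ]
    return [g for _, g in sorted(flagged)]


def acmg_audit(
    profile: CoverageProfile,
    gene_targets: Mapping[str, Sequence[TargetInterval]],
    panel: Sequence[str] | None = None,
    threshold: float = 30.0,
    mtc_flag_threshold: float = 50.0,
) -> PanelAuditReport:
    """Audit a germline coverage profile against a gene panel.

    Defaults to the packaged ACMG-56 list, the 30X per-base floor used for
    germline variant discovery, and a 50X MTC flag.  Panel genes without
    supplied target intervals are reported as missing, never dropped
    silently.
    """
    if panel is None:
        panel = load_acmg56()
    panel_targets = {g: gene_targets.get(g, []) for g in panel}
    mtc = gene_mean_target_coverage(profile, panel_targets)
    frac, _ = threshold_coverage_fraction(profile, panel_targets, threshold)
    missing = sorted(g for g in panel if mtc.get(g) is None)
    return PanelAuditReport(
        per_gene_mtc=mtc,
        per_gene_fraction_ge_threshold=frac,
        threshold=threshold,
        mtc_flag_threshold=mtc_flag_threshold,
        missing_genes=missing,
    )
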