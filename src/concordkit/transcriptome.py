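"""Expression (RPKM) and fusion-transcript concordance between centers.

Expression concordance: gene counts are normalized to RPKM (reads per
kilobase of exon model per million mapped reads), log2(rpkm + offset)
transformed, and compared between centers by Pearson correlation over the
gene intersection; r and r^2 are reported.

Fusion concordance mirrors a two-step multi-caller design: within one
center, the "dual-caller" set is the orientation-aware intersection of two
independent callers' (5' gene, 3' gene) pairs; across centers, the
cross-validation rate is the fraction of one center's dual-caller fusions
found anywhere in the other center's (pooled) calls, quoted as a percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FusionCall",
    "compute_rpkm",
    "expression_concordance",
    "dual_caller_fusions",
    "fusion_cross_validation",
]


@dataclass(frozen=True)
class FusionCall:
    """A fusion transcript as an ordered (5' partner, 3' partner) gene pair."""

    gene5: str
    gene3: str
    caller: str = ""
    center: str = ""
    junction_reads: int | None = None

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("fusion partners must be non-empty symbols")
        if self.gene5 == self.gene3:
            raise ValueError(f"5' and 3' partners identical: {self.gene5}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


def compute_rpkm(
    counts: pd.DataFrame, total_mapped: int | None = None
) -> pd.DataFrame:
    """Add an ``rpkm`` column to a (gene, length_bp, count) table.

    rpkm = 1e9 * count / (total_mapped * length_bp).  When ``total_mapped``
    is not given, the table's count sum is used (the usual convention when
    only gene-level counts are available).
    """
    required = {"gene", "length_bp", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["length_bp"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if total_mapped is None:
        total_mapped = int(counts["count"].sum())
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    out = counts.copy()
    out["rpkm"] = 1e9 * out["count"] / (float(total_mapped) * out["length_bp"])
    return out


def expression_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    log_offset: float = 1.0,
    log_scale: bool = True,
) -> dict:
    """Pearson concordance of two centers' expression tables.

    Tables need ``gene`` and ``rpkm`` columns (see :func:`compute_rpkm`);
    correlation is computed on log2(rpkm + log_offset) over the gene
    intersection (or raw rpkm with ``log_scale=False``).  Returns r, r^2,
    and the number of shared genes; zero variance in either vector yields
    r = None with a flag.
    """
    for name, t in (("A", a), ("B", b)):
        if not {"gene", "rpkm"}.issubset(t.columns):
            raise ValueError(f"table {name} needs 'gene' and 'rpkm' columns")
    merged = a[["gene", "rpkm"]].merge(
        b[["gene", "rpkm"]], on="gene", suffixes=("_a", "_b")
    )
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 shared genes, have {n}")
    xa = merged["rpkm_a"].to_numpy(dtype=float)
    xb = merged["rpkm_b"].to_numpy(dtype=float)
    if log_scale:
        xa = np.log2(xa + log_offset)
        xb = np.log2(xb + log_offset)
    if xa.std() == 0 or xb.std() == 0:
        return {"r": None, "r_squared": None, "n_genes": n, "zero_variance": True}
    r = float(stats.pearsonr(xa, xb).statistic)
    return {"r": r, "r_squared": r * r, "n_genes": n, "zero_variance": False}


def dual_caller_fusions(
    calls_1: Iterable[FusionCall], calls_2: Iterable[FusionCall]
) -> list[FusionCall]:
    """Fusions reported by both callers on one sample.

    Match is the orientation-aware (gene5, gene3) key: A->B and B->A are
    different fusions.  The two inputs must come from distinct callers.
    """
    calls_1 = list(calls_1)
    calls_2 = list(calls_2)
    labels_1 = {c.caller for c in calls_1}
    labels_2 = {c.caller for c in calls_2}
    if calls_1 and calls_2 and labels_1 == labels_2 and len(labels_1) == 1:
        raise ValueError(f"both inputs carry the same caller label {labels_1}")
    pairs_2 = {c.pair for c in calls_2}
    seen: set[tuple[str, str]] = set()
    out = []
    for c in calls_1:
        if c.pair in pairs_2 and c.pair not in seen:
            seen.add(c.pair)
            out.append(c)
    return out


def fusion_cross_validation(
    dual_origin: Sequence[FusionCall],
    other_center_calls: Iterable[FusionCall],
) -> dict:
    """Cross-center validation rate of one center's dual-caller fusions.

    rate = percent of ``dual_origin`` pairs present (any caller) in the
    other center's calls.  An empty dual-caller set makes the rate
    undefined ("not assessable"), never 0 or 100.
    """
    origin_pairs = []
    seen: set[tuple[str, str]] = set()
    for c in dual_origin:
        if c.pair not in seen:
            seen.add(c.pair)
            origin_pairs.append(c.pair)
    other_pairs = {c.pair for c in other_center_calls}
    n = len(origin_pairs)
    if n == 0:
        return {
            "n_dual": 0,
            "n_validated": 0,
            "rate_percent": None,
            "assessable": False,
            "validated": [],
            "unvalidated": [],
        }
    validated = [p for p in origin_pairs if p in other_pairs]
    return {
        "n_dual": n,
        "n_validated": len(validated),
        "rate_percent": 100.0 * len(validated) / n,
        "assessable": True,
        "validated": validated,
        "unvalidated": [p for p in origin_pairs if p not in other_pairs],
    }
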