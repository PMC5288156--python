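"""Somatic call-set normalization, matching and powered cross-validation.

Two sequencing centers calling somatic variants on the same tumor disagree
for three distinct reasons: representation (the same indel written two
ways), power (one center's depth too low to see the variant), and genuine
discordance.  This module separates them: variants are normalized to a
canonical (chrom, pos, ref, alt) key, matched exactly, and each call private
to one center is classified by whether the other center was adequately
powered at that locus.  The cross-validation rate is the fraction of
powered calls that the other center confirmed:

    rate = n_concordant / (n_concordant + n_powered_missed)

Underpowered and depth-unknown loci are reported separately and never
counted as disagreements.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .power import UNASSESSABLE, PowerParams, TumorContext, is_powered

__all__ = [
    "VariantCall",
    "MatchTable",
    "ConcordanceResult",
    "normalize_variant",
    "match_callsets",
    "powered_cross_validation",
    "classify_discordant",
    "panel_concordance",
]

_VALID_BASES = frozenset("ACGT")
_CLASSES = ("SNV", "insertion", "deletion", "MNV")


@dataclass(frozen=True)
class VariantCall:
    """One normalized somatic variant call.

    Coordinates are 1-based inclusive (VCF convention).  ``var_class`` is
    derived from allele lengths when not supplied.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int = 0
    depth: int = 0
    gene: str | None = None
    nonsynonymous: bool = True
    var_class: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        bad = (set(self.ref) | set(self.alt)) - _VALID_BASES
        if bad:
            raise ValueError(f"non-ACGT characters in alleles: {sorted(bad)}")
        if self.depth and not 0 <= self.alt_reads <= self.depth:
            raise ValueError("alt_reads must be in [0, depth]")
        if self.var_class is None:
            object.__setattr__(self, "var_class", _infer_class(self.ref, self.alt))
        elif self.var_class not in _CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0

    @property
    def is_indel(self) -> bool:
        return self.var_class in ("insertion", "deletion")


def _infer_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass(frozen=True)
class MatchTable:
    """Partition of two call sets into shared and private calls."""

    concordant: tuple[tuple[VariantCall, VariantCall], ...]
    a_private: tuple[VariantCall, ...]
    b_private: tuple[VariantCall, ...]

    @property
    def n_concordant(self) -> int:
        return len(self.concordant)


@dataclass(frozen=True)
class ConcordanceResult:
    """Powered cross-validation outcome for one direction (origin -> other)."""

    n_concordant: int
    n_powered_missed: int
    n_underpowered: int
    n_unassessable: int

    @property
    def n_total(self) -> int:
        return (
            self.n_concordant
            + self.n_powered_missed
            + self.n_underpowered
            + self.n_unassessable
        )

    @property
    def cross_validation_rate(self) -> float | None:
        """Fraction of powered origin calls confirmed at the other center.

        None when no origin call was powered (undefined, not 0).
        """
        denom = self.n_concordant + self.n_powered_missed
        return self.n_concordant / denom if denom else None


def normalize_variant(call: VariantCall, ref_context: str | None = None,
                      context_start: int = 1) -> VariantCall:
    """Canonicalize a variant's representation.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing ``pos``).  If ``ref_context`` — the reference sequence
    starting at 1-based ``context_start`` on the call's chromosome — is
    supplied, indels are then left-aligned by repeatedly shifting the event
    one base left while the flanking base allows it.  Idempotent.
    """
    ref, alt, pos = call.ref, call.alt, call.pos
    # right-trim shared suffix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if ref_context is not None and len(ref) != len(alt):
        pos, ref, alt = _left_align(pos, ref, alt, ref_context, context_start)

    if ref == alt:
        raise ValueError(f"normalization produced ref == alt at {call.chrom}:{pos}")
    return replace(call, pos=pos, ref=ref, alt=alt, var_class=_infer_class(ref, alt))


def _left_align(pos: int, ref: str, alt: str, context: str, context_start: int
                ) -> tuple[int, str, str]:
    """Shift an indel left while the reference permits.

    Standard normalization: while both alleles end in the same base, drop
    it; if an allele empties, prepend the reference base preceding ``pos``
    and move left.  Finally trim any shared leading bases.
    """

    def base_before(p: int) -> str | None:
        i = p - 1 - context_start
        return context[i] if 0 <= i < len(context) else None

    while ref[-1] == alt[-1]:
        prev_state = (pos, ref, alt)
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            prev = base_before(pos)
            if prev is None:
                pos, ref, alt = prev_state
                break
            pos -= 1
            ref, alt = prev + ref, prev + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def match_callsets(
    a: Iterable[VariantCall], b: Iterable[VariantCall]
) -> MatchTable:
    """Exact-key match of two normalized call sets.

    Duplicate keys within one set are deduplicated with a warning and
    counted once, keeping the first occurrence.
    """
    a_map = _dedupe(a, "A")
    b_map = _dedupe(b, "B")
    shared_keys = [k for k in a_map if k in b_map]
    concordant = tuple((a_map[k], b_map[k]) for k in shared_keys)
    a_private = tuple(v for k, v in a_map.items() if k not in b_map)
    b_private = tuple(v for k, v in b_map.items() if k not in a_map)
    return MatchTable(concordant=concordant, a_private=a_private, b_private=b_private)


def _dedupe(calls: Iterable[VariantCall], label: str) -> dict:
    out: dict = {}
    dup = 0
    for c in calls:
        if c.key in out:
            dup += 1
            continue
        out[c.key] = c
    if dup:
        warnings.warn(f"{dup} duplicate variant key(s) in set {label}; counted once")
    return out


def powered_cross_validation(
    origin: Sequence[VariantCall],
    other: Sequence[VariantCall],
    other_coverage: Mapping[tuple[str, int], float] | "object",
    ctx: TumorContext,
    params: PowerParams | None = None,
    nonsynonymous_only: bool = True,
) -> ConcordanceResult:
    """Classify each origin call against the other center's call set.

    Every origin call lands in exactly one class: *concordant* (present in
    the other set), *powered-missed* (absent though the other center's depth
    at the locus gave adequate detection power), *underpowered* (absent,
    inadequate power), or *unassessable* (no depth record for the locus).

    ``other_coverage`` maps (chrom, pos) to depth, or is an object with a
    ``depth_at(chrom, pos)`` method (e.g. a coverage profile).  ``ctx`` is
    the tumor context used to form the expected allele fraction — by
    convention the evaluating center's purity estimate.
    """
    if params is None:
        params = PowerParams()
    if nonsynonymous_only:
        origin = [c for c in origin if c.nonsynonymous]
    other_keys = {c.key for c in other}
    depth_lookup = _depth_fn(other_coverage)

    n_conc = n_pm = n_up = n_na = 0
    for call in origin:
        if call.key in other_keys:
            n_conc += 1
            continue
        depth = depth_lookup(call.chrom, call.pos)
        powered = is_powered(depth, ctx, params)
        if powered == UNASSESSABLE:
            n_na += 1
        elif powered:
            n_pm += 1
        else:
            n_up += 1
    return ConcordanceResult(n_conc, n_pm, n_up, n_na)


def _depth_fn(coverage):
    if hasattr(coverage, "depth_at"):
        return coverage.depth_at
    if isinstance(coverage, Mapping):
        return lambda chrom, pos: coverage.get((chrom, pos))
    raise TypeError("other_coverage must be a mapping or expose depth_at()")


def classify_discordant(
    private_calls: Sequence[VariantCall],
    min_depth: float = 30,
    min_af: float = 0.1,
) -> dict:
    """Break down well-supported private calls by variant class.

    Filters to calls with depth >= ``min_depth`` and allele fraction >=
    ``min_af`` (defaults 30X and 0.1), then counts each variant class.  The
    indel fraction — insertions plus deletions over the filtered total — is
    also reported rounded to the nearest integer percent, the convention
    used when quoting how much of inter-center discordance is indel-driven.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if not 0.0 <= min_af <= 1.0:
        raise ValueError("min_af must be in [0, 1]")
    kept = [
        c
        for c in private_calls
        if c.depth >= min_depth and c.allele_fraction >= min_af
    ]
    counts = Counter(c.var_class for c in kept)
    total = len(kept)
    n_indel = counts.get("insertion", 0) + counts.get("deletion", 0)
    result = {
        "n_filtered": total,
        "counts_by_class": {cls: counts.get(cls, 0) for cls in _CLASSES},
        "n_indel": n_indel,
        "indel_fraction": n_indel / total if total else None,
        "indel_percent": round(100.0 * n_indel / total) if total else None,
        "fractions_by_class": (
            {cls: counts.get(cls, 0) / total for cls in _CLASSES} if total else None
        ),
    }
    return result


def panel_concordance(match: MatchTable, panel: Sequence[str]) -> dict:
    """Agreement summary restricted to a gene panel.

    Considers calls (from either set) whose gene annotation is in ``panel``;
    agreement is the fraction of distinct panel variants that both centers
    called.  Panel genes never seen get zero-count rows; with no panel calls
    at all the agreement is vacuously 1.0 and flagged ``n=0``.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    panel_set = set(panel)
    per_gene = {g: {"concordant": 0, "a_private": 0, "b_private": 0} for g in panel_set}

    def bump(gene: str | None, slot: str) -> None:
        if gene in panel_set:
            per_gene[gene][slot] += 1

    for pair in match.concordant:
        bump(pair[0].gene, "concordant")
    for c in match.a_private:
        bump(c.gene, "a_private")
    for c in match.b_private:
        bump(c.gene, "b_private")

    n_conc = sum(v["concordant"] for v in per_gene.values())
    n_priv = sum(v["a_private"] + v["b_private"] for v in per_gene.values())
    n_total = n_conc + n_priv
    return {
        "per_gene": per_gene,
        "n_panel_calls": n_total,
        "agreement": n_conc / n_total if n_total else 1.0,
        "vacuous": n_total == 0,
    }
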