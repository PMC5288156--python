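"""Somatic variant detection power model.

Detection power at a locus is the probability that a caller operating a
log-odds (LOD) threshold would emit a call, given the sequencing depth and
the allele fraction expected for a true variant at that site.  The model is
the standard binomial one used by tumor-only LOD callers: reads supporting
the variant arise Binomial(n, p) where p folds the allele fraction together
with the per-base sequencing error rate, and a site is called when the
number of supporting reads reaches the smallest count whose likelihood-ratio
against the error-only model clears the LOD threshold.

Cross-center comparison of call sets uses this to restrict attention to
adequately powered loci: a call private to one center is only evidence of
discordance if the other center's depth gave it a realistic chance of being
detected there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "PowerParams",
    "TumorContext",
    "effective_allele_fraction",
    "min_alt_reads_to_call",
    "detection_power",
    "is_powered",
    "UNASSESSABLE",
]

#: Sentinel returned by :func:`is_powered` when no depth is known for a site.
UNASSESSABLE = "unassessable"


@dataclass(frozen=True)
class PowerParams:
    """Parameters of the LOD detection model.

    Attributes
    ----------
    error_rate:
        Per-base probability of a sequencing error producing any specific
        wrong base call (``e``).  A mismatch supports the variant allele
        with probability ``e/3``.
    lod_threshold:
        log10 likelihood-ratio cutoff a candidate must reach to be called.
    min_alt_reads:
        Hard floor on the number of variant-supporting reads.
    power_cutoff:
        Probability above which a locus counts as adequately powered.
    interpolate:
        Give fractional credit to the count just below the minimum callable
        one, proportional to how close its LOD comes to the threshold.
        Without it power is a sawtooth in depth (each jump of the minimum
        callable count drops the tail); the credit keeps power effectively
        monotone in depth.  Disable for the plain tail probability.
    """

    error_rate: float = 1e-3
    lod_threshold: float = 6.3
    min_alt_reads: int = 3
    power_cutoff: float = 0.8
    interpolate: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in (0, 0.5), got {self.error_rate}")
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be positive")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if not 0.0 < self.power_cutoff < 1.0:
            raise ValueError("power_cutoff must be in (0, 1)")


@dataclass(frozen=True)
class TumorContext:
    """Sample context that sets the expected allele fraction of a true call.

    ``purity`` is the fraction of tumor cells in the sample; ``copy_number``
    the local total copy number in tumor cells; ``multiplicity`` the number
    of those copies carrying the mutation.  Defaults describe a clonal
    heterozygous mutation in a diploid region.
    """

    purity: float
    copy_number: int = 2
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if not 1 <= self.multiplicity <= self.copy_number:
            raise ValueError(
                f"multiplicity must be in [1, copy_number={self.copy_number}], "
                f"got {self.multiplicity}"
            )


def effective_allele_fraction(ctx: TumorContext) -> float:
    """Expected allele fraction of a clonal mutation in an impure sample.

    With purity ``a``, local tumor copy number ``C`` and mutation
    multiplicity ``m``, reads sampling the locus see ``a*m`` mutant copies
    out of ``2*(1-a) + a*C`` total copies:

        f = a*m / (2*(1-a) + a*C)
    """
    a, c, m = ctx.purity, ctx.copy_number, ctx.multiplicity
    return (a * m) / (2.0 * (1.0 - a) + a * c)


def _p_of(f: float, e: float) -> float:
    """Read-level success probability for allele fraction ``f``."""
    return f * (1.0 - e) + (1.0 - f) * e / 3.0


@lru_cache(maxsize=65536)
def _min_alt_reads_cached(n: int, params: PowerParams) -> int:
    e = params.error_rate
    log10e = math.log(10.0)
    p0 = _p_of(0.0, e)
    for k in range(params.min_alt_reads, n + 1):
        p1 = _p_of(k / n, e)
        lod = (stats.binom.logpmf(k, n, p1) - stats.binom.logpmf(k, n, p0)) / log10e
        if lod >= params.lod_threshold:
            return k
    return n + 1


def min_alt_reads_to_call(n: int, params: PowerParams | None = None) -> int:
    """Smallest alt-read count at depth ``n`` that clears the LOD threshold.

    For candidate count ``k`` the variant hypothesis sets the allele
    fraction to its MLE ``k/n``; the null is error only (f = 0).  Returns
    the smallest ``k >= min_alt_reads`` with

        LOD(k, n) = log10[ Binom(k; n, p(k/n)) / Binom(k; n, p(0)) ]
                  >= lod_threshold,

    or ``n + 1`` if no count at this depth suffices.
    """
    if params is None:
        params = PowerParams()
    if n < 0:
        raise ValueError("depth must be non-negative")
    return _min_alt_reads_cached(int(n), params)


def _lod(k: int, n: int, e: float) -> float:
    p1 = _p_of(k / n, e)
    p0 = _p_of(0.0, e)
    return (stats.binom.logpmf(k, n, p1) - stats.binom.logpmf(k, n, p0)) / math.log(10.0)


def detection_power(n: int, f: float, params: PowerParams | None = None) -> float:
    """Probability of detecting a variant of allele fraction ``f`` at depth ``n``.

    The number of supporting reads is Binomial(n, p(f)) with
    ``p(f) = f*(1-e) + (1-f)*e/3``; power is the tail probability at or
    above the minimum callable count k* from :func:`min_alt_reads_to_call`,
    plus — when ``params.interpolate`` — the fraction of P(K = k* - 1)
    corresponding to how far LOD(k* - 1) reaches toward the threshold:

        power = P(K >= k*) + d * P(K = k* - 1),
        d = 1 - (theta - LOD(k*-1)) / (LOD(k*) - LOD(k*-1)).
    """
    if params is None:
        params = PowerParams()
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele fraction must be in [0, 1], got {f}")
    if n < 0:
        raise ValueError("depth must be non-negative")
    k_star = min_alt_reads_to_call(n, params)
    if k_star > n:
        return 0.0
    p = _p_of(f, params.error_rate)
    power = float(stats.binom.sf(k_star - 1, n, p))
    if params.interpolate and k_star > params.min_alt_reads:
        lod_hi = _lod(k_star, n, params.error_rate)
        lod_lo = _lod(k_star - 1, n, params.error_rate)
        if lod_hi > lod_lo:
            d = 1.0 - (params.lod_threshold - lod_lo) / (lod_hi - lod_lo)
            d = min(max(d, 0.0), 1.0)
            power += d * float(stats.binom.pmf(k_star - 1, n, p))
    return min(power, 1.0)


def is_powered(
    depth_at_site: int | float | None,
    ctx: TumorContext,
    params: PowerParams | None = None,
) -> bool | str:
    """Whether a site is adequately powered for detection.

    Returns True/False, or the :data:`UNASSESSABLE` sentinel when no depth
    record exists for the site — missing coverage must never silently count
    as underpowered.
    """
    if params is None:
        params = PowerParams()
    if depth_at_site is None or (
        isinstance(depth_at_site, float) and np.isnan(depth_at_site)
    ):
        return UNASSESSABLE
    f = effective_allele_fraction(ctx)
    return bool(detection_power(int(depth_at_site), f, params) >= params.power_cutoff)
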