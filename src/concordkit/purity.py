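"""Tumor purity estimation from somatic allele fractions.

A sample of tumor tissue is an admixture of neoplastic and benign cells.
A clonal heterozygous somatic SNV in a copy-neutral (diploid) region is
carried by one of two chromosomes in every tumor cell and by none in normal
cells, so its expected allele fraction is ``alpha / 2`` where ``alpha`` is
the tumor cell content (purity).  Observed alt-read counts at such sites are
modelled as a J-component binomial mixture over allele-fraction cluster
centers; the largest center corresponds to the clonal copy-neutral cluster
and the purity estimate is ``alpha_hat = min(1, 2 * max_j mu_j)``.  Smaller
components absorb subclonal mutations.

The mixture is fitted by expectation-maximization with deterministic
quantile-based initialization; the number of components can be fixed or
selected by BIC over {1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = ["AFObservation", "PurityEstimate", "InsufficientSitesError", "estimate_purity"]


class InsufficientSitesError(ValueError):
    """Raised when too few usable allele-fraction observations remain."""


@dataclass(frozen=True)
class AFObservation:
    """One somatic site's alt-read count and depth.

    ``copy_neutral`` marks sites believed diploid in the tumor; only those
    enter the fit, since the alpha/2 relation assumes two tumor copies.
    """

    alt_reads: int
    depth: int
    chrom: str = ""
    pos: int = 0
    copy_neutral: bool = True

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("alt_reads must be in [0, depth]")


@dataclass
class PurityEstimate:
    """Result of the mixture fit."""

    alpha: float
    component_means: list[float]
    component_weights: list[float]
    log_likelihood: float
    n_used: int
    n_components: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_components == 0:
            self.n_components = len(self.component_means)


def _em_binomial_mixture(
    alt: np.ndarray,
    depth: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    mean_cap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a binomial mixture with component means constrained to (0, cap].

    Initialization is deterministic: raw allele fractions are sorted and cut
    into ``n_components`` equal-count blocks whose means seed the components
    (a 1-D k-means-style seeding that needs no random restarts).  Returns
    (means, weights, log_likelihood); the log-likelihood is non-decreasing
    across iterations by EM's ascent property, asserted per iteration.
    """
    n = alt.size
    raw_af = alt / depth
    order = np.argsort(raw_af)
    blocks = np.array_split(raw_af[order], n_components)
    mu = np.array([max(b.mean(), 1e-4) if b.size else 1e-4 for b in blocks])
    mu = np.clip(mu, 1e-4, mean_cap)
    w = np.full(n_components, 1.0 / n_components)

    prev_ll = -np.inf
    ll = prev_ll
    for _ in range(max_iter):
        # E-step: log responsibilities
        logp = stats.binom.logpmf(alt[:, None], depth[:, None], mu[None, :])
        logp = logp + np.log(w)[None, :]
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        assert ll >= prev_ll - 1e-6, "EM log-likelihood decreased"
        if ll - prev_ll < tol:
            break
        prev_ll = ll
        resp = np.exp(logp - norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        w = nk / n
        mu = (resp * alt[:, None]).sum(axis=0) / np.maximum(
            (resp * depth[:, None]).sum(axis=0), 1e-300
        )
        mu = np.clip(mu, 1e-6, mean_cap)
    return mu, w, ll


def estimate_purity(
    observations: list[AFObservation],
    n_components: int | None = None,
    seed: int | None = None,
    min_sites: int = 25,
    max_components: int = 3,
    min_component_weight: float = 0.15,
) -> PurityEstimate:
    """Estimate tumor purity from copy-neutral somatic allele fractions.

    Parameters
    ----------
    observations:
        Somatic sites with alt/depth counts; only ``copy_neutral`` sites are
        used.
    n_components:
        Fixed component count J; if None (default) J is chosen by BIC over
        ``1..max_components``.
    seed:
        Accepted for interface stability; the fit is deterministic (quantile
        initialization) so the seed does not alter the result.
    min_sites:
        Minimum usable sites; fewer raises :class:`InsufficientSitesError`.
    min_component_weight:
        Components lighter than this cannot set the purity: the clonal
        copy-neutral cluster is by construction a substantial share of the
        sites, whereas near-empty high-AF components are tail absorbers
        that would bias ``2 * max(mean)`` upward.

    Returns
    -------
    PurityEstimate with ``alpha = min(1, 2 * max substantial component mean)``.
    """
    used = [o for o in observations if o.copy_neutral]
    if len(used) < min_sites:
        raise InsufficientSitesError(
            f"need >= {min_sites} copy-neutral sites, have {len(used)}"
        )
    alt = np.array([o.alt_reads for o in used], dtype=float)
    depth = np.array([o.depth for o in used], dtype=float)
    if alt.sum() == 0:
        raise ValueError("all observations have zero alt reads")

    if n_components is not None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        candidates = [n_components]
    else:
        candidates = list(range(1, max_components + 1))

    best: tuple[float, PurityEstimate] | None = None
    n = alt.size
    for j in candidates:
        mu, w, ll = _em_binomial_mixture(alt, depth, j)
        # free parameters: j means + (j-1) weights
        bic = (2 * j - 1) * np.log(n) - 2.0 * ll
        substantial = mu[w >= min_component_weight]
        mu_top = substantial.max() if substantial.size else mu.max()
        est = PurityEstimate(
            alpha=float(min(1.0, 2.0 * mu_top)),
            component_means=[float(m) for m in mu],
            component_weights=[float(x) for x in w],
            log_likelihood=ll,
            n_used=n,
            n_components=j,
        )
        if best is None or bic < best[0]:
            best = (bic, est)
    assert best is not None
    return best[1]
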