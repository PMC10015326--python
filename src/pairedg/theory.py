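"""Closed-form single-locus expectations for additive genetic variance under inbreeding.

For a biallelic locus with genotypic values (-a, d, +a), the additive genetic
variance after one generation of inbreeding at coefficient ``F`` decomposes into
three terms:

    term1 = 2pq(1+F) a^2
    term2 = 4pq ad (q-p) (1-F)
    term3 = 2pq d^2 (q-p)^2 (1-F)^2 / (1+F)

where ``p = 1 - q``.  At ``F = 0`` the total collapses to the textbook outbred
identity ``2pq (a + d(q-p))^2``.  The factor ``(1-F)^2 / (1+F)`` scales the pure
dominance contribution and is smaller than the ``1+F`` inflation of the additive
term, so loci with dominant gene action and unequal allele frequencies deflate
the variance ratio below ``1+F`` under inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LocusParams",
    "VaBreakdown",
    "HomozygoteEnrichment",
    "va_under_inbreeding",
    "deflation_factor",
    "homozygote_enrichment",
    "va_ratio_surface",
]


class DomainError(ValueError):
    """A parameter lies outside its mathematical domain."""


@dataclass(frozen=True)
class LocusParams:
    """Parameters of a single biallelic locus.

    ``q`` is the frequency of the allele whose homozygote has value ``+a``;
    ``p = 1 - q`` is never stored independently.  ``d`` is the heterozygote
    (dominance) value and ``F`` the inbreeding coefficient of the offspring
    generation.
    """

    q: float
    a: float
    d: float
    F: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise DomainError(f"allele frequency q={self.q} outside [0, 1]")
        if not 0.0 <= self.F <= 1.0:
            raise DomainError(f"inbreeding coefficient F={self.F} outside [0, 1]")

    @property
    def p(self) -> float:
        return 1.0 - self.q


@dataclass(frozen=True)
class VaBreakdown:
    """Per-term decomposition of the single-locus additive variance."""

    term1: float
    term2: float
    term3: float

    @property
    def total(self) -> float:
        return self.term1 + self.term2 + self.term3


def va_under_inbreeding(locus: LocusParams) -> VaBreakdown:
    """Additive genetic variance at a locus after one generation of inbreeding.

    Returns the three-term breakdown; ``total`` is their sum.  ``term1`` and
    ``term3`` are non-negative for all valid inputs; only ``term2`` (the
    additive-by-dominance interaction) can change sign.
    """
    q, a, d, F = locus.q, locus.a, locus.d, locus.F
    p = locus.p
    pq = p * q
    term1 = 2.0 * pq * (1.0 + F) * a * a
    term2 = 4.0 * pq * a * d * (q - p) * (1.0 - F)
    term3 = 2.0 * pq * d * d * (q - p) ** 2 * deflation_factor(F)
    return VaBreakdown(term1, term2, term3)


def deflation_factor(F: float) -> float:
    """The factor ``(1-F)^2 / (1+F)`` scaling the dominance variance term.

    Equals 1 at F=0, 0.45 at F=0.25 and tends to 0 as F -> 1.
    """
    if not 0.0 <= F <= 1.0:
        raise DomainError(f"inbreeding coefficient F={F} outside [0, 1]")
    return (1.0 - F) ** 2 / (1.0 + F)


@dataclass(frozen=True)
class HomozygoteEnrichment:
    freq_inbred: float
    freq_outbred: float
    ratio: float


def homozygote_enrichment(q: float, F: float) -> HomozygoteEnrichment:
    """Homozygote frequency for an allele at frequency ``q`` with and without inbreeding.

    Under Hardy-Weinberg with inbreeding coefficient ``F`` the homozygote
    frequency is ``q^2 + F q(1-q)``; the fold-enrichment relative to random
    mating (``q^2``) is ``1 + F(1-q)/q``, which exceeds 25 for any ``q < 0.01``
    at ``F = 0.25``.
    """
    if not 0.0 <= q <= 1.0:
        raise DomainError(f"allele frequency q={q} outside [0, 1]")
    if not 0.0 <= F <= 1.0:
        raise DomainError(f"inbreeding coefficient F={F} outside [0, 1]")
    freq_outbred = q * q
    freq_inbred = q * q + F * q * (1.0 - q)
    if q == 0.0:
        raise DomainError("homozygote enrichment ratio is undefined at q=0")
    ratio = freq_inbred / freq_outbred
    return HomozygoteEnrichment(freq_inbred, freq_outbred, ratio)


def va_ratio_surface(
    q_grid: np.ndarray,
    d_grid: np.ndarray,
    a: float,
    F: float = 0.25,
) -> pd.DataFrame:
    """Ratio of inbred to outbred additive variance over a (q, d) grid.

    Uses only the purely-additive and purely-dominant terms (term1 + term3),
    i.e. the two-term surface convention under which the additive-by-dominance
    interaction (which sums to zero across loci when ``E[d] = 0``) is dropped:

        ratio = [ (1+F) a^2 + d^2 (q-p)^2 (1-F)^2/(1+F) ] / [ a^2 + d^2 (q-p)^2 ]

    (the common factor ``2pq`` cancels).  Cells at the boundary ``q in {0, 1}``
    are reported as NaN with ``boundary=True``: both numerator and denominator
    vanish there, and the 0/0 limit is left undefined rather than silently
    filled.  Cells with ``d = 0`` equal ``1+F`` exactly.

    Returns a long-format frame with columns ``q``, ``d``, ``ratio``,
    ``boundary``.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if q_grid.size == 0 or d_grid.size == 0:
        raise DomainError("empty grid")
    if a <= 0:
        raise DomainError("additive effect a must be positive")
    if np.any((q_grid < 0) | (q_grid > 1)):
        raise DomainError("q grid outside [0, 1]")
    if not 0.0 <= F <= 1.0:
        raise DomainError(f"inbreeding coefficient F={F} outside [0, 1]")

    rows = []
    for q in q_grid:
        p = 1.0 - q
        for d in d_grid:
            boundary = q in (0.0, 1.0)
            if boundary:
                ratio = np.nan
            elif d == 0.0:
                ratio = 1.0 + F
            else:
                dom = d * d * (q - p) ** 2
                num = (1.0 + F) * a * a + dom * deflation_factor(F)
                den = a * a + dom
                ratio = num / den
            rows.append((q, d, ratio, boundary))
    return pd.DataFrame(rows, columns=["q", "d", "ratio", "boundary"])
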