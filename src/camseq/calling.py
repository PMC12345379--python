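"""Background estimation from rarely methylated motifs and m6A site calling.

The background non-conversion rate p0 is pooled over A sites whose central
3-mer context belongs to motifs nearly devoid of m6A (UAG/UAA/CAG/CAA).
Each covered A site is then tested one-sided against Binomial(N, p0); the
modification level is the raw unconverted fraction n_A / N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .align import SiteCount

RARE_MOTIFS = frozenset({"UAG", "UAA", "CAG", "CAA"})


class BackgroundEstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BackgroundModel:
    """Pooled background unconverted fraction from rare-motif A sites."""

    p0: float
    n_sites_used: int
    motifs_used: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly inside (0, 1)")
        if self.n_sites_used <= 0:
            raise ValueError("background requires at least one site")


@dataclass
class SiteCall(SiteCount):
    level: float = 0.0
    p_value: float = 1.0
    significant: bool = False
    passes_level_5: bool = False
    passes_level_10: bool = False


def estimate_background(
    site_counts: Iterable[SiteCount],
    rare_motifs: frozenset[str] = RARE_MOTIFS,
) -> BackgroundModel:
    """Pool n_A / N over rare-motif sites; floor at 1/(N_total+1) when zero.

    Raises :class:`BackgroundEstimationError` when no site matches, with
    the instruction to supply p0 manually.
    """
    total_a = 0
    total_n = 0
    used = 0
    for site in site_counts:
        if site.central_motif(3) in rare_motifs:
            total_a += site.n_A
            total_n += site.coverage
            used += 1
    if used == 0 or total_n == 0:
        raise BackgroundEstimationError(
            "no rare-motif sites available to estimate the background; "
            "supply p0 manually"
        )
    p0 = total_a / total_n if total_a > 0 else 1.0 / (total_n + 1)
    return BackgroundModel(
        p0=p0, n_sites_used=used, motifs_used=frozenset(rare_motifs)
    )


def binomial_pvalue(n_A: int, N: int, p0: float) -> float:
    """One-sided upper-tail P(X >= n_A) under Binomial(N, p0)."""
    if not 0 <= n_A <= N:
        raise ValueError(f"invalid counts n_A={n_A}, N={N}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} outside (0, 1)")
    if n_A == 0:
        return 1.0
    return float(stats.binom.sf(n_A - 1, N, p0))


def call_sites(
    site_counts: Sequence[SiteCount],
    background: BackgroundModel,
    alpha: float = 0.001,
    min_coverage: int = 20,
    adjust_efficiency: bool = False,
) -> list[SiteCall]:
    """Assign level, p-value and pass/fail flags to every retained site.

    Sites with coverage N > ``min_coverage`` (strict) are kept; the raw
    p-value is compared directly to ``alpha`` with no multiple-testing
    correction, reproducing a fixed P < 0.001 filter. When
    ``adjust_efficiency`` is set, levels are rescaled by
    (level - p0) / (1 - p0) and clipped to [0, 1].
    """
    p0 = background.p0
    calls: list[SiteCall] = []
    for site in site_counts:
        n = site.coverage
        if n <= min_coverage:
            continue
        level = site.n_A / n
        if adjust_efficiency:
            level = min(1.0, max(0.0, (level - p0) / (1.0 - p0)))
        p = binomial_pvalue(site.n_A, n, p0)
        calls.append(
            SiteCall(
                reference_id=site.reference_id,
                position=site.position,
                strand=site.strand,
                context=site.context,
                n_A=site.n_A,
                n_G=site.n_G,
                n_other=site.n_other,
                level=level,
                p_value=p,
                significant=p < alpha,
                passes_level_5=level > 0.05,
                passes_level_10=level > 0.10,
            )
        )
    calls.sort(key=lambda c: (c.reference_id, c.position))
    return calls


def manual_background(p0: float) -> BackgroundModel:
    """Wrap an externally supplied background rate."""
    return BackgroundModel(p0=p0, n_sites_used=1, motifs_used=frozenset())
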