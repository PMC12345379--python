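"""Transcript-anatomy placement of sites, metagene profiles, variance
decomposition and gene-level summaries.

Distances are measured in transcript coordinates with the first base of
the stop codon at 0; the deposition hotspot is the closed interval
[-20, +180] around it. Gene-level grouping splits methylated genes by
whether their maximum site level reaches 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SiteCall
from .simulate import TranscriptModel

HOTSPOT = (-20, 180)


@dataclass
class RegionAnnotatedSite:
    call: SiteCall
    gene_id: str
    distance_to_stop: int
    in_hotspot: bool
    metagene_coordinate: float  # [0,1) 5'UTR, [1,2) CDS, [2,3) 3'UTR


@dataclass(frozen=True)
class VarianceReport:
    motif: str
    grouping: str
    F: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float


@dataclass
class GeneSummary:
    gene_id: str
    n_sites: int
    average_level: float
    max_level: float
    group: str  # none | group1 | group2
    expression: float  # log10 coverage per transcript kb


def annotate_sites(
    calls: Sequence[SiteCall],
    transcripts: dict[str, TranscriptModel],
    hotspot: tuple[int, int] = HOTSPOT,
) -> tuple[list[RegionAnnotatedSite], int]:
    """Place each call on its transcript's anatomy.

    Calls on references absent from the annotation are dropped with a
    warning; the count of dropped calls is returned alongside the result.
    """
    annotated: list[RegionAnnotatedSite] = []
    dropped = 0
    for call in calls:
        tx = transcripts.get(call.reference_id)
        if tx is None:
            dropped += 1
            continue
        d = tx.distance_to_stop(call.position)
        annotated.append(
            RegionAnnotatedSite(
                call=call,
                gene_id=tx.id,
                distance_to_stop=d,
                in_hotspot=hotspot[0] <= d <= hotspot[1],
                metagene_coordinate=_metagene_coordinate(tx, call.position),
            )
        )
    if dropped:
        warnings.warn(f"dropped {dropped} calls on unannotated references")
    return annotated, dropped


def _metagene_coordinate(tx: TranscriptModel, pos: int) -> float:
    """Scale a transcript position onto the 5'UTR|CDS|3'UTR axis [0, 3)."""
    n = len(tx.sequence)
    utr5, cds_end = tx.cds_start, tx.cds_end
    if pos < utr5:
        return pos / utr5 if utr5 > 0 else 0.0
    if pos < cds_end:
        span = cds_end - utr5
        return 1.0 + (pos - utr5) / span if span > 0 else 1.0
    span = n - cds_end
    return 2.0 + min((pos - cds_end) / span if span > 0 else 0.0, 0.999999)


def metagene_profile(
    annotated: Sequence[RegionAnnotatedSite], n_bins: int = 30
) -> pd.DataFrame:
    """Methylation mass (level x coverage) density along the metagene axis.

    ``n_bins`` bins per segment; densities sum to 1 over the 3*n_bins bins.
    """
    edges = np.linspace(0.0, 3.0, 3 * n_bins + 1)
    coords = np.array([s.metagene_coordinate for s in annotated])
    mass = np.array([s.call.level * s.call.coverage for s in annotated])
    if coords.size == 0 or mass.sum() == 0:
        warnings.warn("no methylation mass; metagene profile is all zero")
        hist = np.zeros(3 * n_bins)
    else:
        hist, _ = np.histogram(coords, bins=edges, weights=mass)
        hist = hist / hist.sum()
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "segment": ["5UTR"] * n_bins + ["CDS"] * n_bins + ["3UTR"] * n_bins,
            "density": hist,
        }
    )


def variance_F(
    groups: Sequence[Sequence[float]],
    motif: str = "",
    grouping: str = "region",
) -> VarianceReport:
    """One-way ANOVA from explicit between/within sums of squares.

    F is the between-group mean square over the within-group mean square;
    the p-value comes from the F distribution. Zero within-group variance
    with nonzero between-group variance reports F=+inf, p=0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least two non-empty groups")
    n = sum(len(g) for g in groups)
    if n <= k:
        raise ValueError("total observations must exceed group count")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = float("inf"), 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f, dfb, dfw))
    return VarianceReport(
        motif=motif, grouping=grouping, F=float(f), p_value=p,
        df_between=dfb, df_within=dfw,
        ss_between=float(ssb), ss_within=float(ssw),
    )


def regional_variance_by_motif(
    annotated: Sequence[RegionAnnotatedSite],
    min_sites: int = 5,
) -> pd.DataFrame:
    """Per-motif ANOVA of site levels: inside vs outside the hotspot."""
    by_motif: dict[str, tuple[list[float], list[float]]] = {}
    for s in annotated:
        motif = s.call.central_motif(3)
        inside, outside = by_motif.setdefault(motif, ([], []))
        (inside if s.in_hotspot else outside).append(s.call.level)
    rows = []
    for motif, (inside, outside) in sorted(by_motif.items()):
        if len(inside) < min_sites or len(outside) < min_sites:
            continue
        rep = variance_F([inside, outside], motif=motif, grouping="region")
        rows.append(
            {
                "motif": motif, "grouping": "region", "F": rep.F,
                "p_value": rep.p_value, "df_between": rep.df_between,
                "df_within": rep.df_within,
                "n_in_hotspot": len(inside), "n_outside": len(outside),
            }
        )
    return pd.DataFrame(rows)


def gene_variance_by_motif(
    annotated: Sequence[RegionAnnotatedSite],
    min_sites_per_gene: int = 2,
    min_genes: int = 3,
    hotspot_only: bool = True,
) -> pd.DataFrame:
    """Per-motif ANOVA of levels between genes vs within genes.

    Restricted to hotspot sites by default, since regions outside it are
    minimally modified and would confound the gene effect.
    """
    by_motif: dict[str, dict[str, list[float]]] = {}
    for s in annotated:
        if hotspot_only and not s.in_hotspot:
            continue
        motif = s.call.central_motif(3)
        by_motif.setdefault(motif, {}).setdefault(s.gene_id, []).append(
            s.call.level
        )
    rows = []
    for motif, genes in sorted(by_motif.items()):
        groups = [v for v in genes.values() if len(v) >= min_sites_per_gene]
        if len(groups) < min_genes:
            continue
        rep = variance_F(groups, motif=motif, grouping="gene")
        rows.append(
            {
                "motif": motif, "grouping": "gene", "F": rep.F,
                "p_value": rep.p_value, "df_between": rep.df_between,
                "df_within": rep.df_within, "n_genes": len(groups),
            }
        )
    return pd.DataFrame(rows)


def gene_summaries(
    annotated: Sequence[RegionAnnotatedSite],
    transcripts: dict[str, TranscriptModel],
    all_sites: bool = False,
    group2_threshold: float = 0.5,
) -> list[GeneSummary]:
    """Per-gene methylation and expression summary.

    ``average_level`` is the coverage-weighted mean over the gene's
    significant sites (all covered sites when ``all_sites``); ``max_level``
    the maximum significant-site level. Expression is log10 of summed A-site
    coverage per transcript kilobase — a length-normalised proxy from the
    same library. A boundary max_level equal to the threshold is assigned
    to group2 ("above" read inclusively).
    """
    by_gene: dict[str, list[RegionAnnotatedSite]] = {}
    for s in annotated:
        by_gene.setdefault(s.gene_id, []).append(s)
    out: list[GeneSummary] = []
    for gene_id, sites in sorted(by_gene.items()):
        tx = transcripts[gene_id]
        sig = [s for s in sites if s.call.significant]
        pool = sites if all_sites else sig
        cov = sum(s.call.coverage for s in pool)
        avg = (
            sum(s.call.level * s.call.coverage for s in pool) / cov
            if cov else 0.0
        )
        max_level = max((s.call.level for s in sig), default=0.0)
        if not sig:
            group = "none"
        elif max_level >= group2_threshold:
            group = "group2"
        else:
            group = "group1"
        total_cov = sum(s.call.coverage for s in sites)
        kb = len(tx.sequence) / 1000.0
        expression = float(np.log10(total_cov / kb)) if total_cov else float("nan")
        out.append(
            GeneSummary(
                gene_id=gene_id, n_sites=len(sig),
                average_level=avg, max_level=max_level,
                group=group, expression=expression,
            )
        )
    return out


def expression_methylation_association(
    summaries: Sequence[GeneSummary],
) -> pd.DataFrame:
    """Correlations of expression vs average level, overall and per group.

    Pearson and Spearman for all methylated genes, group1 and group2;
    plus Mann-Whitney rank-sum comparisons of expression between groups
    (none vs group1 vs group2). Constant vectors give NaN with a warning.
    """
    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "average_level": [s.average_level for s in summaries],
            "expression": [s.expression for s in summaries],
            "group": [s.group for s in summaries],
        }
    ).dropna(subset=["expression"])

    rows = []
    subsets = {
        "all_methylated": df[df["group"] != "none"],
        "group1": df[df["group"] == "group1"],
        "group2": df[df["group"] == "group2"],
    }
    for name, sub in subsets.items():
        rows.append(_correlation_row(name, sub))
    for a, b in (("none", "group1"), ("group1", "group2"), ("none", "group2")):
        xa = df.loc[df["group"] == a, "expression"]
        xb = df.loc[df["group"] == b, "expression"]
        if len(xa) >= 1 and len(xb) >= 1:
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append(
                {
                    "subset": f"{a}_vs_{b}", "statistic": "rank_sum_U",
                    "n": len(xa) + len(xb), "value": float(u),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def _correlation_row(name: str, sub: pd.DataFrame) -> dict:
    n = len(sub)
    if n < 3:
        return {
            "subset": name, "statistic": "pearson", "n": n,
            "value": float("nan"), "p_value": float("nan"),
        }
    x = sub["expression"].to_numpy()
    y = sub["average_level"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(f"constant vector in subset {name}; correlation NaN")
        return {
            "subset": name, "statistic": "pearson", "n": n,
            "value": float("nan"), "p_value": float("nan"),
        }
    r, pr = stats.pearsonr(x, y)
    rho, ps = stats.spearmanr(x, y)
    return {
        "subset": name, "statistic": "pearson_spearman", "n": n,
        "value": float(r), "p_value": float(pr),
        "spearman": float(rho), "spearman_p": float(ps),
    }
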