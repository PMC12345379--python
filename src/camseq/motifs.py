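"""Sequence-context aggregation: motif tables, signal-to-noise, composition,
overall methylation level and entropy-based positional importance.

All motifs are reported in RNA letters (U, not T) and are centered on the
modified A. The importance score at a flanking position measures, in bits,
how unevenly the methylation signal distributes over the four possible
bases there: 0 when the base identity carries no information, 2 when a
single base carries all of it.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .align import SiteCount
from .calling import SiteCall

BASES = ("A", "C", "G", "U")


def _level(site: Union[SiteCount, SiteCall]) -> float:
    if isinstance(site, SiteCall):
        return site.level
    n = site.coverage
    return site.n_A / n if n else 0.0


def _is_called(site: Union[SiteCount, SiteCall]) -> bool:
    return isinstance(site, SiteCall) and site.significant


def motif_table(
    sites: Sequence[Union[SiteCount, SiteCall]],
    motif_length: int = 3,
    min_sites_filter: int = 10,
) -> pd.DataFrame:
    """Per-motif aggregate over all supplied A sites.

    Columns: ``n_A_sites_total`` (all covered A sites in the motif),
    ``n_sites_called`` (significant ones), ``relative_frequency`` (share of
    called sites), ``mean_level`` and ``weighted_level`` over called sites,
    ``mean_level_all`` over every site, and ``passes_filter``.
    """
    if motif_length not in (3, 5):
        raise ValueError("motif_length must be 3 or 5")
    rows: dict[str, dict] = {}
    for site in sites:
        motif = site.central_motif(motif_length)
        if len(motif) < motif_length or "N" in motif:
            if len(site.context) < motif_length:
                raise ValueError("context shorter than motif")
            continue
        r = rows.setdefault(
            motif,
            {
                "n_A_sites_total": 0,
                "n_sites_called": 0,
                "level_sum_called": 0.0,
                "mass_called": 0.0,
                "cov_called": 0,
                "level_sum_all": 0.0,
            },
        )
        lv = _level(site)
        r["n_A_sites_total"] += 1
        r["level_sum_all"] += lv
        if _is_called(site):
            r["n_sites_called"] += 1
            r["level_sum_called"] += lv
            r["mass_called"] += lv * site.coverage
            r["cov_called"] += site.coverage
    if not rows:
        return pd.DataFrame(
            columns=[
                "n_A_sites_total", "n_sites_called", "relative_frequency",
                "mean_level", "weighted_level", "mean_level_all",
                "passes_filter",
            ]
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    total_called = df["n_sites_called"].sum()
    df["relative_frequency"] = (
        df["n_sites_called"] / total_called if total_called else 0.0
    )
    with np.errstate(invalid="ignore"):
        df["mean_level"] = np.where(
            df["n_sites_called"] > 0,
            df["level_sum_called"] / df["n_sites_called"].clip(lower=1),
            np.nan,
        )
        df["weighted_level"] = np.where(
            df["cov_called"] > 0,
            df["mass_called"] / df["cov_called"].clip(lower=1),
            np.nan,
        )
    df["mean_level_all"] = df["level_sum_all"] / df["n_A_sites_total"]
    df["passes_filter"] = df["n_sites_called"] >= min_sites_filter
    df = df.drop(
        columns=["level_sum_called", "mass_called", "cov_called", "level_sum_all"]
    )
    df.index.name = "motif"
    return df.sort_index()


def snr_uag_gac(
    sites: Sequence[Union[SiteCount, SiteCall]],
    method: str = "mass",
) -> float:
    """UAG/GAC ratio, an upper bound on the false-positive rate.

    ``mass`` (default): ratio of level*coverage mass summed over all A
    sites in each motif. ``count``: ratio of significant-site counts.
    """
    if method == "mass":
        uag = sum(
            _level(s) * s.coverage for s in sites if s.central_motif(3) == "UAG"
        )
        gac = sum(
            _level(s) * s.coverage for s in sites if s.central_motif(3) == "GAC"
        )
    elif method == "count":
        uag = sum(
            1 for s in sites if _is_called(s) and s.central_motif(3) == "UAG"
        )
        gac = sum(
            1 for s in sites if _is_called(s) and s.central_motif(3) == "GAC"
        )
    else:
        raise ValueError("method must be 'mass' or 'count'")
    if gac == 0:
        warnings.warn("zero GAC methylation mass; UAG/GAC ratio undefined")
        return float("nan")
    return uag / gac


def weighted_motif_composition(
    calls: Sequence[SiteCall], target_motif: str
) -> float:
    """Coverage-weighted share of methylation mass on ``target_motif``.

    Sum of (level x coverage) over significant sites in the target motif
    divided by the same sum over all significant sites.
    """
    target_motif = target_motif.upper().replace("T", "U")
    total = 0.0
    target = 0.0
    k = len(target_motif)
    for c in calls:
        if not c.significant:
            continue
        mass = c.level * c.coverage
        total += mass
        if c.central_motif(k) == target_motif:
            target += mass
    if total == 0.0:
        warnings.warn("zero total methylation mass; composition undefined")
        return float("nan")
    return target / total


def overall_m6a_level(
    site_counts: Sequence[SiteCount], p0: Optional[float] = None
) -> tuple[float, float]:
    """Transcriptome-wide unconverted fraction over all A sites.

    Returns (raw, background_subtracted); the subtracted value is raw - p0
    (NaN when p0 is not supplied). Empty input yields NaN.
    """
    total_a = sum(s.n_A for s in site_counts)
    total_n = sum(s.coverage for s in site_counts)
    if total_n == 0:
        return float("nan"), float("nan")
    raw = total_a / total_n
    adj = raw - p0 if p0 is not None else float("nan")
    return raw, adj


def importance_scores(
    sites: Sequence[Union[SiteCount, SiteCall]],
    flank: int = 10,
    weighting: str = "coverage",
) -> pd.DataFrame:
    """Entropy-based importance of each flanking position -10..+10.

    For each offset p and base b, L[p][b] is the (coverage-weighted, or
    unweighted when ``weighting='mean'``) mean methylation level of A sites
    carrying base b at offset p. Normalising L over bases gives q; the
    importance is I[p] = 2 - H(q) bits, with per-base contributions
    c[p][b] = I[p] * q[p][b]. A position with no signal scores 0.

    Returns a DataFrame indexed by offset with columns A, C, G, U, total.
    """
    if weighting not in ("coverage", "mean"):
        raise ValueError("weighting must be 'coverage' or 'mean'")
    offsets = [p for p in range(-flank, flank + 1) if p != 0]
    mass = {p: dict.fromkeys(BASES, 0.0) for p in offsets}
    weight = {p: dict.fromkeys(BASES, 0.0) for p in offsets}
    mid = None
    for site in sites:
        ctx = site.context
        if mid is None:
            mid = len(ctx) // 2
            if mid < flank:
                raise ValueError(
                    f"contexts must cover +/-{flank} around the site"
                )
        lv = _level(site)
        w = site.coverage if weighting == "coverage" else 1.0
        for p in offsets:
            b = ctx[mid + p]
            if b not in mass[p]:
                continue  # N at reference edge
            mass[p][b] += lv * w
            weight[p][b] += w

    rows = []
    for p in offsets:
        L = np.array(
            [
                mass[p][b] / weight[p][b] if weight[p][b] > 0 else 0.0
                for b in BASES
            ]
        )
        total_L = L.sum()
        if total_L <= 0:
            rows.append({"position": p, **dict.fromkeys(BASES, 0.0), "total": 0.0})
            continue
        q = L / total_L
        entropy = -sum(x * math.log2(x) for x in q if x > 0)
        importance = 2.0 - entropy
        contrib = importance * q
        rows.append(
            {
                "position": p,
                **{b: float(c) for b, c in zip(BASES, contrib)},
                "total": float(importance),
            }
        )
    return pd.DataFrame(rows).set_index("position")
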