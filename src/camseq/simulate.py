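"""Synthetic transcriptomes, ground-truth m6A placements and converted reads.

The generator emulates the statistical structure of a chemical-deamination
m6A library: unmodified A is read as G with probability ``e`` (conversion
efficiency, default 0.995 so the background non-conversion rate is 0.5%);
a methylated molecule keeps its A except for a small false-conversion rate
``f``; modification levels are motif-dependent (RAC-enriched) and drawn per
site from a Beta distribution; expression is log-normal; reverse-transcription
stops may truncate reads at converted G's.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

RNA = "ACGU"
_COMP = str.maketrans("ACGU", "UGCA")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class MotifSpec:
    """Methylation rule for one 3-mer context centered on A.

    site_probability: chance an eligible A in this motif becomes a true site.
    beta_a, beta_b: shape parameters of the per-site modification-level Beta.
    """

    site_probability: float
    beta_a: float
    beta_b: float

    def mean_level(self) -> float:
        return self.beta_a / (self.beta_a + self.beta_b)


#: Default motif rules: GAC is the dominant methylated context (mean level
#: 0.38, matching the level observed for the most abundant GAC 5-mers), AAC
#: the second; UAG/UAA/CAG/CAA stay unmethylated and serve as background.
DEFAULT_MOTIF_SPEC = {
    "GAC": MotifSpec(0.15, 2.0, 2.0 * (1 - 0.38) / 0.38),
    "AAC": MotifSpec(0.10, 2.0, 2.0 * (1 - 0.30) / 0.30),
}


@dataclass
class SimulationConfig:
    n_transcripts: int = 50
    length_range: tuple[int, int] = (500, 2000)
    gc_content: float = 0.5
    expression_lognormal_params: tuple[float, float] = (0.0, 1.0)
    motif_level_spec: dict[str, MotifSpec] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_SPEC)
    )
    conversion_efficiency: float = 0.995
    m6a_false_conversion: float = 0.005
    seq_error_rate: float = 0.001
    read_length: int = 100
    n_reads: int = 20000
    rt_stop_rate: float = 0.0
    seed: int = 0
    #: optional explicit motif planting: motif -> occurrences per transcript
    plant_per_transcript: dict[str, int] = field(default_factory=dict)
    #: multiply site_probability inside the stop-codon hotspot (-20..+180)
    hotspot_boost: float = 1.0
    #: restrict the hotspot boost to these motifs (None = all configured)
    hotspot_motifs: Optional[frozenset[str]] = None
    #: if set, fraction of transcripts assigned to a high-methylation group
    #: (max site level above 0.5); the rest stay below 0.4
    gene_high_fraction: Optional[float] = None
    #: >0 couples level negatively to expression rank (0 = off)
    expression_coupling: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "conversion_efficiency",
            "m6a_false_conversion",
            "seq_error_rate",
            "rt_stop_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.length_range[0] < self.read_length:
            raise ConfigurationError(
                "minimum transcript length must be >= read_length"
            )
        if self.length_range[0] > self.length_range[1]:
            raise ConfigurationError("length_range min > max")
        if self.n_transcripts <= 0 or self.n_reads < 0:
            raise ConfigurationError("n_transcripts must be > 0, n_reads >= 0")
        for motif in self.motif_level_spec:
            _validate_motif(motif)
        for motif, count in self.plant_per_transcript.items():
            _validate_motif(motif)
            if count * len(motif) > self.length_range[0]:
                raise ConfigurationError(
                    f"cannot plant {count} x {motif} in a "
                    f"{self.length_range[0]} nt transcript"
                )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TranscriptModel:
    """A simulated transcript: sequence, CDS boundaries, expression weight.

    ``cds_start`` is the 0-based first CDS base; ``cds_end`` the first base
    after the stop codon, so the stop codon occupies [cds_end-3, cds_end).
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    expression_weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start <= self.cds_end <= len(self.sequence):
            raise ValueError("CDS boundaries outside transcript")

    @property
    def stop_codon_start(self) -> int:
        return self.cds_end - 3

    def distance_to_stop(self, position: int) -> int:
        return position - self.stop_codon_start


@dataclass
class GroundTruthSite:
    transcript_id: str
    position: int
    true_level: float
    motif3: str
    motif5: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_level <= 1.0:
            raise ValueError("true_level outside [0, 1]")
        if self.motif3[1] != "A":
            raise ValueError("motif3 must be centered on A")


def _validate_motif(motif: str) -> None:
    if len(motif) != 3 or motif[1] != "A" or any(b not in RNA for b in motif):
        raise ConfigurationError(
            f"motif {motif!r} must be a length-3 RNA string centered on A"
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _context(seq: str, pos: int, flank: int) -> str:
    left = seq[max(0, pos - flank): pos]
    right = seq[pos + 1: pos + 1 + flank]
    return "N" * (flank - len(left)) + left + seq[pos] + right + "N" * (
        flank - len(right)
    )


def build_transcriptome(
    config: SimulationConfig,
) -> list[TranscriptModel]:
    """Draw ``n_transcripts`` i.i.d. sequences at the configured GC content.

    CDS boundaries are placed so the transcript splits roughly into 15%
    5'UTR, 55% CDS and 30% 3'UTR, a typical mRNA anatomy; expression
    weights are log-normal and normalised to sum to 1. Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list(RNA))

    mu, sigma = config.expression_lognormal_params
    weights = rng.lognormal(mu, sigma, size=config.n_transcripts)
    weights = weights / weights.sum()

    lo, hi = config.length_range
    transcripts: list[TranscriptModel] = []
    for i in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(bases[rng.choice(4, size=length, p=probs)])
        seq = _plant_motifs(seq, config, rng)
        utr5 = int(round(length * float(rng.uniform(0.10, 0.20))))
        cds_len = int(round(length * float(rng.uniform(0.50, 0.60))))
        cds_len = max(3, cds_len - cds_len % 3)
        cds_end = min(utr5 + cds_len, length)
        transcripts.append(
            TranscriptModel(
                id=f"tx{i:04d}",
                sequence=seq,
                cds_start=utr5,
                cds_end=cds_end,
                expression_weight=float(weights[i]),
            )
        )
    return transcripts


def _plant_motifs(
    seq: str, config: SimulationConfig, rng: np.random.Generator
) -> str:
    if not config.plant_per_transcript:
        return seq
    arr = list(seq)
    taken: set[int] = set()
    for motif, count in config.plant_per_transcript.items():
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 100 * count + 100:
                raise ConfigurationError(
                    f"could not plant {count} x {motif}: transcript too short"
                )
            start = int(rng.integers(0, len(arr) - len(motif) + 1))
            span = range(start - 1, start + len(motif) + 1)
            if any(p in taken for p in span):
                continue
            arr[start: start + len(motif)] = list(motif)
            taken.update(range(start, start + len(motif)))
            placed += 1
    return "".join(arr)


def assign_methylation(
    transcripts: list[TranscriptModel], config: SimulationConfig
) -> list[GroundTruthSite]:
    """Mark eligible A's as true m6A sites with motif-dependent levels.

    Every A whose 3-mer context matches a configured motif becomes a site
    with that motif's ``site_probability`` (optionally boosted inside the
    stop-codon hotspot) and draws its level from the motif's Beta. A's
    outside configured motifs carry level 0 and are not emitted.
    """
    rng = np.random.default_rng(_child_seed(config.seed, 1))
    sites: list[GroundTruthSite] = []
    if not config.motif_level_spec:
        return sites

    expr_rank = _expression_ranks(transcripts)
    high_group: dict[str, bool] = {}
    if config.gene_high_fraction is not None:
        for tx in transcripts:
            high_group[tx.id] = bool(
                rng.random() < config.gene_high_fraction
            )

    for tx in transcripts:
        seq = tx.sequence
        tx_sites: list[GroundTruthSite] = []
        for pos in range(1, len(seq) - 1):
            if seq[pos] != "A":
                continue
            motif = seq[pos - 1: pos + 2]
            spec = config.motif_level_spec.get(motif)
            if spec is None:
                continue
            p_site = spec.site_probability
            if config.hotspot_boost != 1.0 and _in_hotspot(tx, pos):
                if (
                    config.hotspot_motifs is None
                    or motif in config.hotspot_motifs
                ):
                    p_site = min(1.0, p_site * config.hotspot_boost)
            if rng.random() >= p_site:
                continue
            level = float(rng.beta(spec.beta_a, spec.beta_b))
            if config.expression_coupling > 0.0:
                level *= max(
                    0.05,
                    1.0 - config.expression_coupling * expr_rank[tx.id],
                )
            tx_sites.append(
                GroundTruthSite(
                    transcript_id=tx.id,
                    position=pos,
                    true_level=min(1.0, level),
                    motif3=motif,
                    motif5=_context(seq, pos, 2),
                )
            )
        if config.gene_high_fraction is not None and tx_sites:
            _apply_gene_group(tx_sites, high_group[tx.id], rng)
        sites.extend(tx_sites)
    return sites


def _apply_gene_group(
    tx_sites: list[GroundTruthSite], high: bool, rng: np.random.Generator
) -> None:
    # Two-component gene population: low-group genes keep every site below
    # 0.4; high-group genes get one site pushed above 0.65.
    for s in tx_sites:
        s.true_level = 0.05 + 0.35 * s.true_level
    if high:
        chosen = tx_sites[int(rng.integers(len(tx_sites)))]
        chosen.true_level = float(rng.uniform(0.65, 0.95))


def _in_hotspot(tx: TranscriptModel, pos: int) -> bool:
    return -20 <= tx.distance_to_stop(pos) <= 180


def _expression_ranks(
    transcripts: list[TranscriptModel],
) -> dict[str, float]:
    order = np.argsort([t.expression_weight for t in transcripts])
    n = max(1, len(transcripts) - 1)
    ranks = {}
    for r, idx in enumerate(order):
        ranks[transcripts[idx].id] = r / n
    return ranks


@dataclass
class SimulatedRead:
    name: str
    sequence: str  # DNA alphabet, sequencing orientation
    quality: str
    transcript_id: str
    start: int
    strand: str


def simulate_reads(
    transcripts: list[TranscriptModel],
    truth: list[GroundTruthSite],
    config: SimulationConfig,
) -> list[SimulatedRead]:
    """Sample converted stranded reads from the transcriptome.

    Per molecule, each overlapped truth site is methylated with probability
    ``true_level``; a methylated A survives as A with probability (1-f),
    any other A converts to G with probability e. Uniform sequencing errors
    at ``seq_error_rate``; with ``rt_stop_rate`` per emitted G the read is
    truncated at that G (5' prefix retained). Reads are emitted in the DNA
    alphabet with the originating strand encoded in the read name
    (``name|transcript|start|strand``).
    """
    rng = np.random.default_rng(_child_seed(config.seed, 2))
    truth_by_tx: dict[str, dict[int, float]] = {}
    for s in truth:
        truth_by_tx.setdefault(s.transcript_id, {})[s.position] = s.true_level

    weights = np.array([t.expression_weight for t in transcripts])
    weights = weights / weights.sum()
    tx_idx = rng.choice(len(transcripts), size=config.n_reads, p=weights)

    e = config.conversion_efficiency
    f = config.m6a_false_conversion
    reads: list[SimulatedRead] = []
    for i, ti in enumerate(tx_idx):
        tx = transcripts[ti]
        start = int(rng.integers(0, len(tx.sequence) - config.read_length + 1))
        site_levels = truth_by_tx.get(tx.id, {})
        out = []
        truncated = False
        for offset in range(config.read_length):
            pos = start + offset
            base = tx.sequence[pos]
            if base == "A":
                level = site_levels.get(pos, 0.0)
                methylated = level > 0.0 and rng.random() < level
                if methylated:
                    base = "G" if rng.random() < f else "A"
                else:
                    base = "G" if rng.random() < e else "A"
            if config.seq_error_rate > 0 and rng.random() < config.seq_error_rate:
                base = RNA[(RNA.index(base) + int(rng.integers(1, 4))) % 4]
            out.append(base)
            if (
                base == "G"
                and config.rt_stop_rate > 0
                and rng.random() < config.rt_stop_rate
            ):
                truncated = True
                break
        seq = "".join(out).replace("U", "T")
        reads.append(
            SimulatedRead(
                name=f"read{i:07d}|{tx.id}|{start}|+"
                + ("|rtstop" if truncated else ""),
                sequence=seq,
                quality="I" * len(seq),
                transcript_id=tx.id,
                start=start,
                strand="+",
            )
        )
    return reads


def simulate_site_counts(
    transcripts: list[TranscriptModel],
    truth: list[GroundTruthSite],
    config: SimulationConfig,
    mean_coverage: float = 50.0,
    coverage_dispersion: str = "poisson",
):
    """Draw per-A-site (n_A, n_G) counts directly from the generative model.

    Exact marginal of read-level simulation when ``rt_stop_rate=0`` and
    sequencing errors are folded into ``n_other``: each of N molecules is
    methylated with probability ``true_level`` and then shows A with
    probability (1-f) if methylated, (1-e) otherwise. Coverage is Poisson
    around ``mean_coverage`` (or fixed when ``coverage_dispersion='fixed'``).

    Returns a list of :class:`camseq.align.SiteCount` covering every A in
    every transcript, paired with the matching truth level per site.
    """
    from .align import SiteCount

    rng = np.random.default_rng(_child_seed(config.seed, 3))
    truth_by_tx: dict[str, dict[int, float]] = {}
    for s in truth:
        truth_by_tx.setdefault(s.transcript_id, {})[s.position] = s.true_level

    e = config.conversion_efficiency
    f = config.m6a_false_conversion
    counts: list[SiteCount] = []
    levels: list[float] = []
    for tx in transcripts:
        site_levels = truth_by_tx.get(tx.id, {})
        seq = tx.sequence
        positions = [i for i, b in enumerate(seq) if b == "A"]
        if coverage_dispersion == "fixed":
            ns = np.full(len(positions), int(mean_coverage))
        else:
            ns = rng.poisson(mean_coverage, size=len(positions))
        for pos, n in zip(positions, ns):
            n = int(n)
            if n == 0:
                continue
            level = site_levels.get(pos, 0.0)
            p_a = level * (1 - f) + (1 - level) * (1 - e)
            n_a = int(rng.binomial(n, p_a))
            counts.append(
                SiteCount(
                    reference_id=tx.id,
                    position=pos,
                    strand="+",
                    context=_context(seq, pos, 10),
                    n_A=n_a,
                    n_G=n - n_a,
                    n_other=0,
                )
            )
            levels.append(level)
    return counts, levels


def _child_seed(seed: int, stream: int) -> int:
    # distinct deterministic streams per stage, kept below 2**31
    return (seed * 1000003 + stream) % (2**31 - 1)
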