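# Methods

## The readout model

A deamination-converted library turns methylation state into base calls:
an unmodified A is read as G with probability *e* (conversion efficiency),
while an m6A survives as A except for a small false-conversion rate *f*.
At an A site covered by N informative reads where a fraction ℓ of
molecules is methylated, the unconverted count is

    n_A ~ Binomial(N, ℓ·(1−f) + (1−ℓ)·(1−e))

so the raw level n_A/N estimates ℓ up to an affine distortion with slope
1−f−(1−e) and intercept 1−e. Defaults are e = 0.995 (background
non-conversion 0.5%, the assay's stated operating point), f = 0.005
(whether m6A ever converts is not established; f is a knob, not a claim),
sequencing error 0.001, reverse-transcription stop rate 0.

## Synthetic-data generator

`camseq.simulate` emulates the statistical structure of a converted
library, not its molecular detail:

- **Transcriptome.** i.i.d. sequences at a configurable GC content
  (default 0.5), lengths uniform in 500–2000 nt, split ~15% 5'UTR /
  ~55% CDS / ~30% 3'UTR — a typical mRNA anatomy. Expression weights are
  log-normal(0, 1), normalised to 1.
- **Methylation.** Every A whose 3-mer context matches a configured motif
  becomes a true site with that motif's site probability; its level is
  drawn from a per-motif Beta. Defaults: GAC (p = 0.15, Beta mean 0.38 —
  the level observed for the dominant GAC 5-mer context) and AAC
  (p = 0.10, mean 0.30); the rarely methylated motifs UAG/UAA/CAG/CAA are
  left unmethylated so the background estimator has an honest target.
- **Per-molecule Bernoulli levels.** A molecule is methylated at a site
  with probability ℓ, independently across sites; this is the simplest
  model consistent with a per-site modification ratio. No within-molecule
  correlation is modeled.
- **Reads.** Fragments sample transcripts proportional to expression and
  positions uniformly; conversion, sequencing error, and optional per-G
  RT truncation (5' prefix kept) are applied per base. Reads are emitted
  5'→3' in the DNA alphabet with the origin recoverable from the read
  name; coordinates are 0-based half-open throughout.
- **Structured worlds for recovery tests.** Optional knobs boost the site
  probability of selected motifs inside the stop-codon hotspot, split
  genes into a low-max (< 0.4) / high-max (> 0.65) two-component
  population, or couple level negatively to expression rank. These state
  the worlds the regional/gene analyses are validated against.
- **Count-level shortcut.** `simulate_site_counts` draws (n_A, N) per site
  directly from the binomial above with Poisson (or fixed) coverage. It is
  the exact marginal of read simulation when the RT-stop rate is 0 and
  sequencing errors are excluded from the informative denominator, and it
  is what the large-sample calibration tests use; read-level simulation
  remains the path that exercises the aligner and pipeline.

What a green test on this generator does *not* establish: robustness to
alignment bias from real secondary structure, splice isoforms, PCR
duplicates, quality miscalibration, or motif composition of a real
transcriptome. The generator's i.i.d. sequences make motif frequencies
near-uniform (each 3-mer ≈ 1/16 of A sites), unlike real transcriptomes.

## Collapsed-alphabet alignment

Reads and the reference are compared with A→G applied to both (T→C on the
antisense reference strand), making the aligner blind to conversion
exactly as bisulfite aligners are blind to C/T. The mapper is a
desk-scale seed-and-extend: collapsed k-mers (k = 16) from both strands
are indexed; up to three seeds per read propose candidate placements;
candidates are scored by ungapped collapsed-space mismatches (cap 5% of
read length). The best placement wins; exact ties are kept but flagged
non-unique and discarded before pileup, so repeated motifs cannot bias
levels. Indels are not modeled — short mRNA fragments rarely need them,
and the ungapped design keeps the brute-force all-positions scorer an
exact oracle, which the tests exploit exhaustively on ≤ 2 kb references.
An external SAM over the same reference can substitute for the built-in
mapper; only the minimal dialect (header, FLAG strand bit, POS, SEQ,
QUAL, NM) is consumed.

Pileup counts, per sense-strand A site, reads showing A (unconverted) vs
G (converted) in sense space, skipping bases below Phred 20. Coverage is
defined as n_A + n_G: sequencing errors to C/T are tallied separately and
excluded from the level denominator so they cannot dilute the ratio.
Sites are emitted when coverage is **strictly greater than** 20.

## Site calling

The background p0 pools n_A over N across all A sites whose central 3-mer
is UAG, UAA, CAG or CAA — contexts nearly devoid of m6A — and is floored
at 1/(ΣN+1) when no unconverted read is seen. It is estimated per library,
since the noise level is condition-specific. Each retained site gets a
one-sided exact binomial upper-tail p-value P(X ≥ n_A | N, p0), compared
directly to α = 0.001 with no multiple-testing correction: the target is
a fixed P-cutoff filter, not an FDR. The test form is isolated in one
function so a Poisson or Fisher variant could be swapped in.

Levels are reported raw (n_A/N) by default; an optional efficiency
adjustment maps level → (level − p0)/(1 − p0), clipped to [0, 1]. Raw is
the default because no adjustment is part of the stated filtering, and
the affine distortion is small at e = 0.995.

## Motif analytics

- The motif table aggregates per 3- or 5-mer context: total A sites,
  called sites, relative frequency among called sites, unweighted mean
  level and the coverage-weighted level Σ(level·N)/ΣN.
- The UAG/GAC signal-to-noise ratio defaults to the methylation-mass
  reading, Σ(level·N) over all A sites per motif; a called-site count
  ratio is available via `method="count"`. Both readings of the ratio are
  defensible; mass is the default because it uses all sites and does not
  depend on the significance threshold.
- Weighted motif composition: share of Σ(level·N) over significant sites
  falling on a target motif (e.g. AAC).
- Overall m6A level: pooled Σn_A/ΣN over all A sites, reported raw and
  background-subtracted (raw − p0).
- Importance scores: for each offset p ∈ {−10..+10}\{0} and base b, L[p][b]
  is the coverage-weighted mean level of sites carrying b at p;
  normalising over bases gives q[p]; I[p] = 2 − H(q[p]) in bits, with
  per-base contributions I[p]·q[p][b]. Coverage weighting is the default
  (it matches how every other aggregate here is weighted); an unweighted
  variant is one flag away. A position with zero level mass scores 0 by
  convention. I ∈ [0, 2] always, and permuting base labels permutes
  contributions without changing I.

## Regional and gene analysis

Distances use transcript coordinates with the stop codon's first base at
0. The deposition hotspot is the **closed** interval [−20, +180]; the
printed bounds carry no bracket semantics, so both endpoints are included
and the choice is configurable. The metagene axis scales each transcript
into 5'UTR | CDS | 3'UTR thirds and bins methylation mass (level·N);
densities sum to 1.

One-way ANOVA is computed from explicit sums of squares (the tests check
the SST = SSB + SSW identity and the degenerate cases: zero between-group
variance gives F = 0, zero within-group variance with signal gives
F = +inf with p = 0); the p-value comes from the F distribution. It is
applied per motif to levels inside vs outside the hotspot, and to
between-gene vs within-gene variation restricted to hotspot sites (other
regions are minimally modified and would mask the gene effect).

Gene summaries average level over **significant** sites
(coverage-weighted; an all-covered-sites variant is a flag) and take the
maximum significant-site level. Genes split at max level 0.5 into group1
(below) and group2 (at or above — the boundary must land somewhere; it is
assigned to the upper group and is configurable); genes with no
significant site are "none". Bimodality of per-gene average levels is
deliberately not asserted — only the max-level grouping is implemented.
Expression is log10 of summed A-site coverage per transcript kilobase, a
self-contained proxy from the same library rather than an external
quantification. Association reports Pearson and Spearman correlations of
expression vs average level (all methylated genes, group1, group2) and
Mann–Whitney rank-sum comparisons of expression between none/group1/group2.

## Numerical and interface choices

- Determinism: every stage derives its RNG stream from the single config
  seed; identical config + seed gives byte-identical outputs (hash-checked
  in the manifest).
- RNA alphabet uses U internally; FASTA/FASTQ/SAM are written with T for
  tool compatibility. Motifs are always reported in RNA letters.
- Coordinates are 0-based half-open (BED convention) in all tables; GTF
  output is 1-based inclusive as the format requires.
- The pipeline manifest (JSON) records parameters, input/output SHA-256
  hashes and per-stage row counts; any stage failure aborts with the
  stage name and a nonzero exit.
- `--threads` is accepted for interface compatibility; results are
  independent of it (the desk-scale implementation is single-threaded).

## Known limitations

No splice-aware alignment, paired-end reads, indels, PCR-duplicate or
quality-miscalibration modeling; no replicate merging or differential
methylation; the mapper is for synthetic desk-scale references, not a
production genome aligner. The importance-score formula is a concrete,
documented instantiation (level-mass entropy over bases); published
variants may weight differently, which is why the normalisation is
configurable.
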