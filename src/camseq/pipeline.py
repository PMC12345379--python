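"""End-to-end pipeline: simulate -> align -> pileup -> call -> motifs ->
regions -> genes, with a JSON run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import align as _align
from . import calling as _calling
from . import io as _io
from . import motifs as _motifs
from . import regions as _regions
from . import simulate as _simulate

logger = logging.getLogger("camseq")

STAGES = ["simulate", "align", "pileup", "call", "motifs", "regions", "genes"]

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level", "reads_fastq", "reference_fasta",
    "annotation_gtf", "simulate", "align", "pileup", "call", "motifs",
    "regions",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "camseq_out"
    log_level: str = "INFO"
    # external inputs; when absent the simulate stage provides them
    reads_fastq: Optional[str] = None
    reference_fasta: Optional[str] = None
    annotation_gtf: Optional[str] = None
    simulate: dict = field(default_factory=dict)
    align: dict = field(default_factory=lambda: {"k": 16})
    pileup: dict = field(
        default_factory=lambda: {"min_base_quality": 20, "min_coverage": 20}
    )
    call: dict = field(
        default_factory=lambda: {"alpha": 0.001, "min_coverage": 20}
    )
    motifs: dict = field(default_factory=lambda: {"motif_length": 3})
    regions: dict = field(default_factory=lambda: {"n_bins": 30})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage `{stage}` failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="[camseq %(levelname)s] %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "parameters": dataclasses.asdict(config)}

    # --- simulate (optional when external inputs are given)
    if config.reads_fastq is None:
        logger.info("simulate: generating synthetic library")
        sim_cfg = _simulate.SimulationConfig(
            seed=config.seed, **config.simulate
        )
        transcripts = _simulate.build_transcriptome(sim_cfg)
        truth = _simulate.assign_methylation(transcripts, sim_cfg)
        reads = _simulate.simulate_reads(transcripts, truth, sim_cfg)
        ref_fa = out / "reference.fa"
        reads_fq = out / "reads.fastq"
        gtf = out / "annotation.gtf"
        _io.write_fasta(transcripts, ref_fa)
        _io.write_fastq(reads, reads_fq)
        _io.write_gtf(transcripts, gtf)
        _io.write_truth_bed(truth, out / "truth.bed")
        manifest["stages"]["simulate"] = {
            "n_transcripts": len(transcripts),
            "n_truth_sites": len(truth),
            "n_reads": len(reads),
        }
    else:
        for stage, p in (
            ("align", config.reads_fastq),
            ("align", config.reference_fasta),
        ):
            if p is None or not Path(p).exists():
                raise StageError(stage, f"missing input file: {p}")
        ref_fa = Path(config.reference_fasta)
        reads_fq = Path(config.reads_fastq)
        gtf = Path(config.annotation_gtf) if config.annotation_gtf else None
        manifest["stages"]["simulate"] = {"skipped": True}

    manifest["inputs"] = {
        "reference_fasta": _sha256(ref_fa),
        "reads_fastq": _sha256(reads_fq),
    }

    # --- align
    try:
        references = _io.read_fasta(ref_fa)
        index = _align.build_index(references, k=config.align.get("k", 16))
        fastq = _io.read_fastq(reads_fq)
        alignments = _align.align_reads(
            fastq, index, max_mismatch=config.align.get("max_mismatch")
        )
    except (OSError, _align.InputError, _io.ParseError) as exc:
        raise StageError("align", str(exc)) from exc
    _io.write_sam(alignments, references, out / "alignments.sam")
    unique = [a for a in alignments if a.unique]
    manifest["stages"]["align"] = {
        "n_reads": len(fastq),
        "n_mapped": len(alignments),
        "n_unique": len(unique),
    }
    logger.info(
        "align: %d/%d reads mapped (%d unique)",
        len(alignments), len(fastq), len(unique),
    )

    # --- pileup
    try:
        sites = _align.pileup_A_sites(unique, references, **config.pileup)
    except _align.InputError as exc:
        raise StageError("pileup", str(exc)) from exc
    _io.write_site_counts(sites, out / "site_counts.tsv")
    manifest["stages"]["pileup"] = {"n_sites": len(sites)}

    # --- call
    try:
        background = _calling.estimate_background(sites)
        calls = _calling.call_sites(
            sites, background,
            alpha=config.call.get("alpha", 0.001),
            min_coverage=config.call.get("min_coverage", 20),
        )
    except (_calling.BackgroundEstimationError, ValueError) as exc:
        raise StageError("call", str(exc)) from exc
    _io.write_calls(calls, out / "site_calls.tsv")
    _io.write_calls_bed(calls, out / "site_calls.bed")
    n_sig = sum(c.significant for c in calls)
    manifest["stages"]["call"] = {
        "p0": background.p0,
        "n_sites": len(calls),
        "n_significant": n_sig,
    }
    logger.info("call: %d sites, %d significant, p0=%.5f",
                len(calls), n_sig, background.p0)

    # --- motifs
    table = _motifs.motif_table(
        calls, motif_length=config.motifs.get("motif_length", 3)
    )
    table.to_csv(out / "motif_table.tsv", sep="\t")
    profile = _motifs.importance_scores(calls)
    profile.to_csv(out / "importance.tsv", sep="\t")
    overall_raw, overall_adj = _motifs.overall_m6a_level(sites, background.p0)
    manifest["stages"]["motifs"] = {
        "n_motifs": len(table),
        "snr_uag_gac": _motifs.snr_uag_gac(calls),
        "overall_level_raw": overall_raw,
        "overall_level_adjusted": overall_adj,
    }

    # --- regions
    try:
        sequences = {n: s for n, s in references.items()}
        if gtf is not None:
            transcripts_by_id = _io.read_gtf(gtf, sequences)
        else:
            raise StageError("regions", "no annotation available")
        annotated, dropped = _regions.annotate_sites(calls, transcripts_by_id)
    except (_io.ParseError, OSError) as exc:
        raise StageError("regions", str(exc)) from exc
    metagene = _regions.metagene_profile(
        annotated, n_bins=config.regions.get("n_bins", 30)
    )
    metagene.to_csv(out / "metagene.tsv", sep="\t", index=False)
    var_region = _regions.regional_variance_by_motif(annotated)
    var_region.to_csv(out / "variance_region.tsv", sep="\t", index=False)
    manifest["stages"]["regions"] = {
        "n_annotated": len(annotated),
        "n_dropped": dropped,
        "n_motifs_tested": len(var_region),
    }

    # --- genes
    summaries = _regions.gene_summaries(annotated, transcripts_by_id)
    gene_df = _df_from_summaries(summaries)
    gene_df.to_csv(out / "gene_summaries.tsv", sep="\t", index=False)
    assoc = _regions.expression_methylation_association(summaries)
    assoc.to_csv(out / "expression_association.tsv", sep="\t", index=False)
    manifest["stages"]["genes"] = {
        "n_genes": len(summaries),
        "n_group1": sum(s.group == "group1" for s in summaries),
        "n_group2": sum(s.group == "group2" for s in summaries),
    }

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in {".tsv", ".bed", ".sam", ".fa", ".fastq", ".gtf"}
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _df_from_summaries(summaries):
    import pandas as pd

    return pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries],
        columns=[
            "gene_id", "n_sites", "average_level", "max_level", "group",
            "expression",
        ],
    )
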