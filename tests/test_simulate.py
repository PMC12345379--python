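"""Synthetic-library generator: determinism, composition, methylation
placement and the conversion noise model."""

import math

import numpy as np
import pytest

from camseq.simulate import (
    ConfigurationError,
    MotifSpec,
    SimulationConfig,
    assign_methylation,
    build_transcriptome,
    simulate_reads,
    simulate_site_counts,
)


def _sequences(cfg):
    return [t.sequence for t in build_transcriptome(cfg)]


class TestBuildTranscriptome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_transcripts=5, seed=1)
        assert _sequences(cfg) == _sequences(cfg)

    def test_different_seeds_differ(self):
        a = _sequences(SimulationConfig(n_transcripts=5, seed=1))
        b = _sequences(SimulationConfig(n_transcripts=5, seed=2))
        assert a != b

    def test_zero_gc_gives_au_only(self):
        cfg = SimulationConfig(
            n_transcripts=3, gc_content=0.0, motif_level_spec={}, seed=0
        )
        for seq in _sequences(cfg):
            assert set(seq) <= {"A", "U"}

    def test_gc_content_matches_request(self):
        cfg = SimulationConfig(
            n_transcripts=5, gc_content=0.6, length_range=(2000, 2000),
            motif_level_spec={}, seed=3,
        )
        seqs = _sequences(cfg)
        gc = sum(s.count("G") + s.count("C") for s in seqs) / sum(
            len(s) for s in seqs
        )
        assert gc == pytest.approx(0.6, abs=0.02)

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                length_range=(100, 100), read_length=50,
                plant_per_transcript={"GAC": 50},
            )

    def test_cds_boundaries_inside_transcript(self):
        for tx in build_transcriptome(SimulationConfig(seed=5)):
            assert 0 < tx.cds_start < tx.cds_end <= len(tx.sequence)
            assert tx.stop_codon_start >= tx.cds_start

    def test_expression_weights_normalized(self):
        txs = build_transcriptome(SimulationConfig(seed=5))
        assert sum(t.expression_weight for t in txs) == pytest.approx(1.0)


class TestAssignMethylation:
    def test_empty_spec_yields_no_sites(self):
        cfg = SimulationConfig(motif_level_spec={}, seed=1)
        assert assign_methylation(build_transcriptome(cfg), cfg) == []

    def test_degenerate_beta_gives_level_one(self):
        cfg = SimulationConfig(
            n_transcripts=5,
            motif_level_spec={"GAC": MotifSpec(1.0, 1e6, 1e-6)},
            seed=2,
        )
        sites = assign_methylation(build_transcriptome(cfg), cfg)
        assert sites
        assert all(s.true_level > 0.999 for s in sites)

    def test_sites_are_at_a_in_configured_motif(self):
        cfg = SimulationConfig(n_transcripts=5, seed=3)
        txs = build_transcriptome(cfg)
        by_id = {t.id: t for t in txs}
        for s in assign_methylation(txs, cfg):
            seq = by_id[s.transcript_id].sequence
            assert seq[s.position] == "A"
            assert seq[s.position - 1: s.position + 2] == s.motif3
            assert s.motif3 in cfg.motif_level_spec

    def test_mean_level_matches_beta_mean(self):
        # over many GAC placements the mean level converges to a/(a+b)
        spec = MotifSpec(1.0, 2.0, 2.0 * (1 - 0.38) / 0.38)
        cfg = SimulationConfig(
            n_transcripts=60, length_range=(2000, 2000),
            motif_level_spec={"GAC": spec}, seed=4,
        )
        sites = assign_methylation(build_transcriptome(cfg), cfg)
        levels = np.array([s.true_level for s in sites])
        assert len(levels) > 1000
        se = levels.std(ddof=1) / math.sqrt(len(levels))
        assert abs(levels.mean() - 0.38) < 3 * se

    def test_invalid_motif_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(motif_level_spec={"GGC": MotifSpec(1, 1, 1)})
        with pytest.raises(ConfigurationError):
            SimulationConfig(motif_level_spec={"GACU": MotifSpec(1, 1, 1)})


class TestSimulateReads:
    def test_no_reads_is_valid(self, small_library):
        transcripts, truth, _ = small_library
        cfg = SimulationConfig(n_reads=0, seed=1)
        assert simulate_reads(transcripts, truth, cfg) == []

    def test_perfect_conversion_fully_methylated_site(self):
        # e=1, f=0, level=1: reads show A at the site, G at every other A
        cfg = SimulationConfig(
            n_transcripts=2, n_reads=200,
            motif_level_spec={"GAC": MotifSpec(1.0, 1e6, 1e-6)},
            conversion_efficiency=1.0, m6a_false_conversion=0.0,
            seq_error_rate=0.0, seed=6,
        )
        transcripts = build_transcriptome(cfg)
        truth = assign_methylation(transcripts, cfg)
        reads = simulate_reads(transcripts, truth, cfg)
        site_pos = {(s.transcript_id, s.position) for s in truth}
        by_id = {t.id: t for t in transcripts}
        checked_site = checked_other = 0
        for r in reads:
            seq = by_id[r.transcript_id].sequence
            for off, base in enumerate(r.sequence):
                pos = r.start + off
                if seq[pos] != "A":
                    continue
                if (r.transcript_id, pos) in site_pos:
                    assert base == "A"
                    checked_site += 1
                else:
                    assert base == "G"
                    checked_other += 1
        assert checked_site > 0 and checked_other > 0

    def test_background_nonconversion_rate(self):
        # e=0.995, no methylation: observed A fraction ~ 0.005
        cfg = SimulationConfig(
            n_transcripts=5, n_reads=2000, motif_level_spec={},
            seq_error_rate=0.0, seed=7,
        )
        transcripts = build_transcriptome(cfg)
        reads = simulate_reads(transcripts, [], cfg)
        by_id = {t.id: t for t in transcripts}
        n_a = n_total = 0
        for r in reads:
            seq = by_id[r.transcript_id].sequence
            for off, base in enumerate(r.sequence):
                if seq[r.start + off] == "A":
                    n_total += 1
                    n_a += base == "A"
        assert n_total > 10000
        se = math.sqrt(0.005 * 0.995 / n_total)
        assert abs(n_a / n_total - 0.005) < 3 * se

    def test_conversion_bookkeeping_expectation(self):
        # expected A fraction = level*(1-f) + (1-level)*(1-e)
        level, e, f = 0.3, 0.99, 0.01
        cfg = SimulationConfig(
            n_transcripts=3, n_reads=4000,
            motif_level_spec={
                "GAC": MotifSpec(1.0, 1e6 * level, 1e6 * (1 - level))
            },
            conversion_efficiency=e, m6a_false_conversion=f,
            seq_error_rate=0.0, seed=8,
        )
        transcripts = build_transcriptome(cfg)
        truth = assign_methylation(transcripts, cfg)
        reads = simulate_reads(transcripts, truth, cfg)
        site_pos = {(s.transcript_id, s.position) for s in truth}
        n_a = n_total = 0
        for r in reads:
            for off, base in enumerate(r.sequence):
                if (r.transcript_id, r.start + off) in site_pos:
                    n_total += 1
                    n_a += base == "A"
        expected = level * (1 - f) + (1 - level) * (1 - e)
        se = math.sqrt(expected * (1 - expected) / n_total)
        assert abs(n_a / n_total - expected) < 3 * se

    def test_rt_stop_shortens_reads(self):
        base = dict(n_transcripts=5, n_reads=2000, seed=9)
        lengths = []
        for rate in (0.0, 0.02, 0.1):
            cfg = SimulationConfig(rt_stop_rate=rate, **base)
            transcripts = build_transcriptome(cfg)
            truth = assign_methylation(transcripts, cfg)
            reads = simulate_reads(transcripts, truth, cfg)
            lengths.append(np.mean([len(r.sequence) for r in reads]))
        assert lengths[0] > lengths[1] > lengths[2]
        assert lengths[0] == SimulationConfig(**base).read_length

    def test_reads_carry_origin_tag(self, small_library):
        _, _, reads = small_library
        for r in reads[:100]:
            name, tid, start, strand = r.name.split("|")[:4]
            assert tid == r.transcript_id
            assert int(start) == r.start
            assert strand == r.strand == "+"

    def test_read_determinism(self, small_config, small_library):
        _, _, reads = small_library
        transcripts = build_transcriptome(small_config)
        truth = assign_methylation(transcripts, small_config)
        again = simulate_reads(transcripts, truth, small_config)
        assert [(r.name, r.sequence) for r in again] == [
            (r.name, r.sequence) for r in reads
        ]


class TestSimulateSiteCounts:
    def test_counts_match_generative_expectation(self):
        cfg = SimulationConfig(
            n_transcripts=20, length_range=(1000, 1000), seed=10
        )
        transcripts = build_transcriptome(cfg)
        truth = assign_methylation(transcripts, cfg)
        counts, levels = simulate_site_counts(
            transcripts, truth, cfg, mean_coverage=50
        )
        # every A site present, coverage Poisson(50)
        n_a_ref = sum(t.sequence.count("A") for t in transcripts)
        assert len(counts) >= 0.99 * n_a_ref
        covs = np.array([c.coverage for c in counts])
        assert abs(covs.mean() - 50) < 1.0
        # pooled A fraction at unmethylated sites ~ 1-e
        bg = [(c.n_A, c.coverage) for c, lv in zip(counts, levels) if lv == 0]
        n_a = sum(x for x, _ in bg)
        n = sum(x for _, x in bg)
        se = math.sqrt(0.005 * 0.995 / n)
        assert abs(n_a / n - 0.005) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seq_error_rate=-0.1)
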