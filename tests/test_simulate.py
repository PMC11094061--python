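"""Generator contracts: planted regimes, motif planting, coverage model."""

import re
from pathlib import Path

import numpy as np
import pytest

import apashift as a
from apashift.config import ConfigError, SimConfig
from apashift.simulate import (CORE_PAS, RBM3_MOTIF, gene_layout,
                               reverse_complement)


def read_fasta(path):
    seqs, name = {}, None
    for line in open(path):
        line = line.strip()
        if line.startswith(">"):
            name = line[1:]
            seqs[name] = []
        else:
            seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def transcript_seq(rec, seq):
    return seq if rec.strand == "+" else reverse_complement(seq)


class TestGenerateTruth:
    def test_no_effect_config_gives_identical_pdui_everywhere(self):
        cfg = SimConfig(n_genes=25, frac_shortened=0, frac_lengthened=0, seed=1)
        for rec in a.generate_truth(cfg):
            values = set(rec.true_pdui.values())
            assert len(values) == 1

    def test_planted_fractions_are_exact_counts(self):
        cfg = SimConfig(n_genes=100, frac_shortened=0.6, frac_lengthened=0.1,
                        seed=1)
        truth = a.generate_truth(cfg)
        naive = cfg.conditions[0]
        shortened = [r for r in truth
                     if r.true_pdui["CD3_48h"] < r.true_pdui[naive] - 20]
        lengthened = [r for r in truth
                      if r.true_pdui["CD3_48h"] > r.true_pdui[naive] + 20]
        assert len(shortened) == 60
        assert len(lengthened) == 10

    def test_same_seed_reproduces_truth_exactly(self):
        cfg = SimConfig(n_genes=15, seed=42)
        assert a.generate_truth(cfg) == a.generate_truth(cfg)

    def test_shortened_genes_start_from_long_utrs(self):
        cfg = SimConfig(n_genes=60, frac_shortened=1.0, frac_lengthened=0, seed=2)
        for rec in a.generate_truth(cfg):
            assert rec.true_pdui[cfg.conditions[0]] > 66

    def test_breakpoint_strictly_interior(self):
        cfg = SimConfig(n_genes=50, seed=3)
        for rec in a.generate_truth(cfg):
            assert (cfg.min_pas_separation <= rec.proximal_offset
                    <= rec.utr_length - cfg.min_pas_separation)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(frac_shortened=0.8, frac_lengthened=0.4).validate()
        with pytest.raises(ConfigError):
            SimConfig(min_pas_separation=700, utr_length_range=(600, 900)).validate()


class TestSequences:
    def test_rbm3_motif_planted_within_window_of_distal_site(self, tmp_path):
        cfg = SimConfig(n_genes=40, frac_shortened=1.0, frac_lengthened=0,
                        frac_early=1.0, frac_rbm3=1.0, seed=4)
        truth = a.generate_truth(cfg)
        paths = a.write_annotation_and_sequence(truth, cfg, tmp_path)
        seqs = read_fasta(paths["fasta"])
        assert all(r.rbm3_regulated for r in truth)
        for rec in truth:
            tseq = transcript_seq(rec, seqs[rec.gene_id])
            region = tseq[rec.utr_length - cfg.rbm3_window:
                          rec.utr_length + cfg.rbm3_window]
            assert RBM3_MOTIF in region

    def test_full_fidelity_plants_consensus_at_every_proximal_site(self, tmp_path):
        cfg = SimConfig(n_genes=30, pas_fidelity_p=1.0, pas_fidelity_d=1.0, seed=5)
        truth = a.generate_truth(cfg)
        paths = a.write_annotation_and_sequence(truth, cfg, tmp_path)
        seqs = read_fasta(paths["fasta"])
        for rec in truth:
            tseq = transcript_seq(rec, seqs[rec.gene_id])
            assert CORE_PAS in tseq[rec.proximal_offset - 100:rec.proximal_offset]
            assert CORE_PAS in tseq[rec.utr_length - 100:rec.utr_length]

    def test_partial_fidelity_recovered_by_independent_rescan(self, tmp_path):
        """Brute-force string search on the written FASTA reproduces the
        planted proximal-site fidelity within binomial error."""
        cfg = SimConfig(n_genes=1000, pas_fidelity_p=0.4, pas_fidelity_d=0.9,
                        seed=6)
        truth = a.generate_truth(cfg)
        paths = a.write_annotation_and_sequence(truth, cfg, tmp_path)
        seqs = read_fasta(paths["fasta"])
        hits = 0
        for rec in truth:
            tseq = transcript_seq(rec, seqs[rec.gene_id])
            hits += CORE_PAS in tseq[rec.proximal_offset - 100:rec.proximal_offset]
        frac = hits / len(truth)
        # 0.4 plus ~2% background incidence, +/- 3 binomial SDs at n=1000
        assert abs(frac - 0.414) < 3 * np.sqrt(0.4 * 0.6 / 1000) + 0.01

    def test_empty_truth_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            a.write_annotation_and_sequence([], SimConfig(), tmp_path)


class TestCoverageModel:
    def _noiseless_cfg(self, **kw):
        base = dict(n_genes=6, utr_length_range=(800, 1200),
                    conditions=("naive", "stim"), noise_model="none",
                    replicate_pdui_sd=0.0, n_replicates=1, seed=8)
        base.update(kw)
        return SimConfig(**base)

    def test_single_isoform_limits(self, tmp_path):
        """PDUI 100 -> flat coverage; PDUI 0 -> step to zero at the
        proximal site."""
        cfg = self._noiseless_cfg(frac_shortened=0, frac_lengthened=0)
        truth = a.generate_truth(cfg)
        for rec in truth[:2]:
            rec.true_pdui["naive"] = 100.0
        for rec in truth[2:4]:
            rec.true_pdui["naive"] = 0.0
        a.write_annotation_and_sequence(truth, cfg, tmp_path)
        paths = a.simulate_coverage(truth, cfg, tmp_path)
        ann = a.read_utr_bed(tmp_path / "utr.bed")
        tracks = a.load_coverage(paths["naive_1"], ann)
        for rec in truth[:2]:
            d = tracks[rec.gene_id].depth
            assert np.allclose(d, d[0]) and d[0] > 0
        for rec in truth[2:4]:
            d = tracks[rec.gene_id].depth
            assert np.allclose(d[:rec.proximal_offset], d[0]) and d[0] > 0
            assert np.all(d[rec.proximal_offset:] == 0.0)

    def test_noiseless_segment_ratio_equals_pdui(self, tmp_path):
        """Downstream/upstream mean coverage = true_pdui / 100 exactly."""
        cfg = self._noiseless_cfg(frac_shortened=0.5, frac_lengthened=0.2)
        truth = a.generate_truth(cfg)
        truth[0].true_pdui["naive"] = 40.0
        a.write_annotation_and_sequence(truth, cfg, tmp_path)
        paths = a.simulate_coverage(truth, cfg, tmp_path)
        ann = a.read_utr_bed(tmp_path / "utr.bed")
        tracks = a.load_coverage(paths["naive_1"], ann)
        for rec in truth:
            d = tracks[rec.gene_id].depth
            up = d[:rec.proximal_offset].mean()
            down = d[rec.proximal_offset:].mean()
            assert abs(down / up - rec.true_pdui["naive"] / 100.0) < 1e-9

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimConfig(n_genes=8, seed=9, conditions=("naive", "stim"),
                        n_replicates=2)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        a.simulate_dataset(cfg, d1)
        a.simulate_dataset(cfg, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_minus_strand_written_in_genomic_orientation(self, tmp_path):
        """A minus-strand PDUI-0 gene steps up (not down) along genomic
        coordinates, and load_coverage flips it back."""
        cfg = self._noiseless_cfg(n_genes=12, frac_shortened=0,
                                  frac_lengthened=0)
        truth = a.generate_truth(cfg)
        minus = next(r for r in truth if r.strand == "-")
        minus.true_pdui["naive"] = 0.0
        a.write_annotation_and_sequence(truth, cfg, tmp_path)
        paths = a.simulate_coverage(truth, cfg, tmp_path)
        ann = {x.gene_id: x for x in a.read_utr_bed(tmp_path / "utr.bed")}[minus.gene_id]
        raw = np.zeros(ann.length)
        for line in open(paths["naive_1"]):
            chrom, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if s >= ann.start and e <= ann.end:
                raw[s - ann.start:e - ann.start] = float(v)
        # genomic orientation: zero depth at the low-coordinate end
        assert raw[0] == 0.0 and raw[-1] > 0
        track = a.load_coverage(paths["naive_1"], [ann])[minus.gene_id]
        assert track.depth[0] > 0 and track.depth[-1] == 0.0
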