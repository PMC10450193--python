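"""Generative model: determinism, truth invariants, read termination
fractions, coverage closed forms, and dataset round trips."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from opterm.genome_io import read_sites
from opterm.pipeline import load_dataset
from opterm.simulate import (
    OperonTruth,
    SimulationConfig,
    SimulationTruth,
    TerminatorTruth,
    simulate_architecture,
    simulate_coverage,
    simulate_dataset,
    simulate_reads,
    truth_table,
    write_dataset,
    _expected_abundances,
)
from opterm.genome_io import Gene

from conftest import make_config


def dir_digest(root: Path) -> dict:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.iterdir()) if p.is_file()}


class TestArchitecture:
    def test_type_i_only_truth_has_no_internal_sites(self):
        config = make_config(n_operons_by_type={"I": 4})
        truth = simulate_architecture(config)
        assert truth.terminators == []
        assert all(not op.iotss for op in truth.operons)

    def test_fixed_seed_is_byte_reproducible(self, tmp_path):
        config = make_config(noise="poisson", end_jitter_sd=2.0)
        for d in ("a", "b"):
            truth, evidence = simulate_dataset(config)
            write_dataset(truth, evidence, tmp_path / d)
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_downstream_expected_abundance_is_one_minus_eps(self):
        config = make_config(n_operons_by_type={"II": 1}, epsilon=(0.5, 0.5))
        truth = simulate_architecture(config)
        term = truth.terminators[0]
        ab = truth.expected_abundance.set_index(["gene", "condition"])
        up = ab.loc[(term.upstream_gene, "wt"), "expected_abundance"]
        down = ab.loc[(term.downstream_gene, "wt"), "expected_abundance"]
        assert down == pytest.approx(0.5 * up)

    def test_polyu_tract_embedded_on_coding_strand(self):
        config = make_config(n_operons_by_type={"II": 4})
        truth = simulate_architecture(config)
        seq = truth.sequences[config.contig]
        for term in truth.terminators:
            p = term.position
            if term.strand == "+":
                assert seq[p - 7:p + 1] == "T" * 8
            else:
                assert seq[p:p + 8] == "A" * 8

    def test_operons_do_not_overlap(self):
        truth = simulate_architecture(make_config())
        spans = sorted(op.span for op in truth.operons)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            assert a_hi <= b_lo


class TestReads:
    def test_eps_one_every_crossing_read_ends_at_terminator(self):
        config = make_config(n_operons_by_type={"II": 1},
                             epsilon=(1.0, 1.0), depletion_condition=None)
        truth = simulate_architecture(config)
        term = truth.terminators[0]
        reads = simulate_reads(truth, config, "wt")
        for r in reads:
            # a read either ends at the terminator or never reaches it
            if r.start <= term.position < r.end:
                assert r.three_prime == term.position

    def test_eps_zero_no_read_ends_at_internal_site(self):
        config = make_config(n_operons_by_type={"II": 1}, epsilon=(0.0, 0.0),
                             read_depth=100, noise="poisson",
                             depletion_condition=None)
        truth = simulate_architecture(config)
        term = truth.terminators[0]
        reads = simulate_reads(truth, config, "wt")
        assert reads
        assert not any(r.three_prime == term.position for r in reads)

    def test_termination_fraction_matches_binomial_expectation(self):
        # eps=0.5 at depth 10000: observed fraction within 3 binomial sd
        config = make_config(n_operons_by_type={"II": 1}, epsilon=(0.5, 0.5),
                             read_depth=10_000, noise="poisson",
                             depletion_condition=None, seed=11)
        truth = simulate_architecture(config)
        term = truth.terminators[0]
        reads = simulate_reads(truth, config, "wt")
        crossing = [r for r in reads
                    if min(r.five_prime, r.three_prime) <= term.position
                    and max(r.five_prime, r.three_prime) >= term.position]
        ended = sum(1 for r in crossing if r.three_prime == term.position)
        frac = ended / len(crossing)
        assert abs(frac - 0.5) <= 3 * 0.5 / np.sqrt(len(crossing))

    def test_depletion_scales_termination_fraction(self):
        config = make_config(n_operons_by_type={"II": 1}, epsilon=(0.8, 0.8),
                             depletion_factor=0.5, read_depth=20_000,
                             noise="poisson", seed=5)
        truth = simulate_architecture(config)
        term = truth.terminators[0]
        fracs = {}
        for cond in ("wt", "depleted"):
            reads = simulate_reads(truth, config, cond)
            crossing = [r for r in reads if r.start <= term.position < r.end]
            ended = sum(1 for r in crossing if r.three_prime == term.position)
            fracs[cond] = ended / len(crossing)
        assert fracs["wt"] == pytest.approx(0.8, abs=0.01)
        assert fracs["depleted"] == pytest.approx(0.4, abs=0.015)


def manual_truth(epsilons, gene_len=200, igr=50, depth=100.0):
    """A hand-built operon with stacked internal terminators."""
    config = SimulationConfig(
        n_operons_by_type={"II": 1}, noise="none", coverage_depth=depth,
        n_replicates=1, depletion_condition=None)
    n_genes = len(epsilons) + 1
    genes, pos = [], 30
    gaps = []
    for i in range(n_genes):
        genes.append(Gene("chr1", pos, pos + gene_len, "+", f"g{i}"))
        pos += gene_len
        if i < n_genes - 1:
            gaps.append(pos + igr // 2)
            pos += igr
    op = OperonTruth("op0", "chr1", "+", 0, pos + 30 - 1, "II", genes,
                     terminal_tte=1.0, promoter_weight=1.0)
    for j, eps in enumerate(epsilons):
        op.iotts.append(TerminatorTruth(
            "op0", "chr1", "+", gaps[j], j, {"wt": eps}, 8,
            genes[j].locus_tag, genes[j + 1].locus_tag))
    truth = SimulationTruth(config, {"chr1": "A" * (pos + 60)}, [op], None)
    truth.expected_abundance = _expected_abundances(truth)
    return truth, config


class TestCoverage:
    def test_single_terminator_closed_form(self):
        truth, config = manual_truth([0.75])
        track = [t for t in simulate_coverage(truth, config, "wt", "rep0")
                 if t.strand == "+"][0]
        g0, g1 = truth.operons[0].genes[:2]
        up = track.values[g0.start:g0.end].mean()
        down = track.values[g1.start:g1.end].mean()
        assert up == pytest.approx(100.0)
        assert down == pytest.approx(0.25 * up)

    def test_stacked_terminators_multiply_read_through(self):
        # product rule: two eps=0.5 terminators leave the third gene at
        # 0.25 x the first gene's coverage
        truth, config = manual_truth([0.5, 0.5])
        track = [t for t in simulate_coverage(truth, config, "wt", "rep0")
                 if t.strand == "+"][0]
        genes = truth.operons[0].genes
        first = track.values[genes[0].start:genes[0].end].mean()
        third = track.values[genes[2].start:genes[2].end].mean()
        assert third == pytest.approx(0.25 * first)

    def test_poisson_gene_mean_close_to_expectation(self):
        truth, config = manual_truth([0.5], gene_len=1000)
        config.noise = "poisson"
        track = [t for t in simulate_coverage(truth, config, "wt", "rep0")
                 if t.strand == "+"][0]
        g0 = truth.operons[0].genes[0]
        mean = track.values[g0.start:g0.end].mean()
        assert abs(mean - 100.0) <= 3 * np.sqrt(100.0 / 1000)


class TestDataset:
    def test_manifest_counts_bedgraphs(self, tmp_path):
        config = make_config(n_replicates=2)  # 2 conditions built in
        truth, evidence = simulate_dataset(config)
        manifest = write_dataset(truth, evidence, tmp_path)
        bedgraphs = [f for f in manifest["files"] if f["role"] == "coverage"]
        assert len(bedgraphs) == 2 * 2 * 2  # conditions x replicates x strands

    def test_truth_tsv_one_row_per_terminator(self, noise_free_dataset):
        truth, _ = noise_free_dataset
        assert len(truth_table(truth)) == len(truth.terminators)

    def test_reloaded_sites_match_simulated_positions(self, tmp_path,
                                                      noise_free_dataset):
        truth, evidence = noise_free_dataset
        write_dataset(truth, evidence, tmp_path)
        data = load_dataset(tmp_path)
        for cond in ("wt", "depleted"):
            orig = [(s.position, s.strand, s.count) for s in evidence.tts[cond]]
            back = [(s.position, s.strand, s.count) for s in data.tts[cond]]
            assert back == orig

    def test_config_validation(self):
        with pytest.raises(ValueError, match="epsilon"):
            SimulationConfig(epsilon=(0.5, 1.5))
        with pytest.raises(ValueError, match="depletion_factor"):
            SimulationConfig(depletion_factor=0.0)
        with pytest.raises(ValueError, match="noise"):
            SimulationConfig(noise="gaussian")
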