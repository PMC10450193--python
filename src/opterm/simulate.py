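"""Synthetic multi-evidence transcriptome generator with known ground truth.

Emulates the data model of a single-contig archaeal transcriptome mapped
by four evidence layers: full-length transcript reads, single-base TSS
and TTS sites with read-count scores, and strand-specific per-base
coverage.  Operons of the four architectural types are placed on
alternating strands:

* Type I   — no internal sites;
* Type II  — one internal terminator (ioTTS) with an embedded polyU
  tract, at which each elongating transcript terminates with
  per-terminator efficiency ``eps``;
* Type III — one internal promoter (ioTSS);
* Type IV  — both (the ioTTS upstream of the ioTSS, in distinct
  intergenic regions, so the termination statistics of the ioTTS are
  not confounded by re-initiation).

A "depletion" condition rescales every internal-terminator efficiency
by a factor ``f``, emulating depletion of a general termination factor.
Expected per-base coverage inside an operon is the promoter depth
multiplied by the cumulative read-through product ``prod(1 - eps)`` over
all upstream internal terminators, plus ioTSS contributions; realized
coverage is Poisson around that expectation (or exact for
``noise="none"``).  Reads that fail to terminate at the operon-end
terminator are discarded rather than extended into neighbouring loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from opterm.genome_io import (
    CoverageTrack,
    FullLengthRead,
    Gene,
    SiteRecord,
    write_annotation,
    write_coverage,
    write_genome,
    write_reads,
    write_sites,
)

OPERON_TYPES = ("I", "II", "III", "IV")

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the generative model; defaults are the stated world.

    Ranges are (low, high) tuples; a degenerate range (x, x) fixes the
    value.  ``epsilon`` spans the 30-80% terminator-strength band
    observed genome-wide; ``depletion_factor`` rescales every internal
    epsilon in the depletion condition.
    """

    seed: int = 0
    n_operons_by_type: dict = field(
        default_factory=lambda: {"I": 10, "II": 10, "III": 10, "IV": 10}
    )
    genes_per_operon: tuple = (2, 5)
    gene_length: tuple = (500, 1500)
    igr_length: tuple = (60, 120)
    utr5_length: tuple = (20, 50)
    utr3_length: tuple = (20, 60)
    operon_spacing: tuple = (200, 400)
    promoter_strength: tuple = (0.5, 2.0)
    epsilon: tuple = (0.3, 0.8)
    terminal_tte: tuple = (0.6, 0.9)
    depletion_factor: float = 0.5
    read_depth: float = 50.0
    coverage_depth: float = 100.0
    n_replicates: int = 3
    end_jitter_sd: float = 0.0
    noise: str = "poisson"
    polyu_length: int = 8
    contig: str = "chr1"
    reference_condition: str = "wt"
    depletion_condition: str | None = "depleted"

    def __post_init__(self) -> None:
        lo, hi = self.epsilon
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"epsilon range {self.epsilon} not within [0, 1]")
        if not (0.0 < self.depletion_factor <= 1.0):
            raise ValueError(f"depletion_factor {self.depletion_factor} not in (0, 1]")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        for name in ("genes_per_operon", "gene_length", "igr_length",
                     "utr5_length", "utr3_length", "operon_spacing",
                     "promoter_strength", "terminal_tte"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: degenerate range ({lo}, {hi})")
        unknown = set(self.n_operons_by_type) - set(OPERON_TYPES)
        if unknown:
            raise ValueError(f"unknown operon types {unknown}")

    @property
    def conditions(self) -> list[str]:
        conds = [self.reference_condition]
        if self.depletion_condition:
            conds.append(self.depletion_condition)
        return conds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)


@dataclass
class TerminatorTruth:
    """Ground truth for one internal terminator (ioTTS)."""

    operon_id: str
    contig: str
    strand: str
    position: int  # 0-based last transcribed base
    igr_index: int  # intergenic gap (strand-oriented) hosting the site
    eps_by_condition: dict
    polyu_length: int
    upstream_gene: str
    downstream_gene: str


@dataclass
class IoTssTruth:
    operon_id: str
    contig: str
    strand: str
    position: int
    igr_index: int
    weight: float  # promoter strength relative to the operon promoter


@dataclass
class OperonTruth:
    operon_id: str
    contig: str
    strand: str
    tss: int
    tts: int
    type_label: str
    genes: list  # Gene, in strand (5'->3') order
    terminal_tte: float
    promoter_weight: float
    iotts: list = field(default_factory=list)  # TerminatorTruth
    iotss: list = field(default_factory=list)  # IoTssTruth

    @property
    def span(self) -> tuple[int, int]:
        lo = min(self.tss, self.tts)
        return lo, max(self.tss, self.tts) + 1


@dataclass
class SimulationTruth:
    """Full generative ground truth for one simulated dataset."""

    config: SimulationConfig
    sequences: dict  # contig -> str
    operons: list  # OperonTruth
    expected_abundance: pd.DataFrame  # gene x condition expected mean coverage

    @property
    def genes(self) -> list[Gene]:
        out = []
        for op in self.operons:
            out.extend(op.genes)
        return sorted(out, key=lambda g: (g.contig, g.start))

    @property
    def terminators(self) -> list[TerminatorTruth]:
        return [t for op in self.operons for t in op.iotts]


def _draw_int(rng, lohi) -> int:
    lo, hi = lohi
    return int(lo) if lo == hi else int(rng.integers(int(lo), int(hi) + 1))


def _draw_float(rng, lohi) -> float:
    lo, hi = lohi
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# Architecture


def simulate_architecture(config: SimulationConfig) -> SimulationTruth:
    """Lay out operons on a random genome and derive expected abundances.

    Operons are placed left to right with inter-operon spacing, strands
    alternating.  Internal terminators receive a polyU tract (T-run on
    the coding strand) ending at the ioTTS base.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    type_sequence = [t for t in OPERON_TYPES
                     for _ in range(int(config.n_operons_by_type.get(t, 0)))]
    order = rng.permutation(len(type_sequence))
    type_sequence = [type_sequence[i] for i in order]

    operons: list[OperonTruth] = []
    cursor = _draw_int(rng, config.operon_spacing)
    for idx, type_label in enumerate(type_sequence):
        strand = "+" if idx % 2 == 0 else "-"
        op = _build_operon(rng, config, f"op{idx:04d}", type_label, strand, cursor)
        operons.append(op)
        cursor = op.span[1] + _draw_int(rng, config.operon_spacing)

    genome_len = cursor + _draw_int(rng, config.operon_spacing)
    seq = rng.choice(_BASES, size=genome_len)
    for op in operons:
        for term in op.iotts:
            _embed_polyu(seq, term, config.polyu_length)
    sequences = {config.contig: "".join(seq)}

    truth = SimulationTruth(config, sequences, operons, pd.DataFrame())
    truth.expected_abundance = _expected_abundances(truth)
    return truth


def _build_operon(rng, config, operon_id, type_label, strand, cursor) -> OperonTruth:
    min_genes = 3 if type_label == "IV" else 2
    lo, hi = config.genes_per_operon
    n_genes = _draw_int(rng, (max(int(lo), min_genes), max(int(hi), min_genes)))
    gene_lens = [_draw_int(rng, config.gene_length) for _ in range(n_genes)]
    igr_lens = [_draw_int(rng, config.igr_length) for _ in range(n_genes - 1)]
    utr5 = _draw_int(rng, config.utr5_length)
    utr3 = _draw_int(rng, config.utr3_length)

    # oriented layout: 0 = TSS base; genes 5'->3'
    pos = utr5
    gene_spans = []
    for i, glen in enumerate(gene_lens):
        gene_spans.append((pos, pos + glen))
        pos += glen
        if i < n_genes - 1:
            pos += igr_lens[i]
    length = pos + utr3  # TTS base at length - 1

    def to_genomic_point(p: int) -> int:
        return cursor + p if strand == "+" else cursor + (length - 1 - p)

    def to_genomic_span(a: int, b: int) -> tuple[int, int]:
        return (cursor + a, cursor + b) if strand == "+" else (
            cursor + length - b, cursor + length - a)

    genes = []
    for i, (a, b) in enumerate(gene_spans):
        gs, ge = to_genomic_span(a, b)
        genes.append(Gene(config.contig, gs, ge, strand, f"{operon_id}_g{i}"))

    op = OperonTruth(
        operon_id=operon_id,
        contig=config.contig,
        strand=strand,
        tss=to_genomic_point(0),
        tts=to_genomic_point(length - 1),
        type_label=type_label,
        genes=genes,
        terminal_tte=_draw_float(rng, config.terminal_tte),
        promoter_weight=_draw_float(rng, config.promoter_strength),
    )

    def igr_midpoint(j: int) -> int:
        a = gene_spans[j][1]
        b = gene_spans[j + 1][0]
        return (a + b) // 2

    eps = _draw_float(rng, config.epsilon)
    if type_label in ("II", "IV"):
        j = 0
        eps_by_cond = {config.reference_condition: eps}
        if config.depletion_condition:
            eps_by_cond[config.depletion_condition] = config.depletion_factor * eps
        op.iotts.append(TerminatorTruth(
            operon_id=operon_id,
            contig=config.contig,
            strand=strand,
            position=to_genomic_point(igr_midpoint(j)),
            igr_index=j,
            eps_by_condition=eps_by_cond,
            polyu_length=config.polyu_length,
            upstream_gene=genes[j].locus_tag,
            downstream_gene=genes[j + 1].locus_tag,
        ))
    if type_label in ("III", "IV"):
        # Type IV: ioTSS in the second gap so it sits downstream of the
        # ioTTS's downstream gene and cannot confound its TDER
        j = 1 if type_label == "IV" else 0
        q = igr_midpoint(j)
        op.iotss.append(IoTssTruth(
            operon_id=operon_id,
            contig=config.contig,
            strand=strand,
            position=to_genomic_point(q),
            igr_index=j,
            weight=_draw_float(rng, config.promoter_strength),
        ))
    return op


def _embed_polyu(seq: np.ndarray, term: TerminatorTruth, polyu_length: int) -> None:
    """Write a T-run on the coding strand ending at the TTS base."""
    p = term.position
    if term.strand == "+":
        seq[p - polyu_length + 1 : p + 1] = "T"
    else:
        # coding strand is '-', so the tract appears as an A-run on '+'
        seq[p : p + polyu_length] = "A"


# ---------------------------------------------------------------------------
# Expected coverage model


def _oriented_events(op: OperonTruth, config: SimulationConfig, condition: str):
    """Per-operon transcription events in strand-oriented coordinates.

    Returns (length, promoters, terminators): promoters as (pos, depth
    scale), internal terminators as (pos, eps) sorted 5'->3'.
    """
    lo, hi = op.span
    length = hi - lo

    def orient(p: int) -> int:
        return p - lo if op.strand == "+" else (hi - 1) - p

    promoters = [(0, 1.0)]
    for s in op.iotss:
        promoters.append((orient(s.position), s.weight / op.promoter_weight))
    terminators = sorted(
        (orient(t.position), t.eps_by_condition[condition]) for t in op.iotts
    )
    return length, sorted(promoters), terminators


def _expected_operon_coverage(op, config, condition) -> np.ndarray:
    """Expected per-base coverage over the operon span, oriented 5'->3'."""
    length, promoters, terminators = _oriented_events(op, config, condition)
    cov = np.zeros(length)
    for pos, scale in promoters:
        cov[pos:] += config.coverage_depth * scale
    for pos, eps in terminators:
        cov[pos + 1:] *= (1.0 - eps)
    return cov


def _expected_abundances(truth: SimulationTruth) -> pd.DataFrame:
    config = truth.config
    rows = []
    for op in truth.operons:
        lo, hi = op.span
        for condition in config.conditions:
            cov = _expected_operon_coverage(op, config, condition)
            for gene in op.genes:
                a = gene.start - lo if op.strand == "+" else (hi - 1) - (gene.end - 1)
                b = a + gene.length
                rows.append({
                    "gene": gene.locus_tag,
                    "operon_id": op.operon_id,
                    "condition": condition,
                    "expected_abundance": float(cov[a:b].mean()),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(
    truth: SimulationTruth, config: SimulationConfig, condition: str
) -> list[FullLengthRead]:
    """Simulate full-length transcript reads for one condition.

    Each transcript starts at the operon TSS (or an ioTSS, with its own
    strength) and terminates at each internal terminator it crosses with
    probability eps, else reads through; survivors terminate at the
    operon-end terminator with probability ``terminal_tte`` and are
    otherwise discarded.  Read ends are jittered by rounded Gaussian
    noise truncated to the contig.
    """
    cond_idx = config.conditions.index(condition)
    rng = np.random.default_rng([int(config.seed), 1, cond_idx])
    reads: list[FullLengthRead] = []
    contig_len = len(truth.sequences[config.contig])

    for op in truth.operons:
        lo, hi = op.span
        length, promoters, terminators = _oriented_events(op, config, condition)
        counter = 0
        for start_pos, scale in promoters:
            expected = config.read_depth * scale
            if config.noise == "poisson":
                n = int(rng.poisson(expected))
            else:
                n = int(round(expected))
            downstream = [(p, e) for p, e in terminators if p > start_pos]
            downstream.append((length - 1, op.terminal_tte))
            end_positions: list[tuple[int, int]] = []  # (oriented end, count)
            survivors = n
            for tpos, teps in downstream:
                if survivors <= 0:
                    break
                if config.noise == "poisson":
                    k = int(rng.binomial(survivors, teps))
                else:
                    k = int(round(survivors * teps))
                if k > 0:
                    end_positions.append((tpos, k))
                survivors -= k
            # survivors past the operon-end terminator are run-on
            # molecules: they end a short distance into the downstream
            # spacer (kept well below the inter-operon spacing)
            for _ in range(survivors):
                end_positions.append((length - 1 + int(rng.integers(20, 101)), 1))
            for end_pos, k in end_positions:
                for _ in range(k):
                    s, e = start_pos, end_pos
                    if config.end_jitter_sd > 0:
                        s += int(round(rng.normal(0, config.end_jitter_sd)))
                        e += int(round(rng.normal(0, config.end_jitter_sd)))
                    e = max(s + 1, e)
                    if op.strand == "+":
                        g0, g1 = lo + s, lo + e + 1
                    else:
                        g0, g1 = (hi - 1) - e, (hi - 1) - s + 1
                    g0 = max(0, g0)
                    g1 = min(contig_len, g1)
                    reads.append(FullLengthRead(
                        config.contig, g0, g1, op.strand,
                        f"{op.operon_id}_{condition}_r{counter}"))
                    counter += 1
    return reads


def sites_from_reads(
    reads: Sequence[FullLengthRead], condition: str
) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Aggregate read 5'/3' ends into TSS/TTS site records with counts."""
    tss_counts: dict[tuple, int] = {}
    tts_counts: dict[tuple, int] = {}
    for r in reads:
        k5 = (r.contig, r.five_prime, r.strand)
        k3 = (r.contig, r.three_prime, r.strand)
        tss_counts[k5] = tss_counts.get(k5, 0) + 1
        tts_counts[k3] = tts_counts.get(k3, 0) + 1
    tss = [SiteRecord(c, p, s, "TSS", n, condition)
           for (c, p, s), n in sorted(tss_counts.items())]
    tts = [SiteRecord(c, p, s, "TTS", n, condition)
           for (c, p, s), n in sorted(tts_counts.items())]
    return tss, tts


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    truth: SimulationTruth,
    config: SimulationConfig,
    condition: str,
    replicate: str,
) -> list[CoverageTrack]:
    """Simulate strand-specific per-base coverage for one replicate."""
    cond_idx = config.conditions.index(condition)
    rep_idx = int(replicate.lstrip("rep") or 0)
    contig_len = len(truth.sequences[config.contig])
    expected = {s: np.zeros(contig_len) for s in ("+", "-")}
    for op in truth.operons:
        lo, hi = op.span
        cov = _expected_operon_coverage(op, config, condition)
        if op.strand == "+":
            expected["+"][lo:hi] += cov
        else:
            expected["-"][lo:hi] += cov[::-1]
    tracks = []
    for strand_idx, strand in enumerate(("+", "-")):
        if config.noise == "poisson":
            rng = np.random.default_rng(
                [int(config.seed), 2, cond_idx, rep_idx, strand_idx])
            values = rng.poisson(expected[strand]).astype(float)
        else:
            values = expected[strand]
        tracks.append(CoverageTrack(config.contig, strand, condition, replicate, values))
    return tracks


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class EvidenceSet:
    """All simulated evidence layers, keyed by condition/replicate."""

    reads: dict  # condition -> list[FullLengthRead]
    tss: dict  # condition -> list[SiteRecord]
    tts: dict  # condition -> list[SiteRecord]
    coverage: dict  # (condition, replicate) -> list[CoverageTrack]


def simulate_dataset(config: SimulationConfig) -> tuple[SimulationTruth, EvidenceSet]:
    """Run the full generative model: architecture, reads, sites, coverage."""
    truth = simulate_architecture(config)
    reads, tss, tts, coverage = {}, {}, {}, {}
    for condition in config.conditions:
        reads[condition] = simulate_reads(truth, config, condition)
        tss[condition], tts[condition] = sites_from_reads(reads[condition], condition)
        for rep in range(config.n_replicates):
            replicate = f"rep{rep}"
            coverage[(condition, replicate)] = simulate_coverage(
                truth, config, condition, replicate)
    return truth, EvidenceSet(reads, tss, tts, coverage)


def truth_table(truth: SimulationTruth) -> pd.DataFrame:
    """One row per simulated internal terminator."""
    config = truth.config
    rows = []
    for term in truth.terminators:
        row = {
            "operon_id": term.operon_id,
            "contig": term.contig,
            "strand": term.strand,
            "position": term.position,
            "igr_index": term.igr_index,
            "polyu_length": term.polyu_length,
            "upstream_gene": term.upstream_gene,
            "downstream_gene": term.downstream_gene,
        }
        for condition in config.conditions:
            row[f"epsilon_{condition}"] = term.eps_by_condition[condition]
        rows.append(row)
    return pd.DataFrame(rows)


def operon_table(truth: SimulationTruth) -> pd.DataFrame:
    rows = []
    for op in truth.operons:
        rows.append({
            "operon_id": op.operon_id,
            "contig": op.contig,
            "strand": op.strand,
            "tss": op.tss,
            "tts": op.tts,
            "type": op.type_label,
            "n_genes": len(op.genes),
            "genes": ",".join(g.locus_tag for g in op.genes),
            "n_iotss": len(op.iotss),
            "n_iotts": len(op.iotts),
            "terminal_tte": op.terminal_tte,
        })
    return pd.DataFrame(rows)


def write_dataset(
    truth: SimulationTruth, evidence: EvidenceSet, out_dir: str | Path
) -> dict:
    """Write every evidence layer plus truth tables; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = truth.config
    manifest: dict = {"seed": config.seed, "contig": config.contig,
                      "conditions": config.conditions,
                      "n_replicates": config.n_replicates, "files": []}

    def register(path: Path, role: str, **tags) -> None:
        manifest["files"].append({"path": path.name, "role": role, **tags})

    genome_path = out / "genome.fasta"
    write_genome(truth.sequences, genome_path)
    register(genome_path, "genome")

    gff_path = out / "genes.gff3"
    write_annotation(truth.genes, gff_path)
    register(gff_path, "annotation")

    for condition in config.conditions:
        for kind, sites in (("tss", evidence.tss[condition]),
                            ("tts", evidence.tts[condition])):
            path = out / f"{kind}_{condition}.bed"
            write_sites(sites, path)
            register(path, kind, condition=condition)
        path = out / f"reads_{condition}.bed"
        write_reads(evidence.reads[condition], path)
        register(path, "reads", condition=condition)
        for rep in range(config.n_replicates):
            replicate = f"rep{rep}"
            for track in evidence.coverage[(condition, replicate)]:
                tag = "fwd" if track.strand == "+" else "rev"
                path = out / f"coverage_{condition}_{replicate}_{tag}.bedgraph"
                write_coverage(track, path)
                register(path, "coverage", condition=condition,
                         replicate=replicate, strand=track.strand)

    truth_path = out / "truth_terminators.tsv"
    truth_table(truth).to_csv(truth_path, sep="\t", index=False)
    register(truth_path, "truth_terminators")

    op_path = out / "truth_operons.tsv"
    operon_table(truth).to_csv(op_path, sep="\t", index=False)
    register(op_path, "truth_operons")

    ab_path = out / "truth_abundance.tsv"
    truth.expected_abundance.to_csv(ab_path, sep="\t", index=False)
    register(ab_path, "truth_abundance")

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
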