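"""Transcription-unit assembly, operon calling and type classification.

A transcription unit (TU) is a same-strand (TSS, TTS) pair supported by
at least ``min_read_support`` full-length reads whose strand-oriented
5' end falls within ``delta5`` nt of the TSS and 3' end within
``delta3`` nt of the TTS.  TUs sharing genes are grouped; the TU with
the most genes defines the operon extent; TSS/TTS sites strictly inside
that extent and located in an intergenic gap between consecutive operon
genes become internal sites (ioTSS/ioTTS), which drive the four-type
classification:

    Type I: no internal sites; Type II: >=1 ioTTS; Type III: >=1 ioTSS;
    Type IV: both.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from opterm.genome_io import FullLengthRead, Gene, SiteRecord

logger = logging.getLogger(__name__)


@dataclass
class CallerParams:
    """End-matching tolerances and read-support threshold for TU calling."""

    delta5: int = 20
    delta3: int = 50
    min_read_support: int = 1

    def __post_init__(self) -> None:
        if self.delta5 < 0 or self.delta3 < 0 or self.min_read_support < 1:
            raise ValueError("caller parameters must be positive")


@dataclass
class TranscriptionUnit:
    """A read-supported (TSS, TTS) pair and the genes it fully contains."""

    contig: str
    strand: str
    tss: SiteRecord
    tts: SiteRecord
    gene_list: list  # Gene, 5'->3' on the strand
    supporting_reads: int

    @property
    def span(self) -> tuple[int, int]:
        """Genomic half-open interval covered by the TU."""
        lo = min(self.tss.position, self.tts.position)
        hi = max(self.tss.position, self.tts.position) + 1
        return lo, hi

    @property
    def span_length(self) -> int:
        lo, hi = self.span
        return hi - lo


@dataclass
class Operon:
    """A maximal multi-gene transcription unit with its internal sites."""

    operon_id: str
    contig: str
    strand: str
    tss: SiteRecord
    tts: SiteRecord
    genes: list  # Gene, 5'->3' on the strand
    supporting_reads: int
    internal_tss: list = field(default_factory=list)
    internal_tts: list = field(default_factory=list)
    type_label: str = "I"
    boundary_confirmed: bool = True

    @property
    def span(self) -> tuple[int, int]:
        lo = min(self.tss.position, self.tts.position)
        hi = max(self.tss.position, self.tts.position) + 1
        return lo, hi

    @property
    def span_length(self) -> int:
        lo, hi = self.span
        return hi - lo


def _dedupe_sites(sites: Iterable[SiteRecord]) -> list[SiteRecord]:
    """Union sites across conditions: sum counts per (contig, pos, strand)."""
    merged: dict[tuple, SiteRecord] = {}
    for s in sites:
        key = (s.contig, s.position, s.strand, s.kind)
        if key in merged:
            prev = merged[key]
            merged[key] = SiteRecord(s.contig, s.position, s.strand, s.kind,
                                     prev.count + s.count, "union")
        else:
            merged[key] = SiteRecord(s.contig, s.position, s.strand, s.kind,
                                     s.count, "union")
    return [merged[k] for k in sorted(merged)]


def build_transcription_units(
    genes: Sequence[Gene],
    tss_list: Sequence[SiteRecord],
    tts_list: Sequence[SiteRecord],
    reads: Sequence[FullLengthRead],
    params: CallerParams | None = None,
) -> list[TranscriptionUnit]:
    """Assemble TUs from site and full-length-read evidence.

    Sites are unioned across conditions before pairing.  A TU requires
    >= ``min_read_support`` reads matching both ends; TUs containing no
    fully-covered gene are discarded.  Mis-stranded sites are skipped
    with a logged warning rather than raising.
    """
    params = params or CallerParams()
    tss_u = _dedupe_sites(tss_list)
    tts_u = _dedupe_sites(tts_list)
    for s in tss_u + tts_u:
        if s.kind not in ("TSS", "TTS"):  # pragma: no cover - defensive
            logger.warning("skipping site with unknown kind %r", s.kind)

    # index sites by (contig, strand) with sorted position arrays
    def index(sites):
        idx: dict[tuple, list[SiteRecord]] = {}
        for s in sites:
            idx.setdefault((s.contig, s.strand), []).append(s)
        return {k: sorted(v, key=lambda s: s.position) for k, v in idx.items()}

    tss_idx = index(tss_u)
    tts_idx = index(tts_u)

    support: dict[tuple, int] = {}
    for read in reads:
        key = (read.contig, read.strand)
        near5 = _sites_near(tss_idx.get(key, []), read.five_prime, params.delta5)
        near3 = _sites_near(tts_idx.get(key, []), read.three_prime, params.delta3)
        for tss in near5:
            for tts in near3:
                if read.strand == "+" and tss.position >= tts.position:
                    continue
                if read.strand == "-" and tss.position <= tts.position:
                    continue
                pair = (read.contig, read.strand, tss.position, tts.position)
                support[pair] = support.get(pair, 0) + 1

    site_by_pos = {("TSS", s.contig, s.strand, s.position): s for s in tss_u}
    site_by_pos.update({("TTS", s.contig, s.strand, s.position): s for s in tts_u})

    gene_idx: dict[tuple, list[Gene]] = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        gene_idx.setdefault((g.contig, g.strand), []).append(g)

    tus: list[TranscriptionUnit] = []
    for (contig, strand, tss_pos, tts_pos), n in sorted(support.items()):
        if n < params.min_read_support:
            continue
        tss = site_by_pos[("TSS", contig, strand, tss_pos)]
        tts = site_by_pos[("TTS", contig, strand, tts_pos)]
        lo = min(tss_pos, tts_pos)
        hi = max(tss_pos, tts_pos) + 1
        contained = [g for g in gene_idx.get((contig, strand), [])
                     if g.start >= lo and g.end <= hi]
        if not contained:
            continue
        if strand == "-":
            contained = contained[::-1]
        tus.append(TranscriptionUnit(contig, strand, tss, tts, contained, n))
    tus.sort(key=lambda t: (t.contig, t.span[0], t.span[1], t.strand))
    return tus


def _sites_near(sorted_sites: list[SiteRecord], pos: int, delta: int) -> list[SiteRecord]:
    positions = [s.position for s in sorted_sites]
    lo = bisect_left(positions, pos - delta)
    hi = bisect_right(positions, pos + delta)
    return sorted_sites[lo:hi]


def call_operons(
    tus: Sequence[TranscriptionUnit],
    tss_list: Sequence[SiteRecord],
    tts_list: Sequence[SiteRecord],
    genes: Sequence[Gene],
) -> tuple[list[Operon], list[TranscriptionUnit]]:
    """Group TUs into operons and detect internal (ioTSS/ioTTS) sites.

    Returns ``(operons, single_gene_tus)``.  TUs sharing any gene are
    grouped; within a group the TU with the most genes (ties: longest
    span, then leftmost) defines the operon extent.  Groups whose
    defining TU covers a single gene are reported as single-gene TUs.
    """
    # union-find over locus tags
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for tu in tus:
        tags = [g.locus_tag for g in tu.gene_list]
        for t in tags:
            parent.setdefault(t, t)
        for t in tags[1:]:
            union(tags[0], t)

    groups: dict[str, list[TranscriptionUnit]] = {}
    for tu in tus:
        root = find(tu.gene_list[0].locus_tag)
        groups.setdefault(root, []).append(tu)

    tss_u = _dedupe_sites(tss_list)
    tts_u = _dedupe_sites(tts_list)

    operons: list[Operon] = []
    singles: list[TranscriptionUnit] = []
    for root in sorted(groups):
        members = groups[root]
        defining = max(
            members,
            key=lambda t: (len(t.gene_list), t.span_length, -t.span[0]),
        )
        if len(defining.gene_list) < 2:
            singles.extend(members)
            continue
        op = Operon(
            operon_id="",
            contig=defining.contig,
            strand=defining.strand,
            tss=defining.tss,
            tts=defining.tts,
            genes=list(defining.gene_list),
            supporting_reads=defining.supporting_reads,
        )
        op.internal_tss = _internal_sites(op, tss_u)
        op.internal_tts = _internal_sites(op, tts_u)
        op.type_label = classify_operon_type(op)
        op.boundary_confirmed = _boundary_confirmed(op, genes, tss_u)
        operons.append(op)

    operons.sort(key=lambda o: (o.contig, o.span[0]))
    for i, op in enumerate(operons):
        op.operon_id = f"operon_{i:04d}"
    singles.sort(key=lambda t: (t.contig, t.span[0]))
    return operons, singles


def _internal_sites(op: Operon, sites: list[SiteRecord]) -> list[SiteRecord]:
    """Sites strictly inside the operon span that fall in an intergenic
    gap between consecutive operon genes."""
    lo, hi = op.span
    genomic = sorted(op.genes, key=lambda g: g.start)
    gaps = [(genomic[i].end, genomic[i + 1].start) for i in range(len(genomic) - 1)]
    out = []
    for s in sites:
        if s.contig != op.contig or s.strand != op.strand:
            continue
        if not (lo < s.position < hi - 1):
            continue
        if any(a <= s.position < b for a, b in gaps):
            out.append(s)
    return out


def _boundary_confirmed(
    op: Operon, genes: Sequence[Gene], tss_u: list[SiteRecord]
) -> bool:
    """Whether the next same-strand gene past the operon TTS has a TSS of
    its own (a confidence flag on the 3' boundary; never alters calls)."""
    lo, hi = op.span
    same = [g for g in genes if g.contig == op.contig and g.strand == op.strand]
    if op.strand == "+":
        downstream = [g for g in same if g.start >= hi]
        if not downstream:
            return True
        nxt = min(downstream, key=lambda g: g.start)
        return any(hi - 1 < s.position <= nxt.start
                   for s in tss_u
                   if s.contig == op.contig and s.strand == op.strand)
    downstream = [g for g in same if g.end <= lo]
    if not downstream:
        return True
    nxt = max(downstream, key=lambda g: g.end)
    return any(nxt.end - 1 <= s.position < lo
               for s in tss_u
               if s.contig == op.contig and s.strand == op.strand)


def classify_operon_type(operon: Operon) -> str:
    """Four-way architecture label from internal site counts."""
    has_tss = len(operon.internal_tss) > 0
    has_tts = len(operon.internal_tts) > 0
    if has_tss and has_tts:
        return "IV"
    if has_tss:
        return "III"
    if has_tts:
        return "II"
    return "I"


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero; 0 when empty."""
    if denominator == 0:
        return 0
    return round_half_away(100.0 * numerator / denominator)


def summarize_operons(
    operons: Sequence[Operon], single_gene_tus: Sequence[TranscriptionUnit]
) -> dict:
    """Summary statistics of the operon map.

    Reports TU and operon counts, per-type counts and integer-rounded
    percentages, the fraction of operons with internal sites, a
    gene-count histogram, and the median operon length in nt.
    """
    n_operons = len(operons)
    type_counts = {t: 0 for t in ("I", "II", "III", "IV")}
    for op in operons:
        type_counts[op.type_label] += 1
    n_iotss = sum(1 for op in operons if op.internal_tss)
    n_iotts = sum(1 for op in operons if op.internal_tts)
    gene_counts = pd.Series([len(op.genes) for op in operons], dtype=int)
    lengths = [op.span_length for op in operons]
    return {
        "n_tus": len(single_gene_tus) + n_operons,
        "n_single_gene_tus": len(single_gene_tus),
        "n_operons": n_operons,
        "type_counts": type_counts,
        "type_percent": {t: percent(c, n_operons) for t, c in type_counts.items()},
        "n_iotss_operons": n_iotss,
        "n_iotts_operons": n_iotts,
        "pct_iotss_operons": percent(n_iotss, n_operons),
        "pct_iotts_operons": percent(n_iotts, n_operons),
        "gene_count_histogram": gene_counts.value_counts().sort_index().to_dict(),
        "median_operon_length_nt": float(np.median(lengths)) if lengths else float("nan"),
    }


def operons_to_frame(operons: Sequence[Operon]) -> pd.DataFrame:
    """Tabular (BED12-like) view of called operons."""
    rows = []
    for op in operons:
        lo, hi = op.span
        rows.append({
            "operon_id": op.operon_id,
            "contig": op.contig,
            "start": lo,
            "end": hi,
            "strand": op.strand,
            "n_genes": len(op.genes),
            "genes": ",".join(g.locus_tag for g in op.genes),
            "type": op.type_label,
            "n_iotss": len(op.internal_tss),
            "n_iotts": len(op.internal_tts),
            "supporting_reads": op.supporting_reads,
            "boundary_confirmed": op.boundary_confirmed,
        })
    return pd.DataFrame(rows)
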