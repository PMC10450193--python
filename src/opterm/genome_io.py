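"""Domain types and readers/writers for genomic evidence files.

All internal coordinates are 0-based half-open intervals; single-base
sites (TSS/TTS) are stored as the 0-based index of the base itself.
Writers convert back to each format's native convention (GFF3 1-based
inclusive; BED/bedGraph 0-based half-open).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")
SITE_KINDS = ("TSS", "TTS")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class Gene:
    """A stranded genomic interval with a locus tag.

    ``start``/``end`` are 0-based half-open; ``strand`` is '+' or '-'.
    """

    contig: str
    start: int
    end: int
    strand: str
    locus_tag: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.locus_tag}: start {self.start} >= end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.locus_tag}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SiteRecord:
    """A single-base TSS or TTS with a supporting-read count.

    ``position`` is the 0-based index of the first (TSS) or last (TTS)
    transcribed base.  ``condition`` tags the growth condition / strain
    the evidence came from.
    """

    contig: str
    position: int
    strand: str
    kind: str
    count: int
    condition: str

    def __post_init__(self) -> None:
        if self.kind not in SITE_KINDS:
            raise ValidationError(f"site kind must be TSS or TTS, got {self.kind!r}")
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.count < 0:
            raise ValidationError(f"negative count {self.count}")


@dataclass(frozen=True)
class FullLengthRead:
    """One contiguous mapped full-length transcript read (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    read_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"read {self.read_id}: start >= end")
        if self.strand not in STRANDS:
            raise ValidationError(f"read {self.read_id}: bad strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """0-based position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class CoverageTrack:
    """Strand-specific per-base coverage over one contig for one replicate."""

    contig: str
    strand: str
    condition: str
    replicate: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValidationError("coverage values must be non-negative")
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# GFF3

_GFF3_COLUMNS = 9
_GENE_FEATURES = {"gene", "CDS"}


def read_annotation(path: str | Path) -> list[Gene]:
    """Read gene features from a GFF3 file into 0-based half-open genes.

    Records of type ``gene`` or ``CDS`` must carry a ``locus_tag`` (or
    ``ID``) attribute.  Coordinates are converted from GFF3 1-based
    inclusive to the internal convention, and genes are returned sorted
    by (contig, start).

    Raises
    ------
    ParseError
        On a malformed line (names the line number).
    ValidationError
        On a duplicate locus_tag.
    """
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF3_COLUMNS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_GFF3_COLUMNS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in _GENE_FEATURES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in STRANDS:
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            attr_map = _parse_gff3_attributes(attrs, path, lineno)
            tag = attr_map.get("locus_tag") or attr_map.get("ID")
            if tag is None:
                raise ParseError(
                    f"{path}: line {lineno}: {ftype} record lacks locus_tag/ID"
                )
            if tag in seen:
                raise ValidationError(f"{path}: duplicate locus_tag {tag!r}")
            seen.add(tag)
            genes.append(Gene(contig, start1 - 1, end1, strand, tag))
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def _parse_gff3_attributes(attrs: str, path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"{path}: line {lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key] = value
    return out


def write_annotation(genes: Sequence[Gene], path: str | Path) -> None:
    """Write genes as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            fh.write(
                f"{g.contig}\topterm\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.locus_tag};locus_tag={g.locus_tag}\n"
            )


# ---------------------------------------------------------------------------
# BED6 sites and reads

_BED6_NAMES = ["contig", "start", "end", "name", "score", "strand"]


def _read_bed6(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            names=_BED6_NAMES,
            header=None,
            comment="#",
            dtype={"contig": str, "name": str, "strand": str},
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: not parseable as BED6: {exc}") from exc
    if df.empty:
        return df
    for col in ("start", "end", "score"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ParseError(f"{path}: BED column {col!r} must be integer")
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        raise ParseError(f"{path}: bad strand value {df.loc[bad, 'strand'].iloc[0]!r}")
    return df


def read_sites(path: str | Path, kind: str, condition: str) -> list[SiteRecord]:
    """Read single-base TSS/TTS sites from a BED6 file.

    The BED score column is the integer supporting-read count and
    chromStart is taken verbatim as the 0-based site position; records
    must span exactly one base.
    """
    if kind not in SITE_KINDS:
        raise ValidationError(f"kind must be TSS or TTS, got {kind!r}")
    df = _read_bed6(path)
    sites: list[SiteRecord] = []
    for row in df.itertuples(index=False):
        if row.end != row.start + 1:
            raise ValidationError(
                f"{path}: site {row.name}: chromEnd must equal chromStart+1 "
                f"(got {row.start}..{row.end})"
            )
        if row.score < 0:
            raise ValidationError(f"{path}: site {row.name}: negative count")
        sites.append(
            SiteRecord(row.contig, int(row.start), row.strand, kind, int(row.score), condition)
        )
    return sites


def write_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    """Write sites as BED6 (score = supporting read count)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            name = f"{s.kind.lower()}_{i}"
            fh.write(
                f"{s.contig}\t{s.position}\t{s.position + 1}\t{name}\t"
                f"{s.count}\t{s.strand}\n"
            )


def read_reads(path: str | Path) -> list[FullLengthRead]:
    """Read full-length transcript reads as BED6 intervals."""
    df = _read_bed6(path)
    return [
        FullLengthRead(row.contig, int(row.start), int(row.end), row.strand, row.name)
        for row in df.itertuples(index=False)
    ]


def write_reads(reads: Iterable[FullLengthRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage


def read_coverage(
    path: str | Path,
    strand: str,
    condition: str,
    replicate: str,
    contig_lengths: dict[str, int],
) -> list[CoverageTrack]:
    """Read a bedGraph file into dense per-base coverage vectors.

    Intervals are 0-based half-open and may be sparse (unlisted
    positions are 0); overlapping intervals or intervals beyond the
    contig length are rejected.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            names=["contig", "start", "end", "value"],
            header=None,
            comment="t",  # skips optional "track" header lines
            dtype={"contig": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: not parseable as bedGraph: {exc}") from exc
    tracks: list[CoverageTrack] = []
    for contig, sub in df.groupby("contig", sort=True):
        if contig not in contig_lengths:
            raise ValidationError(f"{path}: unknown contig {contig!r}")
        length = contig_lengths[contig]
        values = np.zeros(length, dtype=float)
        sub = sub.sort_values("start")
        prev_end = 0
        for row in sub.itertuples(index=False):
            if row.end > length:
                raise ValidationError(
                    f"{path}: interval {row.start}..{row.end} beyond contig "
                    f"{contig} length {length}"
                )
            if row.start < prev_end:
                raise ValidationError(
                    f"{path}: overlapping bedGraph intervals at {contig}:{row.start}"
                )
            values[row.start : row.end] = row.value
            prev_end = row.end
        tracks.append(CoverageTrack(contig, strand, condition, replicate, values))
    # contigs absent from the file still get an all-zero track
    for contig, length in contig_lengths.items():
        if not any(t.contig == contig for t in tracks):
            tracks.append(
                CoverageTrack(contig, strand, condition, replicate, np.zeros(length))
            )
    return tracks


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write per-base coverage as run-length-compressed bedGraph."""
    values = track.values
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        # boundaries of equal-value runs
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(values)]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v == 0:
                continue
            v_repr = int(v) if float(v).is_integer() else v
            fh.write(f"{track.contig}\t{s}\t{e}\t{v_repr}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into an upper-case {contig: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def contig_lengths(sequences: dict[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in sequences.items()}
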