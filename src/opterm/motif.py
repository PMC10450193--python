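"""Terminator-motif profiling around ioTTSs.

Windows span offsets -36..+1 around the termination base (38 nt,
strand-oriented: minus-strand windows are reverse-complemented), the
convention used for intrinsic-terminator logos.  Profiles are plain
position frequency matrices with per-column Shannon information content
(2 - entropy, bits); no small-sample correction is applied.  The polyU
tract of an archaeal intrinsic terminator appears as a T-run ending at
offset 36 (the TTS base itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from opterm.genome_io import SiteRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

WINDOW_UP = 36  # bases upstream of the TTS base
WINDOW_DOWN = 1  # bases downstream
U_TRACT_REGION = 12  # terminal offsets scanned for the longest T-run


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TerminatorWindow:
    """Strand-oriented sequence window around one ioTTS.

    With the default window the sequence is 38 nt and the TTS base sits
    at offset ``WINDOW_UP`` (= 36), with one downstream base after it.
    """

    iotts: SiteRecord
    sequence: str

    def __post_init__(self) -> None:
        if any(b not in ALPHABET for b in self.sequence):
            raise ValueError("window contains non-ACGT characters")


@dataclass
class MotifProfile:
    """Position counts, smoothed frequencies and information content."""

    counts: np.ndarray  # 4 x W ints, rows in ALPHABET order
    frequencies: np.ndarray  # column-stochastic 4 x W
    info_content: np.ndarray  # W values in [0, 2] bits
    n_windows: int


def extract_terminator_windows(
    sequences: dict,
    iotts_list: Sequence[SiteRecord],
    window_up: int = WINDOW_UP,
    window_down: int = WINDOW_DOWN,
) -> list[TerminatorWindow]:
    """Cut strand-oriented windows of ``window_up + window_down + 1`` nt.

    For a plus-strand site at 0-based position p the window is
    ``genome[p - window_up : p + window_down + 1]``; for a minus-strand
    site the mirrored interval is reverse-complemented so the TTS base
    always sits at offset ``window_up``.  Sites whose window would run
    off the contig are skipped with a warning.
    """
    windows: list[TerminatorWindow] = []
    skipped = 0
    for site in iotts_list:
        if site.contig not in sequences:
            raise KeyError(f"contig {site.contig!r} missing from genome FASTA")
        seq = sequences[site.contig]
        p = site.position
        if site.strand == "+":
            a, b = p - window_up, p + window_down + 1
            if a < 0 or b > len(seq):
                skipped += 1
                continue
            windows.append(TerminatorWindow(site, seq[a:b].upper()))
        else:
            a, b = p - window_down, p + window_up + 1
            if a < 0 or b > len(seq):
                skipped += 1
                continue
            windows.append(TerminatorWindow(site, reverse_complement(seq[a:b].upper())))
    if skipped:
        logger.warning("%d site(s) skipped: window out of contig bounds", skipped)
    return windows


def build_motif_profile(
    windows: Sequence[TerminatorWindow], pseudocount: float = 0.25
) -> MotifProfile:
    """Position frequency matrix and per-column information content.

    ``pseudocount`` is added per base per column before normalising
    (default 0.25 = one pseudo-observation split evenly).  Information
    content is 2 - H(column) bits; no small-sample correction.
    """
    if not windows:
        raise ValueError("no terminator windows to profile")
    width = len(windows[0].sequence)
    if any(len(w.sequence) != width for w in windows):
        raise ValueError("windows have inconsistent lengths")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.zeros((4, width), dtype=int)
    index = {b: i for i, b in enumerate(ALPHABET)}
    for w in windows:
        for j, base in enumerate(w.sequence):
            counts[index[base], j] += 1
    smoothed = counts + pseudocount
    frequencies = smoothed / smoothed.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(frequencies > 0,
                         frequencies * np.log2(frequencies), 0.0)
    info_content = 2.0 + plogp.sum(axis=0)
    return MotifProfile(counts, frequencies, info_content, len(windows))


def u_tract_score(window: TerminatorWindow, region: int = U_TRACT_REGION) -> int:
    """Longest T-run within the terminal ``region`` window positions."""
    tail = window.sequence[-region:]
    best = run = 0
    for base in tail:
        run = run + 1 if base == "T" else 0
        best = max(best, run)
    return best


def profile_to_frame(profile: MotifProfile):
    """Per-column table: counts, frequencies and bits (TSV-ready)."""
    import pandas as pd

    width = profile.counts.shape[1]
    rows = []
    for j in range(width):
        row = {"offset": j - WINDOW_UP, "column": j}
        for i, b in enumerate(ALPHABET):
            row[f"count_{b}"] = int(profile.counts[i, j])
            row[f"freq_{b}"] = float(profile.frequencies[i, j])
        row["bits"] = float(profile.info_content[j])
        rows.append(row)
    return pd.DataFrame(rows)
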