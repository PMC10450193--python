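"""Per-ioTTS termination statistics from strand-specific coverage.

The central quantity is the ioTTS-based differential expression ratio
(TDER): the abundance of the gene immediately upstream of an internal
terminator divided by the abundance of the gene immediately downstream.
From it derive the termination efficacy TTE = 1 - TDER^-1 (the fraction
of elongating polymerases terminated at the site) and, when a
factor-depletion condition is available, the dependency
TDER(depletion) / TDER(reference); dependency < 1 marks
factor-dependent terminators.

TDER tiers follow closed-interval-on-the-upper-tier boundaries:
TDER >= 2 is high significance, 1.5 <= TDER < 2 mid, < 1.5 low.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from opterm.genome_io import CoverageTrack, Gene, SiteRecord
from opterm.operons import Operon

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class GeneAbundance:
    """Mean per-base coverage over a gene body (reads/base) + pseudocount."""

    gene: Gene
    condition: str
    replicate: str
    abundance: float


@dataclass
class TderRecord:
    """All statistics for one (ioTTS, condition) pair."""

    operon_id: str
    iotts: SiteRecord
    condition: str
    upstream_gene: Gene
    downstream_gene: Gene
    a_up: float
    a_down: float
    tder: float
    tier: str
    tte: float
    dependency: float | None = None
    p_value: float | None = None
    flags: list = field(default_factory=list)


def quantify_gene_abundance(
    track: CoverageTrack, gene: Gene, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> GeneAbundance:
    """Mean per-base coverage over [start, end) plus a pseudocount.

    The pseudocount keeps downstream ratios finite for silent genes.
    """
    if gene.length == 0:
        raise ValueError(f"gene {gene.locus_tag} has zero length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if gene.end > len(track.values):
        raise ValueError(f"gene {gene.locus_tag} extends beyond track")
    mean = float(track.values[gene.start:gene.end].mean()) + pseudocount
    return GeneAbundance(gene, track.condition, track.replicate, mean)


def compute_tder(a_up: float, a_down: float) -> float:
    """Upstream/downstream abundance ratio across an internal terminator."""
    if a_down <= 0:
        raise ValueError(
            "downstream abundance must be positive; quantify with a "
            "pseudocount to avoid zero denominators"
        )
    return a_up / a_down


def classify_tder(tder: float) -> str:
    """Significance tier: >=2 high, [1.5, 2) mid, <1.5 low."""
    if tder <= 0:
        raise ValueError("TDER must be positive")
    if tder >= 2.0:
        return "high"
    if tder >= 1.5:
        return "mid"
    return "low"


def compute_tte(tder: float) -> float:
    """Termination efficacy 1 - 1/TDER.

    Values below 0 (TDER < 1, i.e. the downstream gene is *more*
    abundant) are returned raw; callers flag them as ``negative_tte``.
    """
    if tder <= 0:
        raise ValueError("TDER must be positive")
    return 1.0 - 1.0 / tder


def compute_dependency(tder_depletion: float, tder_reference: float) -> float:
    """Depletion-condition TDER over reference TDER; < 1 means the
    terminator weakens when the termination factor is depleted."""
    if tder_depletion <= 0 or tder_reference <= 0:
        raise ValueError("TDER ratios must be positive")
    return tder_depletion / tder_reference


def tder_ttest(
    up_replicates: Sequence[float], down_replicates: Sequence[float]
) -> float:
    """Welch two-sample t-test on log2 abundances; two-sided p-value.

    With zero variance on both sides and equal means (a degenerate
    noise-free simulation) the statistic is 0/0; p is reported as 1.
    """
    if len(up_replicates) < 2 or len(down_replicates) < 2:
        raise ValueError(
            "need >= 2 replicates per side for a t-test; run in "
            "single-replicate mode (p reported as missing) instead"
        )
    up = np.log2(np.asarray(up_replicates, dtype=float))
    down = np.log2(np.asarray(down_replicates, dtype=float))
    with warnings.catch_warnings():
        # noise-free replicates are identical; the 0/0 statistic is
        # resolved below instead of warned about
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(up, down, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0 if np.isclose(up.mean(), down.mean()) else 0.0
    return p


def abundance_table(
    tracks: Iterable[CoverageTrack],
    genes: Sequence[Gene],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Quantify every gene on every matching track.

    Returns a tidy frame (gene, condition, replicate, abundance); a
    gene is quantified on tracks matching its contig and strand.
    """
    rows = []
    for track in tracks:
        for gene in genes:
            if gene.contig != track.contig or gene.strand != track.strand:
                continue
            ab = quantify_gene_abundance(track, gene, pseudocount)
            rows.append({
                "gene": gene.locus_tag,
                "condition": ab.condition,
                "replicate": ab.replicate,
                "abundance": ab.abundance,
            })
    return pd.DataFrame(rows)


def _flanking_genes(op: Operon, site: SiteRecord) -> tuple[Gene, Gene] | None:
    """Operon genes immediately flanking a site, in strand orientation
    (upstream = 5' side).  None when the site is not inside a gap."""
    genomic = sorted(op.genes, key=lambda g: g.start)
    for i in range(len(genomic) - 1):
        if genomic[i].end <= site.position < genomic[i + 1].start:
            if op.strand == "+":
                return genomic[i], genomic[i + 1]
            return genomic[i + 1], genomic[i]
    return None


def _is_between(strand: str, a: int, x: int, b: int) -> bool:
    """x strictly between a and b in strand orientation (a 5' of b)."""
    return a < x < b if strand == "+" else b < x < a


def analyze_all_iotts(
    operons: Sequence[Operon],
    abundances: pd.DataFrame,
    reference_condition: str,
    depletion_condition: str | None = None,
) -> list[TderRecord]:
    """Compute TDER/tier/TTE (+ dependency, t-test p) for every ioTTS.

    One record per (ioTTS, condition).  Replicate abundances are
    averaged before the ratio; the same replicates feed the Welch
    t-test.  An ioTSS lying between the ioTTS and its downstream gene
    flags the record ``confounded_by_ioTSS`` (downstream abundance then
    mixes read-through and re-initiation).
    """
    conditions = [reference_condition]
    if depletion_condition:
        conditions.append(depletion_condition)
    means = abundances.groupby(["gene", "condition"])["abundance"].mean()
    by_rep = abundances.groupby(["gene", "condition"])["abundance"].apply(list)

    records: list[TderRecord] = []
    for op in operons:
        for site in op.internal_tts:
            flanks = _flanking_genes(op, site)
            if flanks is None:
                logger.warning(
                    "ioTTS at %s:%d in %s has no flanking gene pair; skipped",
                    site.contig, site.position, op.operon_id)
                continue
            up, down = flanks
            confounded = any(
                _is_between(op.strand, site.position, s.position,
                            down.start if op.strand == "+" else down.end - 1)
                for s in op.internal_tss
            )
            tders: dict[str, float] = {}
            per_condition: list[TderRecord] = []
            for condition in conditions:
                try:
                    a_up = float(means.loc[(up.locus_tag, condition)])
                    a_down = float(means.loc[(down.locus_tag, condition)])
                except KeyError:
                    logger.warning("no abundance for %s/%s in condition %s",
                                   up.locus_tag, down.locus_tag, condition)
                    continue
                tder = compute_tder(a_up, a_down)
                tte = compute_tte(tder)
                flags = []
                if confounded:
                    flags.append("confounded_by_ioTSS")
                if tte < 0:
                    flags.append("negative_tte")
                ups = by_rep.loc[(up.locus_tag, condition)]
                downs = by_rep.loc[(down.locus_tag, condition)]
                p = tder_ttest(ups, downs) if min(len(ups), len(downs)) >= 2 else None
                rec = TderRecord(
                    operon_id=op.operon_id,
                    iotts=site,
                    condition=condition,
                    upstream_gene=up,
                    downstream_gene=down,
                    a_up=a_up,
                    a_down=a_down,
                    tder=tder,
                    tier=classify_tder(tder),
                    tte=tte,
                    p_value=p,
                    flags=flags,
                )
                tders[condition] = tder
                per_condition.append(rec)
            if depletion_condition and reference_condition in tders \
                    and depletion_condition in tders:
                dep = compute_dependency(tders[depletion_condition],
                                         tders[reference_condition])
                for rec in per_condition:
                    rec.dependency = dep
            records.extend(per_condition)
    return records


def records_to_frame(records: Sequence[TderRecord]) -> pd.DataFrame:
    """Tidy TSV-ready view: one row per ioTTS x condition."""
    rows = []
    for r in records:
        rows.append({
            "operon_id": r.operon_id,
            "contig": r.iotts.contig,
            "iotts_position": r.iotts.position,
            "strand": r.iotts.strand,
            "condition": r.condition,
            "upstream_gene": r.upstream_gene.locus_tag,
            "downstream_gene": r.downstream_gene.locus_tag,
            "A_up": r.a_up,
            "A_down": r.a_down,
            "TDER": r.tder,
            "tier": r.tier,
            "TTE": r.tte,
            "dependency": r.dependency,
            "p_value": r.p_value,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)
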