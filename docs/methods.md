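# Methods

## The measurement model

An operon transcribed from a single promoter can carry termination
sites in the intergenic regions between its genes.  At such an internal
terminator (ioTTS) each elongating polymerase terminates with
probability ε (the terminator's *efficiency*) and otherwise reads
through.  Steady-state transcript abundance downstream of the site is
therefore (1 − ε) times the upstream abundance, and with several
terminators in series the attenuations multiply.  The pipeline inverts
this: from per-gene abundances $A_{up}$ and $A_{down}$ flanking an
ioTTS it computes

* TDER = $A_{up}/A_{down}$ — the differential expression ratio,
* TTE = $1 - \mathrm{TDER}^{-1}$ — the termination efficacy, the
  estimator of ε,
* dependency = TDER(depletion)/TDER(reference) — how much the ratio
  collapses when a general termination factor is depleted.  If
  depletion rescales ε to fε, the expected dependency is
  $(1-\varepsilon)/(1-f\varepsilon)$.

TTE is undefined in sign when the downstream gene is *more* abundant
(TDER < 1, e.g. because of an internal promoter); such records keep
their raw negative TTE and are flagged `negative_tte` rather than
clipped.

## Operon calling

A transcription unit requires three pieces of evidence: a TSS, a
same-strand TTS downstream of it, and at least `min_read_support`
full-length reads whose 5′ end lies within `delta5` nt of the TSS and
3′ end within `delta3` nt of the TTS.  Defaults are `delta5 = 20`,
`delta3 = 50`, `min_read_support = 1`: wide enough to absorb a few nt
of end jitter in real long-read data, tight enough that a read is never
assigned to the wrong site in the simulated world, where sites are at
least an intergenic region apart.  All three are exposed in the
configuration and CLI.

Sites from different conditions are unioned (counts summed) before
calling; termination statistics are condition-specific downstream.
TUs sharing any gene are grouped with a union–find; the TU with the
most genes defines the operon (ties: longest span, then leftmost
start — deterministic, and irrelevant whenever evidence is complete).
Genes only partially covered by the span are excluded: a full-length
transcript must contain the whole gene.  TSS/TTS sites strictly inside
the span that fall in an intergenic gap between two consecutive operon
genes become ioTSS/ioTTS; sites inside a gene body never do.  The
requirement that the next gene beyond an operon's 3′ end have a TSS of
its own is kept as a *boundary-confidence flag* (`boundary_confirmed`)
rather than a call-changing rule, because as an inclusion criterion it
would silently delete operons whose downstream neighbour is poorly
mapped.

## Abundance and statistics

Per-gene abundance is the mean per-base coverage over the full gene
body plus a pseudocount (default 0.1 reads/base; median and trimmed
alternatives would be easy to add but the mean is what the simulator's
closed forms predict).  Replicates are averaged before the TDER ratio;
the same replicate values feed a Welch two-sample t-test on log2
abundances (two-sided).  When both replicate sets are identical — a
noise-free simulation — the 0/0 t-statistic is resolved to p = 1 for
equal means.  Tier boundaries are closed on the upper tier (TDER
exactly 2 → high, exactly 1.5 → mid) so that classification is
deterministic.  No multiple-testing correction is applied across
ioTTSs; p-values are reported raw.

When an internal promoter sits between an ioTTS and its downstream
gene, the downstream abundance mixes read-through with re-initiation;
the record is flagged `confounded_by_ioTSS` and kept, since dropping it
would bias terminator surveys toward simple operons.

## Motif profiling

Windows cover offsets −36..+1 around the termination base — 38
positions, with the TTS base at offset 36 — reverse-complemented for
minus-strand sites.  (The alternative 37-nt reading of "36 nt upstream
to 1 nt downstream" is accommodated by `--window-up/--window-down`.)
Analysis stays in DNA space (T, not U).  Frequencies use a pseudocount
of 0.25 per base per column; information content is 2 − H(column) bits
with *no* small-sample correction, which keeps the closed-form unit
tests exact but means absolute bit values are slightly higher than a
corrected logo would show for small site sets.  The U-tract score is
the longest T-run within the last 12 window positions.  No logo image
is rendered; the profile TSV contains everything a logo would show.

## The synthetic world

Defaults encode the stated biology rather than convenient numbers:
internal-terminator efficiencies ε ~ U[0.3, 0.8] (the 30–80% range
observed for most terminators genome-wide); operons of 2–5 genes,
10 per type, on alternating strands; genes 500–1500 nt, intergenic
regions 60–120 nt; polyU tracts of 8 T's on the coding strand ending at
the ioTTS base; full-length read depth 50 per operon promoter; coverage
depth 100 at the operon 5′ end; 3 replicates; a depletion condition
with every internal ε multiplied by f = 0.5.  Promoter strength is a
relative weight: the operon 5′ end gets the configured coverage depth
exactly, and each internal promoter contributes coverage and reads
scaled by its strength relative to the host promoter.

Reads start at a promoter, terminate at each internal terminator they
cross with probability ε(condition), and at the operon-end terminator
with its own efficiency (drawn from [0.6, 0.9]); survivors run on
20–100 nt into the downstream spacer, which is why scattered low-count
3′-end sites appear past operon ends, as they do in real Term-seq data.
With `noise="none"` all counts are deterministic expected values
(largest-remainder apportioning for reads, exact expectations for
coverage), giving byte-reproducible datasets and exact closed-form
recovery; with `noise="poisson"` read counts are Poisson/binomial and
coverage is Poisson around its expectation.  Read ends can be jittered
by rounded Gaussian noise (default sd 0; 3 nt is a realistic setting —
site calls then spread over neighbouring bases, which the calling
tolerances absorb).

Type IV operons have ≥3 genes with the ioTTS in the first intergenic
gap and the ioTSS in the second, so the terminator's TDER is never
confounded by re-initiation in the default world; confounded layouts
can be produced by placing sites manually.  Exactly one ioTTS is placed
per Type II/IV operon: stacking several strong terminators would drive
the expected full-length read count per operon below one at the default
depth and make architecture recovery depend on luck rather than on the
caller.

What the generator does **not** emulate: sequencing error, antisense
transcription, rRNA contamination, overlapping operons, condition-
dependent promoter activity, or 3′-end degradation gradients.  A green
recovery test therefore establishes that the pipeline inverts its own
generative model correctly — not that it is robust to every artefact of
real libraries.

## Numerical conventions

All internal coordinates are 0-based half-open; single-base sites store
the index of the base itself (TSS = first transcribed base, TTS =
last).  Writers convert back to each format's native convention (GFF3
1-based inclusive, BED/bedGraph 0-based half-open).  bedGraph parsing
uses round-trip float precision so that written coverage re-reads
bit-exactly.  Percentages are rounded half away from zero to integers;
ratios are reported to 1 decimal in summaries.  All randomness flows
from a single integer seed through per-stream `numpy` generators
(`[seed, stream, condition, replicate, strand]`), so any layer can be
regenerated independently and whole datasets are byte-reproducible.

## Known limitations

* Operon extent is the defining TU's span; a handful of run-on reads
  can extend the reported 3′ boundary a few tens of nt past the true
  terminator (gene content and type are unaffected).
* TDER-based TTE assumes coverage is proportional to transcript
  abundance within an operon; library-specific positional biases are
  out of scope.
* The t-test treats replicate gene abundances as independent
  log-normal; with 2 replicates its power is nominal only.
* Multi-contig inputs are supported, but sites and genes never pair
  across contigs and the simulator emits a single contig.
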