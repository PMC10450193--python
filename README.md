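# opterm — operon architecture and internal transcription termination

Genes inside prokaryotic operons are co-transcribed from one promoter,
yet their transcript and protein levels are often markedly uneven.  In
archaea a major cause is *internal* transcription termination: Term-seq
and full-length transcript sequencing reveal termination sites in the
intergenic regions **within** operons (ioTTSs), at which only a fraction
of elongating RNA polymerases terminate.  The resulting partial
read-through sets a stoichiometric ratio between upstream and
downstream gene products — for example between ribosomal-protein and
RNA-polymerase-subunit genes sharing an operon.

`opterm` implements the computational side of this analysis for
anyone working with prokaryotic transcriptome maps built from
single-base TSS (dRNA-seq), TTS (Term-seq), full-length transcript
reads and strand-specific coverage:

* **Operon/TU calling** — a transcription unit is a same-strand
  (TSS, TTS) pair supported by a full-length read covering it end to
  end; TUs sharing genes are grouped, the gene-richest TU defines the
  operon, and internal sites in intergenic gaps become ioTSS/ioTTS.
  Operons are classified into four types: I (no internal sites),
  II (≥1 ioTTS), III (≥1 ioTSS), IV (both).
* **Termination statistics** — for each ioTTS with upstream/downstream
  gene abundances $A_{up}, A_{down}$ (mean per-base coverage):

  $$\mathrm{TDER} = A_{up}/A_{down}, \qquad
    \mathrm{TTE} = 1 - \mathrm{TDER}^{-1}, \qquad
    \mathrm{dependency} = \mathrm{TDER}_{depletion}/\mathrm{TDER}_{reference}$$

  TDER ≥ 2 is high significance, 1.5 ≤ TDER < 2 mid, < 1.5 low; TTE is
  the fraction of transcription events terminated at the site, and a
  dependency below 1 marks terminators that weaken when the general
  termination factor is depleted.  A Welch t-test on log2 replicate
  abundances accompanies each ratio.
* **Terminator motif profiling** — strand-oriented windows spanning
  offsets −36..+1 around each ioTTS, position frequency matrices,
  per-column information content (bits), and the polyU-tract score
  (longest T-run in the terminal 12 positions).
* **Synthetic data with ground truth** — a generator that emits every
  evidence layer (FASTA/GFF3/BED6/bedGraph) for operons of all four
  types with known per-terminator termination efficiency ε, Poisson
  coverage noise, replicates, and a depletion condition in which every
  ε is scaled by a factor *f*.  Because coverage downstream of a
  terminator drops by (1 − ε), the pipeline should recover TTE = ε —
  which makes every stage testable by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default simulated world (40 operons, 10 per type; ε ~ U[0.3, 0.8];
depletion factor 0.5; Poisson coverage at depth 100; 3 replicates):

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_call_operons.py
python analysis/03_termination_stats.py
python analysis/04_motif_profile.py
python analysis/05_recovery_benchmarks.py --seed 0
```

which prints:

```
simulated 40 operons (20 internal terminators, 20 internal promoters) on a 177869 nt contig
40 TUs, of which 40 are operons (>=2 genes)
type percentages: {'I': 25, 'II': 25, 'III': 25, 'IV': 25}
50% of operons carry an ioTTS, 50% an ioTSS; median operon length 3992 nt
20 ioTTS records in wt; tiers: {'high': 14, 'mid': 5, 'low': 1}
median TDER 2.38, median TTE 0.579
median dependency (depletion/reference TDER) 0.593 — values < 1 mark factor-dependent terminators
profiled 20 terminator windows
mean information content: 1.72 bits over the U-tract (offsets -7..0) vs 0.09 bits background
mean U-tract score (longest T-run in the terminal 12 nt): 8.7
noise-free: precision 1.00, recall 1.00, type accuracy 1.00
Poisson: 50 terminators, mean |TTE - eps| = 0.0014, slope = 0.997
dependency: 50 terminators, MAE vs closed form = 0.0024
```

Reading this: every simulated operon and type label is recovered
exactly on noise-free data; with Poisson noise the measured termination
efficacy tracks the true ε essentially 1:1 (slope 0.997, mean absolute
error 0.0014); the depletion/reference dependency matches its closed
form (1 − ε)/(1 − fε); and the embedded polyU tracts reappear as a
1.72-bit information peak in the last eight window columns with a mean
U-tract score of 8.7 (8 embedded T's plus chance extensions).

The same stages are exposed as a CLI (`opterm simulate`,
`opterm call-operons`, `opterm termination-stats`, `opterm motif`,
`opterm run-all`, `opterm compare-truth`) for use on real datasets in
the same formats.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline end to end on freshly simulated data — the
noise-free architecture-recovery setting and the Poisson
termination-efficacy setting — and writes the results JSON.

## Layout

* `src/opterm/` — the library: `genome_io` (formats + domain types),
  `simulate` (generative model), `operons` (TU/operon caller),
  `termination` (TDER/TTE/dependency), `motif` (terminator windows and
  profiles), `pipeline` (orchestration), `cli`.
* `analysis/` — numbered narrative drivers writing to `results/`.
* `tests/` — pytest suite, including property-based invariants and the
  acceptance checks in `tests/test_acceptance.py`.
* `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations.
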