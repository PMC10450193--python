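"""Quantify gene abundances from coverage and compute per-ioTTS
termination statistics: TDER, significance tier, TTE, factor
dependency and replicate t-test p-values."""

import argparse
from pathlib import Path

from opterm.operons import build_transcription_units, call_operons
from opterm.pipeline import load_dataset
from opterm.termination import abundance_table, analyze_all_iotts, \
    records_to_frame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--pseudocount", type=float, default=0.1)
    args = ap.parse_args()

    data = load_dataset(args.input)
    all_tss = [s for v in data.tss.values() for s in v]
    all_tts = [s for v in data.tts.values() for s in v]
    all_reads = [r for v in data.reads.values() for r in v]
    tus = build_transcription_units(data.genes, all_tss, all_tts, all_reads)
    operons, _ = call_operons(tus, all_tss, all_tts, data.genes)

    tracks = [t for v in data.coverage.values() for t in v]
    abundances = abundance_table(tracks, data.genes, args.pseudocount)
    records = analyze_all_iotts(operons, abundances,
                                data.reference_condition,
                                data.depletion_condition)
    frame = records_to_frame(records)
    args.out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out / "tder.tsv", sep="\t", index=False)

    ref = frame[frame["condition"] == data.reference_condition]
    tiers = ref["tier"].value_counts().to_dict()
    print(f"{len(ref)} ioTTS records in {data.reference_condition}; "
          f"tiers: {tiers}")
    print(f"median TDER {ref['TDER'].median():.2f}, "
          f"median TTE {ref['TTE'].median():.3f}")
    if data.depletion_condition:
        dep = ref["dependency"].dropna()
        print(f"median dependency (depletion/reference TDER) {dep.median():.3f} "
              f"— values < 1 mark factor-dependent terminators")


if __name__ == "__main__":
    main()
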