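"""Profile the terminator motif in the -36..+1 window around called
ioTTSs: position frequencies, information content, and U-tract scores."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from opterm import genome_io
from opterm.motif import build_motif_profile, extract_terminator_windows, \
    profile_to_frame, u_tract_score


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/dataset"))
    ap.add_argument("--sites", type=Path, default=Path("results/tder.tsv"),
                    help="tder.tsv from step 03 (ioTTS positions)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    sequences = genome_io.read_genome(args.input / "genome.fasta")
    tder = pd.read_csv(args.sites, sep="\t")
    sites = [
        genome_io.SiteRecord(r.contig, int(r.iotts_position), r.strand, "TTS",
                             1, "union")
        for r in tder.drop_duplicates(["contig", "iotts_position", "strand"])
             .itertuples(index=False)
    ]
    windows = extract_terminator_windows(sequences, sites)
    profile = build_motif_profile(windows)
    args.out.mkdir(parents=True, exist_ok=True)
    profile_to_frame(profile).to_csv(args.out / "motif_profile.tsv", sep="\t",
                                     index=False)
    scores = [u_tract_score(w) for w in windows]
    terminal = profile.info_content[29:37].mean()
    background = np.delete(profile.info_content, np.arange(29, 37)).mean()
    print(f"profiled {len(windows)} terminator windows")
    print(f"mean information content: {terminal:.2f} bits over the U-tract "
          f"(offsets -7..0) vs {background:.2f} bits background")
    print(f"mean U-tract score (longest T-run in the terminal 12 nt): "
          f"{np.mean(scores):.1f}")


if __name__ == "__main__":
    main()
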