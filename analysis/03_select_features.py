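#!/usr/bin/env python
"""Reduce each chromosome's feature set by MIC thresholding.

Builds locus selections at the two fixed thresholds (0.65, 0.52) and at a
threshold learned jointly across chromosomes (largest grid value keeping at
least two loci everywhere), and reports the reduction each achieves.
"""

import argparse
from pathlib import Path

from micclust.evaluate import proportional_size
from micclust.mic import read_profile
from micclust.selection import learn_threshold, select_loci, write_selection


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--mic", type=Path, default=Path("results/mic"))
    ap.add_argument("--out", type=Path, default=Path("results/selection"))
    ap.add_argument("--min-loci", type=int, default=2)
    args = ap.parse_args()

    paths = sorted(args.mic.glob("mic_chr*.tsv"), key=lambda p: (len(p.stem), p.stem))
    if not paths:
        raise SystemExit(f"no MIC profiles under {args.mic}; run 02 first")
    profiles = {p.stem.removeprefix("mic_"): read_profile(p) for p in paths}
    gamma = learn_threshold(list(profiles.values()), min_loci=args.min_loci)
    print(f"learned threshold across {len(profiles)} chromosomes: gamma = {gamma:.2f}")

    args.out.mkdir(parents=True, exist_ok=True)
    configs = [("0.65", 0.65), ("0.52", 0.52), ("learned", gamma)]
    print(f"{'chrom':<7}{'m':>7}" + "".join(f"{f'v@{name}':>16}" for name, _ in configs))
    for cid, profile in profiles.items():
        profile.chromosome_id = cid
        row = f"{cid:<7}{profile.m:>7}"
        for i, (name, g) in enumerate(configs):
            sel = select_loci(profile, g)
            write_selection(sel, args.out / f"selection_{cid}.tsv", append=i > 0)
            pct = proportional_size(sel.v, sel.m)
            row += f"{sel.v:>6} ({pct:5.2f}%)".rjust(16)
        print(row)
    print(f"selections -> {args.out}")


if __name__ == "__main__":
    main()
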