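#!/usr/bin/env python
"""Score per-position nucleobase preferences from SIA pool CSPs.

Turns the four-pools-per-position CSP table into a normalised specificity
matrix (each position's four scores sum to 1) and a consensus string.
"""

import argparse
from pathlib import Path

from didomain import io
from didomain.sia import consensus, sia_scores


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/simulated/dynamic/sia_pools.tsv"))
    parser.add_argument("--aggregate", choices=("mean", "median"), default="mean")
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    pools = io.read_sia_tsv(args.input)
    matrix = sia_scores(pools, aggregate=args.aggregate)
    labels = consensus(matrix)

    matrix.round(4).rename_axis("position").to_csv(args.outdir / "sia_matrix.tsv", sep="\t")
    io.write_json({"matrix": {int(p): row.to_dict() for p, row in matrix.iterrows()},
                   "consensus": labels}, args.outdir / "sia_scores.json")
    lines = ["position  A      C      G      U      preference"]
    for pos, row in matrix.iterrows():
        lines.append(f"{pos:>8d}  " + "  ".join(f"{row[b]:.3f}" for b in "ACGU") + f"  {labels[int(pos)]}")
    text = "\n".join(lines)
    (args.outdir / "sia_consensus.txt").write_text(text + "\n")
    print(text)
    print(f"wrote {args.outdir}/sia_matrix.tsv, sia_scores.json, sia_consensus.txt")


if __name__ == "__main__":
    main()
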