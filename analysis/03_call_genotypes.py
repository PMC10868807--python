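#!/usr/bin/env python
"""Call per-colony duplex genotypes from the traced reads.

Applies the MM2 flank-concordance fix to every informative read, builds
per-colony haplotype frequency tables, and assigns each colony the two most
frequent haplotypes above the 19% threshold (one haplotype above: a
homoduplex). Compares the calls with the simulation truth table.

Outputs under --out: genotypes.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ssa_spectra import call_colony


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--traces", type=Path, default=Path("results/traces.tsv"))
    parser.add_argument("--truth", type=Path, default=Path("results/library/truth.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--threshold", type=float, default=0.19)
    args = parser.parse_args()

    traces = pd.read_csv(args.traces, sep="\t")
    rows = []
    genotypes = {}
    for cid, group in traces.groupby("colony_id"):
        genotype, table = call_colony(
            list(group["calls"]), colony_id=cid, threshold=args.threshold
        )
        genotypes[cid] = genotype
        rows.append(
            {
                "colony_id": cid,
                "top": genotype.top,
                "bottom": genotype.bottom,
                "flags": ",".join(sorted(genotype.flags)),
                "support": ",".join(f"{f:.4f}" for f in genotype.support),
                "n_informative": table.n_informative,
                "n_excluded": table.n_excluded,
            }
        )
    frame = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out / "genotypes.tsv", sep="\t", index=False)

    truth = pd.read_csv(args.truth, sep="\t")
    n_correct = sum(
        genotypes[row.colony_id].unordered() == frozenset((row.top, row.bottom))
        for row in truth.itertuples()
        if genotypes.get(row.colony_id) is not None
        and genotypes[row.colony_id].unordered() is not None
    )
    print(f"called {len(frame)} colonies -> {args.out / 'genotypes.tsv'}")
    print(
        f"duplex genotype accuracy vs truth: {n_correct}/{len(truth)} "
        f"({100 * n_correct / len(truth):.1f}%)"
    )
    print("most frequent called genotypes:")
    top = frame.groupby(["top", "bottom"]).size().sort_values(ascending=False).head(5)
    for (t, b), n in top.items():
        print(f"  {t}/{b}: {n} colonies")


if __name__ == "__main__":
    main()
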