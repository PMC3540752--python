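#!/usr/bin/env python
"""Crosstalk between bias groups under degree-preserving randomization.

Builds the bias x chromosome-class partition from the DE calls, runs 100
network randomizations, and reports which group pairs are enriched or
depleted in links (FDR < 0.05).
"""

import argparse
from pathlib import Path

import pandas as pd

from biasnet.crosstalk import compose_bias_partition, crosstalk, write_crosstalk
from biasnet.diffexpr import BiasTable
from biasnet.network_io import read_chromosome_classes, read_network


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", default="results/bundle")
    ap.add_argument("--de-table", default="results/02_de_gonad_adult.tsv")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/03_crosstalk_gonad_adult.tsv")
    args = ap.parse_args()
    bundle = Path(args.bundle)

    net = read_network(bundle / "network.tsv")
    chrom = read_chromosome_classes(bundle / "chromosome_classes.tsv")
    de = pd.read_csv(args.de_table, sep="\t", index_col=0)
    bias = BiasTable(labels=de["label"], condition=("gonad", "adult"), fdr_cutoff=0.1)

    part = compose_bias_partition(bias, chrom)
    part = {g: l for g, l in part.items() if g in net.genes}
    result = crosstalk(net, part, n_rand=100, seed=args.seed)
    write_crosstalk(result, args.out)

    t = result.table
    sig = t[(t["fdr"] < 0.05)].sort_values("z", ascending=False)
    print(f"{len(t)} group pairs tested; {len(sig)} significant at FDR < 0.05")
    print("strongest enrichments / depletions (z):")
    for _, r in pd.concat([sig.head(4), sig.tail(3)]).iterrows():
        print(
            f"  {r.label_a:>12} - {r.label_b:<12} observed {r.observed:5d} "
            f"null {r.null_mean:7.1f}  z {r.z:+7.1f} ({r.sign})"
        )
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
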