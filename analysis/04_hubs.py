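#!/usr/bin/env python
"""Relate sex bias to network connectivity.

Computes the Spearman correlation of DE FDR vs node degree within each
bias category, and the rank-sum list of the most sex-biased hub genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from biasnet.diffexpr import BiasTable, DEResult
from biasnet.hubs import bias_degree_correlation, rank_hubs, write_correlations, write_hubs
from biasnet.network_io import degrees, read_network


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", default="results/bundle")
    ap.add_argument("--de-table", default="results/02_de_gonad_adult.tsv")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    bundle = Path(args.bundle)

    net = read_network(bundle / "network.tsv")
    table = pd.read_csv(args.de_table, sep="\t", index_col=0)
    de = DEResult(table=table, condition=("gonad", "adult"), d0=float("nan"), n_male=3, n_female=3)
    bias = BiasTable(labels=table["label"], condition=("gonad", "adult"), fdr_cutoff=0.1)
    deg = degrees(net)

    corr = bias_degree_correlation(de, deg, bias)
    corr_out = Path(args.outdir) / "04_fdr_degree_correlation.tsv"
    write_correlations(corr, corr_out)
    print("Spearman correlation of DE FDR vs degree per bias category")
    print("(positive rho = stronger bias pairs with lower connectivity):")
    for r in corr:
        print(f"  {r.category:>9}: rho {r.rho:+.3f}  p {r.p:.3g}  n {r.n}")

    hubs_table = rank_hubs(de, deg, top_n=20)
    hubs_out = Path(args.outdir) / "04_top_sex_biased_hubs.tsv"
    write_hubs(hubs_table, hubs_out)
    top = hubs_table.iloc[0]
    print(
        f"top sex-biased hub: {top.gene_id} "
        f"(fdr {top.fdr:.2g}, degree {top.degree}, rank sum {top.rank_sum})"
    )
    print(f"tables written to {corr_out} and {hubs_out}")


if __name__ == "__main__":
    main()
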