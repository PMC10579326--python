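#!/usr/bin/env python
"""Nonparametric comparisons of the fitted rates: Kruskal-Wallis across the
four depths, then one-sided pairwise Wilcoxon tests (BH-adjusted) between
depths and between treatments.  Reads results/campaign/rates.tsv."""

from pathlib import Path

import pandas as pd

from mpnmethane.pipeline import RunConfig, stats_stage

out = Path("results/campaign")
rates = pd.read_csv(out / "rates.tsv", sep="\t")
omnibus, depth_pairs, treatments = stats_stage(rates, RunConfig())

omnibus.to_csv(out / "stats_omnibus.tsv", sep="\t", index=False)
depth_pairs.to_csv(out / "stats_depth_pairs.tsv", sep="\t", index=False)
treatments.to_csv(out / "stats_treatments.tsv", sep="\t", index=False)

row = omnibus.iloc[0]
print(f"depth omnibus: H = {row.H:.1f}, df = {row.df}, p = {row.p:.2g}")
print("BH-adjusted depth contrasts (shallower tested greater):")
print(depth_pairs[["group_a", "group_b", "p_adj"]]
      .assign(p_adj=lambda d: d.p_adj.round(4)).to_string(index=False))
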