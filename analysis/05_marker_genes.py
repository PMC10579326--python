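#!/usr/bin/env python
"""Marker-gene normalization on a simulated count table: per-gene TPM and
the recA-normalized phnJ percentage (one recA copy per bacterium assumed).
Writes results/campaign/genes.tsv."""

import sys
from pathlib import Path

from mpnmethane.genes import phnj_relative_abundance, tpm
from mpnmethane.synth import SimulationConfig, simulate_count_table

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path("results/campaign")
out.mkdir(parents=True, exist_ok=True)

table = simulate_count_table(SimulationConfig(seed=seed),
                             total_reads=1_000_000)
table["tpm"] = tpm(table)
pct = phnj_relative_abundance(table)
table["phnj_percent_of_genomes"] = pct
table.to_csv(out / "genes.tsv", sep="\t", index=False)

print(table[["gene_id", "gene_family", "read_count", "tpm"]]
      .round(1).to_string(index=False))
print(f"phnJ carried by {pct:.2f}% of genomes (recA-normalized)")
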