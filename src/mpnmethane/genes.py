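"""Downstream count arithmetic for phnJ / recA marker-gene tables.

Upstream assembly, ORF calling, clustering and read mapping are assumed
done; the input is a flat table of representative genes with ORF length,
mapped-read count (already filtered at >80% identity) and taxon/family
labels.  Two normalizations are provided: TPM (length-normalized rates
scaled to one million) and the single-copy-gene convention, which expresses
the length-normalized phnJ signal as a percentage of the length-normalized
recA signal — i.e. the percentage of genomes carrying phnJ, assuming one
recA copy per bacterium.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "UndefinedTpmError",
    "UndefinedAbundanceError",
    "validate_count_table",
    "tpm",
    "phnj_relative_abundance",
    "identity_filter",
]

REQUIRED_COLUMNS = ("gene_id", "orf_length", "read_count", "taxon",
                    "gene_family")

#: Strict lower bound on percent identity for a mapped read to count.
IDENTITY_THRESHOLD = 80.0


class UndefinedTpmError(ValueError):
    """TPM is undefined when every gene has zero mapped reads."""


class UndefinedAbundanceError(ValueError):
    """recA-normalized abundance is undefined without recA signal."""


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (table["orf_length"] <= 0).any():
        raise ValueError("ORF lengths must be positive")
    if (table["read_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    return table


def tpm(table: pd.DataFrame) -> pd.Series:
    """Transcripts/fragments per million over the table's genes.

    rate_i = count_i / length_i; TPM_i = 1e6 * rate_i / sum(rate); the
    column sums to one million by construction.
    """
    validate_count_table(table)
    rate = table["read_count"] / table["orf_length"]
    total = rate.sum()
    if total <= 0:
        raise UndefinedTpmError("all read counts are zero")
    out = 1e6 * rate / total
    out.name = "tpm"
    return out


def phnj_relative_abundance(table: pd.DataFrame) -> float:
    """phnJ abundance as % of genomes, normalized to single-copy recA.

    100 * sum(count/length over phnJ rows) / sum(count/length over recA
    rows); length normalization happens per cluster before summation.
    """
    validate_count_table(table)
    rate = table["read_count"] / table["orf_length"]
    phnj = rate[table["gene_family"] == "phnJ"].sum()
    reca = rate[table["gene_family"] == "recA"].sum()
    if reca <= 0:
        raise UndefinedAbundanceError("no recA signal to normalize against")
    return 100.0 * phnj / reca


def identity_filter(raw_hits: pd.DataFrame,
                    threshold: float = IDENTITY_THRESHOLD) -> pd.DataFrame:
    """Aggregate per-read/per-alignment hits into a gene count table.

    Keeps rows with ``percent_identity`` strictly above ``threshold`` and
    sums their counts per gene, carrying length/taxon/family through.
    ``raw_hits`` needs the :data:`REQUIRED_COLUMNS` plus percent_identity;
    a missing ``read_count`` column defaults to one read per row.
    """
    hits = raw_hits.copy()
    if "read_count" not in hits.columns:
        hits["read_count"] = 1
    if ((hits["percent_identity"] < 0) | (hits["percent_identity"] > 100)).any():
        raise ValueError("percent identity must lie in [0, 100]")
    kept = hits[hits["percent_identity"] > threshold]
    if kept.empty:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    out = (kept.groupby(["gene_id", "orf_length", "taxon", "gene_family"],
                        as_index=False)["read_count"].sum())
    return out[list(REQUIRED_COLUMNS)]
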