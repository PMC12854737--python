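"""Relative-abundance summaries of amplicon taxon count tables.

The input boundary is a finished taxon table (samples × taxa integer
counts) from 16S/18S amplicon sequencing; no rarefaction or denoising is
applied.  Counts are converted to per-sample proportions, and minor taxa
beyond the n most abundant (by mean relative abundance across samples) are
lumped into a residual category so stacked-bar style summaries stay
readable.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["relative_abundance", "lump_minor_taxa", "to_long_format"]


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample taxon proportions (rows = samples, columns = taxa).

    Each row of the result sums to 1.  A sample with zero total reads has
    no defined composition and raises an error naming it.
    """
    if table.empty:
        raise ValueError("taxon table is empty")
    if (table.to_numpy() < 0).any():
        raise ValueError("taxon counts must be non-negative")
    totals = table.sum(axis=1)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(
            f"sample(s) with zero total reads: {list(zero.index)}")
    return table.div(totals, axis=0)


def lump_minor_taxa(proportions: pd.DataFrame, n_top: int,
                    label: str = "Other") -> pd.DataFrame:
    """Keep the ``n_top`` most abundant taxa, lump the rest under ``label``.

    Abundance ranking uses the mean relative abundance across samples, ties
    broken lexicographically by taxon name.  Per-sample totals are
    preserved exactly; if every taxon is retained the residual column is
    omitted.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    means = proportions.mean(axis=0)
    ranked = means.sort_index().sort_values(ascending=False, kind="stable")
    keep = list(ranked.index[:n_top])
    rest = [t for t in proportions.columns if t not in keep]
    out = proportions[keep].copy()
    if rest:
        out[label] = proportions[rest].sum(axis=1)
    return out


def to_long_format(proportions: pd.DataFrame) -> pd.DataFrame:
    """Stacked-bar-ready long format: sample, taxon, proportion."""
    return (proportions.rename_axis(index="sample", columns="taxon")
            .stack().rename("proportion").reset_index())
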