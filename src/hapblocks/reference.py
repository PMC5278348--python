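"""Packaged reference tables."""

from importlib import resources

import pandas as pd


def wheat_chromosome_block_summary() -> pd.DataFrame:
    """Published per-chromosome haplotype-block summary of a 9K-array wheat
    diversity panel (A and B genome chromosomes): SNP totals, block counts,
    tag-SNP counts, mean block spans (cM) and haplotype counts.

    Used to exercise the genome-level aggregation arithmetic of
    :func:`hapblocks.blocks.aggregate_block_summary` against known totals.
    """
    with resources.files("hapblocks.data").joinpath(
        "wheat_chromosome_block_summary.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})
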