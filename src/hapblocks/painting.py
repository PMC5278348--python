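"""Founder-reference allele painting and block-transmission summaries.

Every line's alleles are compared SNP-by-SNP with a founder line (identity
in state, not IBD): a call equal to the founder's is painted ``green``, a
different call ``yellow``, and a missing call — or any call at a SNP where
the founder itself is missing — ``white``.  The comparison runs on the
MAF-filtered SNP subset.  Per block, the fraction of green member SNPs
(white excluded) summarises how much of the founder's haplotype a line
carries; a block is called founder-type when that fraction reaches a
configurable threshold (default 0.9).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import Block
from .panel import CALL_A0, CALL_A1, GenotypePanel, PanelError

PAINT_SAME = 1  # "green"
PAINT_DIFF = 0  # "yellow"
PAINT_MISSING = -1  # "white"

STATE_NAMES = {PAINT_SAME: "green", PAINT_DIFF: "yellow", PAINT_MISSING: "white"}

FOUNDER_TYPE_FRACTION = 0.9


@dataclasses.dataclass(frozen=True)
class PaintingMatrix:
    founder_id: str
    line_ids: tuple
    snp_ids: tuple
    states: np.ndarray  # lines x SNPs of PAINT_* codes
    genetic_map: pd.DataFrame

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.line_ids, columns=self.snp_ids)

    def long_table(self) -> pd.DataFrame:
        """Plot-ready long table ordered by (chromosome, cM)."""
        rows = []
        for j, snp in enumerate(self.snp_ids):
            chrom = self.genetic_map.iloc[j]["chrom"]
            cm = float(self.genetic_map.iloc[j]["cm"])
            for i, line in enumerate(self.line_ids):
                rows.append((line, snp, chrom, cm, STATE_NAMES[int(self.states[i, j])]))
        return pd.DataFrame(rows, columns=["line", "snp_id", "chrom", "cm", "state"])


def paint_against_founder(
    panel: GenotypePanel,
    founder_id: str,
    maf: float = 0.05,
    het_as_missing: bool = True,
) -> PaintingMatrix:
    """Paint every line against the founder over the MAF-filtered SNPs.

    Heterozygous calls are painted white under the default selfing-crop
    convention.  At SNPs where the founder is missing, every line is white.
    """
    if founder_id not in panel.line_ids:
        raise PanelError(f"founder {founder_id!r} not in panel")
    sub = panel.filter_maf(maf, het_as_missing) if maf > 0 else panel
    fi = sub.line_index(founder_id)
    calls = sub.calls
    homo = (calls == CALL_A0) | (calls == CALL_A1)
    if het_as_missing:
        informative = homo
    else:
        informative = calls >= 0
    founder_row = calls[fi]
    founder_ok = informative[fi]
    states = np.full(calls.shape, PAINT_MISSING, dtype=np.int8)
    paintable = informative & founder_ok[None, :]
    states[paintable & (calls == founder_row[None, :])] = PAINT_SAME
    states[paintable & (calls != founder_row[None, :])] = PAINT_DIFF
    return PaintingMatrix(
        founder_id, tuple(sub.line_ids), tuple(sub.snp_ids), states, sub.genetic_map
    )


def block_transmission_summary(
    painting: PaintingMatrix,
    blocks: Sequence[Block] | Mapping[str, Sequence[Block]],
    founder_fraction: float = FOUNDER_TYPE_FRACTION,
) -> pd.DataFrame:
    """Per line x block fraction of founder-identical member SNPs.

    White (missing/unpaintable) member SNPs are excluded from the
    denominator; the fraction is NaN when a line has no scored member SNP.
    ``founder_type`` flags fractions >= ``founder_fraction``.
    """
    if isinstance(blocks, Mapping):
        blocks = [b for chrom in blocks.values() for b in chrom]
    pos = {s: j for j, s in enumerate(painting.snp_ids)}
    rows = []
    for block in blocks:
        cols = [pos[s] for s in block.snp_ids if s in pos]
        if not cols:
            continue
        sub = painting.states[:, cols]
        scored = (sub != PAINT_MISSING).sum(axis=1)
        green = (sub == PAINT_SAME).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(scored > 0, green / scored, np.nan)
        for i, line in enumerate(painting.line_ids):
            rows.append(
                {
                    "line": line,
                    "block_id": block.block_id,
                    "chrom": block.chromosome,
                    "n_scored": int(scored[i]),
                    "fraction_founder": float(frac[i]),
                    "founder_type": bool(
                        scored[i] > 0 and frac[i] >= founder_fraction
                    ),
                }
            )
    return pd.DataFrame(rows)
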