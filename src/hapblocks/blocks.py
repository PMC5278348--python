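"""Solid-spine-of-LD haplotype blocks, haplotype tables and tag SNPs.

A candidate interval ``[i..j]`` of consecutive mapped SNPs is a valid spine
block iff the outer pair and every outer-to-interior pair are in strong LD:

    D'(i, j) > t  and for every interior k:  D'(i, k) > t  and  D'(k, j) > t

with strict ``>`` at the threshold (default t = 0.8).  The interior markers
need not be in LD with each other.  Blocks are found by a deterministic
greedy left-to-right scan: start at the leftmost unblocked SNP ``i``, grow
``j`` while the interval stays valid, emit ``[i..j]`` if ``j > i``, continue
after ``j``.  Uninformative pairs (monomorphic locus, too few informative
lines) count as failing the threshold.  Two member SNPs are the minimum;
zero-cM spans (co-located markers) are allowed; there is no span cap.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ld import MIN_INFORMATIVE, dprime_matrix
from .panel import GenotypePanel, PanelError

DPRIME_THRESHOLD = 0.8
COMMON_HAPLOTYPE_FREQ = 0.05


@dataclasses.dataclass(frozen=True)
class Block:
    """One haplotype block: contiguous run of mapped SNPs on a chromosome."""

    block_id: str  # "HapB-<chrom>-<index>", 1-based along the chromosome
    chromosome: str
    first: int  # index into the chromosome's SNP list
    last: int
    snp_ids: tuple
    span_cm: float
    tag_snp_ids: tuple = ()

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclasses.dataclass(frozen=True)
class BlockHaplotypes:
    """Distinct haplotype strings of one block, numbered 1.. by descending
    frequency (ties broken lexicographically); per-line assignment is the
    1-based haplotype number or 0 when any member call is missing."""

    block_id: str
    haplotypes: tuple  # strings over member SNPs, '0'/'1' per allele
    frequencies: np.ndarray
    assignments: np.ndarray  # per panel line, 1-based index or 0
    n_assigned: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def haplotype_label(self, number: int) -> str:
        """e.g. 'HapB-1A-29-2' for haplotype 2 of block HapB-1A-29."""
        return f"{self.block_id}-{number}"


def _spine_blocks_from_dprime(dp: np.ndarray, threshold: float) -> list:
    """Greedy spine scan over a (possibly NaN-holed) |D'| matrix.

    Returns [(first, last), ...] with last > first, disjoint and ordered.
    NaN entries fail the threshold.
    """

    s = dp.shape[0]

    def ok(a, b):
        v = dp[a, b]
        return np.isfinite(v) and v > threshold

    def valid(i, j):
        if not ok(i, j):
            return False
        return all(ok(i, k) and ok(k, j) for k in range(i + 1, j))

    out = []
    i = 0
    while i < s - 1:
        j = i
        while j + 1 < s and valid(i, j + 1):
            j += 1
        if j > i:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def detect_blocks(
    panel: GenotypePanel,
    chromosome: str,
    dprime_threshold: float = DPRIME_THRESHOLD,
    het_as_missing: bool = True,
    min_informative: int = MIN_INFORMATIVE,
) -> list:
    """Solid-spine haplotype blocks for one chromosome, in map order."""
    snp_ids, dp, _, _ = dprime_matrix(
        panel, chromosome, het_as_missing, min_informative=min_informative
    )
    if len(snp_ids) < 2:
        raise PanelError(f"chromosome {chromosome!r} has fewer than 2 mapped SNPs")
    cm = panel.positions_cm(snp_ids)
    blocks = []
    for rank, (i, j) in enumerate(_spine_blocks_from_dprime(dp, dprime_threshold), 1):
        blocks.append(
            Block(
                block_id=f"HapB-{chromosome}-{rank}",
                chromosome=str(chromosome),
                first=i,
                last=j,
                snp_ids=tuple(snp_ids[i : j + 1]),
                span_cm=float(cm[j] - cm[i]),
            )
        )
    return blocks


def detect_blocks_genome(
    panel: GenotypePanel,
    dprime_threshold: float = DPRIME_THRESHOLD,
    het_as_missing: bool = True,
    min_informative: int = MIN_INFORMATIVE,
) -> dict:
    """detect_blocks for every chromosome with >= 2 SNPs; dict chrom -> blocks."""
    out = {}
    for chrom in panel.chromosomes:
        if panel.chrom_snp_indices(chrom).size >= 2:
            out[chrom] = detect_blocks(
                panel, chrom, dprime_threshold, het_as_missing, min_informative
            )
    return out


# --------------------------------------------------------------------------- #
# haplotypes


def enumerate_haplotypes(
    panel: GenotypePanel,
    blocks: Sequence[Block],
    het_as_missing: bool = True,
) -> dict:
    """Distinct complete haplotype strings per block among informative lines.

    A line with any missing (or heterozygous, under the default convention)
    call inside the block is unassigned — it neither founds nor joins a
    haplotype class.  Returns dict block_id -> :class:`BlockHaplotypes`;
    blocks with zero informative lines get an empty table (flagged by
    ``n_assigned == 0``) and are excluded from association downstream.
    """
    x = panel.haploid_calls(het_as_missing)
    snp_pos = {s: k for k, s in enumerate(panel.snp_ids)}
    out = {}
    for block in blocks:
        cols = [snp_pos[s] for s in block.snp_ids]
        sub = x[:, cols]
        complete = ~np.isnan(sub).any(axis=1)
        strings = {}
        line_str = [None] * panel.n_lines
        for i in np.flatnonzero(complete):
            h = "".join("1" if v == 1 else "0" for v in sub[i])
            line_str[i] = h
            strings[h] = strings.get(h, 0) + 1
        n_assigned = int(complete.sum())
        # descending frequency, ties lexicographic
        ordered = sorted(strings.items(), key=lambda kv: (-kv[1], kv[0]))
        haps = tuple(h for h, _ in ordered)
        freqs = np.array([c / n_assigned for _, c in ordered]) if n_assigned else np.array([])
        number = {h: k + 1 for k, h in enumerate(haps)}
        assignments = np.array(
            [number[s] if s is not None else 0 for s in line_str], dtype=int
        )
        out[block.block_id] = BlockHaplotypes(
            block.block_id, haps, freqs, assignments, n_assigned
        )
    return out


def select_tag_snps(
    haplotypes: BlockHaplotypes,
    block: Block,
    common_freq: float = COMMON_HAPLOTYPE_FREQ,
) -> tuple:
    """Greedy minimal member-SNP set distinguishing all common haplotypes.

    Haplotypes with frequency >= ``common_freq`` must be pairwise separable
    by the joint genotype at the selected SNPs.  At each step the SNP
    separating the most still-confounded pairs is added; ties go to the
    leftmost SNP.  With fewer than two common haplotypes the tag set is
    empty.
    """
    common = [
        h for h, f in zip(haplotypes.haplotypes, haplotypes.frequencies)
        if f >= common_freq
    ]
    if len(common) < 2:
        return ()
    pairs = [(a, b) for ai, a in enumerate(common) for b in common[ai + 1 :]]
    uncovered = set(range(len(pairs)))
    chosen: list[int] = []
    n_snps = len(block.snp_ids)
    while uncovered:
        best, best_gain = None, 0
        for s in range(n_snps):
            if s in chosen:
                continue
            gain = sum(1 for p in uncovered if pairs[p][0][s] != pairs[p][1][s])
            if gain > best_gain:  # strict: ties keep the leftmost
                best, best_gain = s, gain
        if best is None:  # unreachable for distinct strings; guard anyway
            break
        chosen.append(best)
        uncovered = {p for p in uncovered if pairs[p][0][best] == pairs[p][1][best]}
    return tuple(block.snp_ids[s] for s in sorted(chosen))


def with_tags(
    panel: GenotypePanel,
    blocks: Sequence[Block],
    haplotypes: Mapping[str, BlockHaplotypes],
    common_freq: float = COMMON_HAPLOTYPE_FREQ,
) -> list:
    """Return the blocks with their tag-SNP sets filled in."""
    return [
        dataclasses.replace(
            b, tag_snp_ids=select_tag_snps(haplotypes[b.block_id], b, common_freq)
        )
        for b in blocks
    ]


# --------------------------------------------------------------------------- #
# Table-1-style summaries


def summarize_blocks(
    blocks_by_chrom: Mapping[str, Sequence[Block]],
    haplotypes: Mapping[str, BlockHaplotypes],
    panel: GenotypePanel,
) -> pd.DataFrame:
    """Per-chromosome block summary (one row per chromosome).

    Columns mirror the classic per-chromosome block table: SNP totals and
    coverage, tag-SNP counts, block counts, cM span statistics and haplotype
    counts.
    """
    rows = []
    for chrom, blocks in blocks_by_chrom.items():
        total_snps = int(panel.chrom_snp_indices(chrom).size)
        n_in = sum(b.n_snps for b in blocks)
        n_tag = sum(len(b.tag_snp_ids) for b in blocks)
        spans = [b.span_cm for b in blocks]
        haps = [haplotypes[b.block_id].n_haplotypes for b in blocks]
        sizes = [b.n_snps for b in blocks]
        tags = [len(b.tag_snp_ids) for b in blocks]
        rows.append(
            {
                "chrom": chrom,
                "total_snps": total_snps,
                "snps_in_blocks": n_in,
                "pct_snps_in_blocks": 100.0 * n_in / total_snps if total_snps else np.nan,
                "snps_per_block_min": min(sizes) if sizes else np.nan,
                "snps_per_block_max": max(sizes) if sizes else np.nan,
                "tag_snps": n_tag,
                "pct_tag_snps": 100.0 * n_tag / total_snps if total_snps else np.nan,
                "tags_per_block_min": min(tags) if tags else np.nan,
                "tags_per_block_max": max(tags) if tags else np.nan,
                "n_blocks": len(blocks),
                "mean_span_cm": float(np.mean(spans)) if spans else np.nan,
                "span_min_cm": min(spans) if spans else np.nan,
                "span_max_cm": max(spans) if spans else np.nan,
                "total_haplotypes": int(np.sum(haps)) if haps else 0,
                "mean_haplotypes": float(np.mean(haps)) if haps else np.nan,
                "haps_per_block_min": min(haps) if haps else np.nan,
                "haps_per_block_max": max(haps) if haps else np.nan,
            }
        )
    return pd.DataFrame(rows)


def aggregate_block_summary(
    per_chrom: pd.DataFrame, genome_of=None
) -> dict:
    """Genome-level aggregates of a per-chromosome block summary.

    Two kinds of means are emitted, clearly labelled:

    * block-count-**weighted** means (span and haplotypes per block pooled
      over all blocks), overall and per genome group;
    * the **unweighted** mean of the per-chromosome means (the convention of
      summary-table total rows).

    ``genome_of`` maps a chromosome label to its genome group; the default
    takes the trailing letter (``"1A" -> "A"``).
    """
    df = per_chrom
    if genome_of is None:
        genome_of = lambda chrom: str(chrom)[-1]
    total_snps = int(df["total_snps"].sum())
    total_blocks = int(df["n_blocks"].sum())
    out = {
        "total_snps": total_snps,
        "snps_in_blocks": int(df["snps_in_blocks"].sum()),
        "pct_snps_in_blocks": 100.0 * df["snps_in_blocks"].sum() / total_snps,
        "tag_snps": int(df["tag_snps"].sum()),
        "pct_tag_snps": 100.0 * df["tag_snps"].sum() / total_snps,
        "total_blocks": total_blocks,
        "total_haplotypes": int(df["total_haplotypes"].sum()),
        "mean_haplotypes_weighted": float(df["total_haplotypes"].sum() / total_blocks),
        "mean_span_cm_weighted": float(
            (df["mean_span_cm"] * df["n_blocks"]).sum() / total_blocks
        ),
        "mean_span_cm_unweighted": float(df["mean_span_cm"].mean()),
        "per_genome": {},
    }
    groups = df.assign(genome=[genome_of(c) for c in df["chrom"]]).groupby("genome")
    for genome, sub in groups:
        nb = int(sub["n_blocks"].sum())
        out["per_genome"][genome] = {
            "total_blocks": nb,
            "mean_span_cm_weighted": float(
                (sub["mean_span_cm"] * sub["n_blocks"]).sum() / nb
            ),
            "mean_span_cm_unweighted": float(sub["mean_span_cm"].mean()),
            "mean_haplotypes_weighted": float(sub["total_haplotypes"].sum() / nb),
        }
    return out
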