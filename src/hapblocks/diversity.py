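"""Gene diversity, PIC, Nei's Gst and the three-block sliding-window profile.

Gene diversity (expected heterozygosity) of a locus with allele frequencies
:math:`p_i` is :math:`H = 1 - \\sum_i p_i^2`.  The polymorphism information
content discounts indistinguishable matings:

.. math:: \\mathrm{PIC} = 1 - \\sum_i p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2.

Differentiation between populations is Nei's Gst,
:math:`(H_T - H_S)/H_T`, where :math:`H_S` is the mean within-population
diversity weighted by informative-line counts and :math:`H_T` the diversity
of the pooled frequencies.  Both work identically whether the "alleles" are
SNP alleles or block haplotypes (one haplotype treated as a single marker).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import Block, BlockHaplotypes
from .panel import GenotypePanel, PanelError, PopulationPartition

_SIMPLEX_TOL = 1e-9


def _check_simplex(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0 or (p < 0).any() or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise PanelError(f"frequencies must lie on the simplex, got {freqs}")
    return p


def gene_diversity(freqs) -> float:
    """1 - sum(p_i^2) for allele/haplotype frequencies on the simplex."""
    p = _check_simplex(freqs)
    return float(1.0 - np.sum(p * p))


def pic(freqs) -> float:
    """Botstein polymorphism information content."""
    p = _check_simplex(freqs)
    p2 = p * p
    cross = (np.sum(p2) ** 2 - np.sum(p2 * p2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(p2) - 2.0 * cross)


@dataclasses.dataclass(frozen=True)
class DifferentiationStat:
    locus: str
    hs: float
    ht: float
    gst: float  # NaN when Ht == 0
    n_per_pop: dict


def _counts_to_freqs(counts: Mapping[str, int]) -> np.ndarray:
    total = sum(counts.values())
    return np.array([c / total for c in counts.values()], dtype=float)


def differentiation_from_counts(
    locus: str, counts_per_pop: Mapping[str, Mapping[str, int]]
) -> DifferentiationStat:
    """Nei's Gst from per-population allele (or haplotype) counts.

    Populations are weighted by their informative-line counts both in
    :math:`H_S` and in the pooled frequencies, so :math:`H_T \\ge H_S`
    always holds.
    """
    pops = {p: dict(c) for p, c in counts_per_pop.items() if sum(c.values()) > 0}
    if len(pops) < 2:
        raise PanelError(f"locus {locus!r}: need >= 2 populations with data")
    sizes = {p: sum(c.values()) for p, c in pops.items()}
    total = sum(sizes.values())
    alleles = sorted({a for c in pops.values() for a in c})
    pooled = {a: sum(c.get(a, 0) for c in pops.values()) for a in alleles}
    ht = gene_diversity(_counts_to_freqs(pooled))
    hs = sum(
        sizes[p] / total * gene_diversity(
            np.array([c.get(a, 0) for a in alleles], float) / sizes[p]
        )
        for p, c in pops.items()
    )
    gst = (ht - hs) / ht if ht > 0 else np.nan
    return DifferentiationStat(locus, float(hs), float(ht), float(gst), sizes)


def _snp_counts(panel, partition, snp_id, het_as_missing=True):
    j = panel.snp_index(snp_id)
    x = panel.haploid_calls(het_as_missing)[:, j]
    idx = {l: i for i, l in enumerate(panel.line_ids)}
    out = {}
    for pop in partition.populations:
        vals = [x[idx[l]] for l in partition.lines_in(pop) if l in idx]
        vals = [v for v in vals if not np.isnan(v)]
        out[pop] = {"0": sum(1 for v in vals if v == 0),
                    "1": sum(1 for v in vals if v == 1)}
    return out


def fst_snp(
    panel: GenotypePanel,
    partition: PopulationPartition,
    snp_id: str,
    het_as_missing: bool = True,
) -> DifferentiationStat:
    """Gst of one SNP between the partition's populations."""
    partition.validate_against(panel)
    return differentiation_from_counts(
        snp_id, _snp_counts(panel, partition, snp_id, het_as_missing)
    )


def _block_counts(haplotypes: BlockHaplotypes, panel, partition):
    """Per-population haplotype counts, recomputed from each population's
    assigned lines only."""
    idx = {l: i for i, l in enumerate(panel.line_ids)}
    out = {}
    for pop in partition.populations:
        counts: dict[str, int] = {}
        for l in partition.lines_in(pop):
            a = haplotypes.assignments[idx[l]]
            if a > 0:
                counts[haplotypes.haplotypes[a - 1]] = counts.get(
                    haplotypes.haplotypes[a - 1], 0
                ) + 1
        out[pop] = counts
    return out


def fst_block(
    haplotypes: BlockHaplotypes,
    panel: GenotypePanel,
    partition: PopulationPartition,
) -> DifferentiationStat:
    """Gst of one block, treating each haplotype as a single allele."""
    partition.validate_against(panel)
    return differentiation_from_counts(
        haplotypes.block_id, _block_counts(haplotypes, panel, partition)
    )


def gst_scan(
    panel: GenotypePanel,
    partition: PopulationPartition,
    het_as_missing: bool = True,
) -> pd.DataFrame:
    """Per-SNP Hs/Ht/Gst across the whole panel (vectorised genome scan).

    Agrees locus-by-locus with :func:`fst_snp`; loci informative in fewer
    than two populations, or with Ht = 0, get NaN."""
    partition.validate_against(panel)
    x = panel.haploid_calls(het_as_missing)
    idx = {l: i for i, l in enumerate(panel.line_ids)}
    pops = partition.populations
    n_k = np.zeros((len(pops), panel.n_snps))
    p_k = np.zeros((len(pops), panel.n_snps))
    for r, pop in enumerate(pops):
        rows = [idx[l] for l in partition.lines_in(pop)]
        sub = x[rows]
        informative = ~np.isnan(sub)
        n_k[r] = informative.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_k[r] = np.where(
                n_k[r] > 0,
                np.where(informative, sub, 0.0).sum(axis=0) / np.maximum(n_k[r], 1),
                np.nan,
            )
    total = n_k.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.nansum(n_k * p_k, axis=0) / total
        ht = 2 * pooled * (1 - pooled)
        hs = np.nansum(n_k * 2 * p_k * (1 - p_k), axis=0) / total
        gst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    informative_pops = (n_k > 0).sum(axis=0)
    bad = informative_pops < 2
    for arr in (hs, ht, gst):
        arr[bad] = np.nan
    return pd.DataFrame(
        {"snp_id": list(panel.snp_ids), "hs": hs, "ht": ht, "gst": gst}
    )


def snp_diversity_table(
    panel: GenotypePanel, het_as_missing: bool = True
) -> pd.DataFrame:
    """Per-SNP gene diversity and PIC over the whole panel."""
    p = panel.allele_frequency(het_as_missing)
    rows = []
    for j, snp in enumerate(panel.snp_ids):
        if np.isnan(p[j]):
            rows.append((snp, np.nan, np.nan))
            continue
        freqs = np.array([1 - p[j], p[j]])
        rows.append((snp, gene_diversity(freqs), pic(freqs)))
    return pd.DataFrame(rows, columns=["snp_id", "gene_diversity", "pic"])


# --------------------------------------------------------------------------- #
# sliding windows


def _block_diversity_in_pop(haplotypes, panel, lines_idx) -> float:
    """Haplotype gene diversity of one block within a set of line indices
    (frequencies recomputed from those lines only); NaN with no assigned
    line."""
    counts: dict[int, int] = {}
    for i in lines_idx:
        a = haplotypes.assignments[i]
        if a > 0:
            counts[a] = counts.get(a, 0) + 1
    if not counts:
        return np.nan
    return gene_diversity(_counts_to_freqs({str(k): v for k, v in counts.items()}))


def sliding_window_profile(
    haplotypes: Mapping[str, BlockHaplotypes],
    blocks: Sequence[Block],
    panel: GenotypePanel,
    partition: PopulationPartition | None = None,
    population: str | None = None,
    window: int = 3,
    pooled: bool = False,
) -> pd.DataFrame:
    """Three-block sliding-window diversity profile along a chromosome.

    Windows of ``window`` consecutive blocks are shifted one block at a time
    from the short arm to the long arm; the per-window index is the
    arithmetic mean of the blocks' haplotype gene diversities computed within
    the named population (or the whole panel).  With ``pooled=True`` the
    alternative pooled index — the gene diversity of the concatenated
    haplotype classes of the window's blocks — is returned instead.

    Fewer than ``window`` blocks yields an empty profile.
    """
    if population is None:
        lines_idx = list(range(panel.n_lines))
    else:
        if partition is None:
            raise PanelError("a partition is required to select a population")
        partition.validate_against(panel)
        idx = {l: i for i, l in enumerate(panel.line_ids)}
        lines_idx = [idx[l] for l in partition.lines_in(population)]
    blocks = sorted(blocks, key=lambda b: b.first)
    mids = {
        b.block_id: float(np.mean(panel.positions_cm(b.snp_ids))) for b in blocks
    }
    rows = []
    for w in range(max(0, len(blocks) - window + 1)):
        chunk = blocks[w : w + window]
        if pooled:
            counts: dict[str, int] = {}
            for b in chunk:
                h = haplotypes[b.block_id]
                for i in lines_idx:
                    a = h.assignments[i]
                    if a > 0:
                        key = f"{b.block_id}:{a}"
                        counts[key] = counts.get(key, 0) + 1
            div = gene_diversity(_counts_to_freqs(counts)) if counts else np.nan
        else:
            vals = [
                _block_diversity_in_pop(haplotypes[b.block_id], panel, lines_idx)
                for b in chunk
            ]
            div = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan
        rows.append(
            {
                "window": w + 1,
                "first_block": chunk[0].block_id,
                "last_block": chunk[-1].block_id,
                "midpoint_cm": float(np.mean([mids[b.block_id] for b in chunk])),
                "diversity": div,
            }
        )
    return pd.DataFrame(rows, columns=["window", "first_block", "last_block",
                                       "midpoint_cm", "diversity"])
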