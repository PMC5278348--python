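r"""Pairwise linkage disequilibrium on inbred panels.

Because every line is homozygous, two-locus haplotype frequencies are read
directly off the genotype matrix (no EM phasing): a line homozygous for
alleles ``A`` and ``B`` at two SNPs carries haplotype ``AB``.  From the
haplotype counts,

.. math::

    D      = p_{AB} - p_A p_B \\
    D'     = |D| / D_{max} \\
    r^2    = D^2 / (p_A p_a p_B p_b)

with :math:`D_{max} = \min(p_A p_b,\, p_a p_B)` when :math:`D > 0` and
:math:`\min(p_A p_B,\, p_a p_b)` otherwise.  ``|D'|`` (unsigned) is used
throughout, matching the display convention of the block-building rule
("extend spine if D' > 0.8"), which is sign-free.

Missing calls are handled by pairwise-complete deletion; the number of
informative lines is recorded for audit.  Pairs with too few informative
lines (default < 5) are flagged uninformative — D' is unstable at tiny
counts — and treated as failing the spine threshold by block detection.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError

#: default minimum informative lines for a pair to count as informative
MIN_INFORMATIVE = 5


@dataclasses.dataclass(frozen=True)
class LDStatistic:
    """LD between one SNP pair; ``dprime``/``r2`` are NaN when undefined
    (a locus monomorphic among the informative lines)."""

    snp_i: str
    snp_j: str
    dprime: float
    r2: float
    n_informative: int
    distance_cm: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.dprime)


def _dprime_r2_from_counts(n00, n01, n10, n11):
    """|D'| and r2 from two-locus haplotype counts (alleles coded 0/1).

    Returns (dprime, r2, n); NaNs when either locus is monomorphic.
    """
    n = n00 + n01 + n10 + n11
    if n == 0:
        return np.nan, np.nan, 0
    pA = (n10 + n11) / n  # allele 1 at locus i
    pB = (n01 + n11) / n  # allele 1 at locus j
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return np.nan, np.nan, n
    d = n11 / n - pA * pB
    if d > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(d) / dmax
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    return min(dprime, 1.0), min(r2, 1.0), n


def pairwise_ld(
    panel: GenotypePanel,
    snp_i: str,
    snp_j: str,
    het_as_missing: bool = True,
) -> LDStatistic:
    """LD statistics for one SNP pair, pairwise-complete over the lines."""
    ji, jj = panel.snp_index(snp_i), panel.snp_index(snp_j)
    x = panel.haploid_calls(het_as_missing)
    xi, xj = x[:, ji], x[:, jj]
    ok = ~np.isnan(xi) & ~np.isnan(xj)
    xi, xj = xi[ok], xj[ok]
    n11 = int(np.sum((xi == 1) & (xj == 1)))
    n10 = int(np.sum((xi == 1) & (xj == 0)))
    n01 = int(np.sum((xi == 0) & (xj == 1)))
    n00 = int(np.sum((xi == 0) & (xj == 0)))
    dprime, r2, n = _dprime_r2_from_counts(n00, n01, n10, n11)
    cm = panel.positions_cm([snp_i, snp_j])
    return LDStatistic(snp_i, snp_j, dprime, r2, n, float(abs(cm[1] - cm[0])))


def dprime_matrix(
    panel: GenotypePanel,
    chromosome: str,
    het_as_missing: bool = True,
    min_informative: int = MIN_INFORMATIVE,
):
    """All-pairs |D'| for one chromosome.

    Returns ``(snp_ids, D, R2, N)`` where ``D``/``R2`` are S x S symmetric
    arrays with NaN on uninformative or undefined pairs and ``N`` the
    informative-line counts.  Vectorised with four boolean cross-products so
    whole chromosomes are cheap.
    """
    idx = panel.chrom_snp_indices(chromosome)
    snp_ids = [panel.snp_ids[j] for j in idx]
    x = panel.haploid_calls(het_as_missing)[:, idx]
    one = (x == 1).astype(np.float64)
    zero = (x == 0).astype(np.float64)
    n11 = one.T @ one
    n10 = one.T @ zero
    n01 = zero.T @ one
    n00 = zero.T @ zero
    n = n00 + n01 + n10 + n11
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (n10 + n11) / n
        pB = (n01 + n11) / n
        d = n11 / n - pA * pB
        dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
        dmax_neg = np.minimum(pA * pB, (1 - pA) * (1 - pB))
        dmax = np.where(d > 0, dmax_pos, dmax_neg)
        dprime = np.where(dmax > 0, np.abs(d) / dmax, 0.0)
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    poly = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    bad = ~poly | (n < min_informative)
    dprime = np.where(bad, np.nan, np.minimum(dprime, 1.0))
    r2 = np.where(bad, np.nan, np.minimum(r2, 1.0))
    np.fill_diagonal(dprime, np.nan)
    np.fill_diagonal(r2, np.nan)
    return snp_ids, dprime, r2, n.astype(int)


def ld_matrix(
    panel: GenotypePanel,
    chromosome: str,
    max_distance_cm: float | None = None,
    het_as_missing: bool = True,
    min_informative: int = 0,
) -> pd.DataFrame:
    """All SNP pairs on a chromosome (optionally distance-capped) as a tidy
    DataFrame (snp_i, snp_j, distance_cm, dprime, r2, n_informative)."""
    snp_ids, dp, r2, n = dprime_matrix(
        panel, chromosome, het_as_missing, min_informative=max(min_informative, 0)
    )
    cm = panel.positions_cm(snp_ids)
    rows = []
    for a in range(len(snp_ids)):
        for b in range(a + 1, len(snp_ids)):
            dist = abs(cm[b] - cm[a])
            if max_distance_cm is not None and dist > max_distance_cm:
                continue
            rows.append(
                (snp_ids[a], snp_ids[b], dist, dp[a, b], r2[a, b], n[a, b])
            )
    return pd.DataFrame(
        rows, columns=["snp_i", "snp_j", "distance_cm", "dprime", "r2", "n_informative"]
    )


def ld_decay_profile(
    stats: pd.DataFrame | Iterable[LDStatistic], bin_width_cm: float
) -> pd.DataFrame:
    """Mean r2 per distance bin [k*w, (k+1)*w).

    Bins with no pairs are absent from the output (reported empty, not zero).
    """
    if bin_width_cm <= 0:
        raise PanelError(f"bin width must be positive, got {bin_width_cm}")
    if isinstance(stats, pd.DataFrame):
        dist = stats["distance_cm"].to_numpy(dtype=float)
        r2 = stats["r2"].to_numpy(dtype=float)
    else:
        stats = list(stats)
        dist = np.array([s.distance_cm for s in stats], dtype=float)
        r2 = np.array([s.r2 for s in stats], dtype=float)
    if dist.size == 0:
        raise PanelError("no LD statistics to bin")
    ok = np.isfinite(r2)
    dist, r2 = dist[ok], r2[ok]
    bins = np.floor(dist / bin_width_cm).astype(int)
    rows = []
    for b in sorted(set(bins.tolist())):
        sel = bins == b
        rows.append(
            (b * bin_width_cm, (b + 1) * bin_width_cm, float(np.mean(r2[sel])),
             int(np.sum(sel)))
        )
    return pd.DataFrame(rows, columns=["bin_start_cm", "bin_end_cm", "mean_r2", "n_pairs"])
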