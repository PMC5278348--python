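"""Mixed-linear-model association (Q + K, P3D) per SNP and per haplotype block.

The model for a phenotype vector :math:`y` over inbred lines is

.. math:: y = \\mu + Q\\gamma + M\\beta + u + e,
          \\quad u \\sim N(0, \\sigma_a^2 K), \\quad e \\sim N(0, \\sigma_e^2 I)

with structure covariates :math:`Q` (fixed), a marker design :math:`M` (one
dosage column for a SNP, haplotype-class indicators for a block) and kinship
:math:`K`.  Variance components are estimated **once** on the null model
(no marker) by REML over the ratio :math:`\\delta = \\sigma_e^2/\\sigma_a^2`
using an eigendecomposition of :math:`K` — the "population parameters
previously determined" (P3D) scheme — and reused for every marker, where the
test is an F-test on :math:`\\beta` under generalised least squares.

Significance is declared at :math:`P < 1/n` for *n* markers tested; the
threshold is reported rounded to two significant digits and its
:math:`-\\log_{10}` to two decimals (e.g. n = 4434 gives 2.3e-4 / 3.65,
n = 847 gives 1.2e-3 / 2.93).

The phenotypic variation explained by a marker is reported as the one-way
ANOVA ratio :math:`R^2 = SSA/SST` on the phenotype grouped by marker class,
computed outside the mixed model.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .blocks import Block, BlockHaplotypes
from .panel import GenotypePanel, PanelError
from .relatedness import KinshipMatrix

RARE_HAPLOTYPE_FREQ = 0.05


@dataclasses.dataclass(frozen=True)
class SignificanceRule:
    """The P < 1/n declaration rule for n markers."""

    n_markers: int
    threshold: float  # 1/n rounded to 2 significant digits
    neglog10: float  # -log10(1/n) rounded to 2 decimals

    def passes(self, p_value: float) -> bool:
        return p_value < self.threshold


def significance_rule(n_markers: int) -> SignificanceRule:
    if n_markers <= 0:
        raise PanelError("need a positive marker count")
    exact = 1.0 / n_markers
    return SignificanceRule(
        n_markers=n_markers,
        threshold=float(f"{exact:.1e}"),
        neglog10=round(-math.log10(exact), 2),
    )


def marker_r2(y, groups) -> float:
    """One-way ANOVA R^2 = SSA/SST of ``y`` grouped by marker class."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    ssa = 0.0
    for g in np.unique(groups):
        sub = y[groups == g]
        ssa += sub.size * (sub.mean() - y.mean()) ** 2
    return float(ssa / sst)


# --------------------------------------------------------------------------- #
# P3D machinery


@dataclasses.dataclass(frozen=True)
class P3DContext:
    """Null-model variance components plus the rotation reused per marker."""

    line_ids: tuple
    eigvecs: np.ndarray  # U, columns are eigenvectors of K
    eigvals: np.ndarray  # d >= 0
    delta: float  # sigma_e^2 / sigma_a^2
    sigma_a2: float
    sigma_e2: float
    y_rot: np.ndarray  # U' y
    x0_rot: np.ndarray  # U' [1, Q]
    y: np.ndarray
    x0: np.ndarray
    kinship: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / (self.eigvals + self.delta)


def _weighted_rss(x, y, w):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(sw[:, None] * x, sw * y, rcond=None)
    resid = y - x @ beta
    return float(np.sum(w * resid * resid)), beta


def _reml_neg_loglik(log_delta, d, yt, xt):
    delta = math.exp(log_delta)
    w = 1.0 / (d + delta)
    n, p = xt.shape
    rss, _ = _weighted_rss(xt, yt, w)
    sigma_a2 = rss / (n - p)
    xtwx = xt.T @ (w[:, None] * xt)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0 or sigma_a2 <= 0:
        return np.inf
    _, logdet_xtx = np.linalg.slogdet(xt.T @ xt)
    ll = -0.5 * (
        (n - p) * (math.log(2 * math.pi * sigma_a2) + 1)
        + np.sum(np.log(d + delta))
        + logdet_xtwx
        - logdet_xtx
    )
    return -ll


def p3d_null(
    y: np.ndarray,
    covariates: np.ndarray | None,
    kinship: np.ndarray,
    line_ids: Sequence[str],
) -> P3DContext:
    """Estimate the null-model variance components once (P3D).

    ``covariates`` excludes the intercept (added here).  ``kinship`` must be
    positive semi-definite up to numerical jitter; slightly negative
    eigenvalues are clipped to zero with a warning, larger violations raise.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.var(y) == 0:
        raise PanelError("zero-variance phenotype")
    x0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        x0 = np.column_stack([x0, np.asarray(covariates, dtype=float)])
    k = np.asarray(kinship, dtype=float)
    if k.shape != (n, n):
        raise PanelError(f"kinship shape {k.shape} does not match n={n}")
    if not np.isfinite(k).all():
        raise PanelError("kinship contains non-finite entries")
    k = (k + k.T) / 2.0
    d, u = np.linalg.eigh(k)
    if d.min() < -1e-8 * max(1.0, float(d.max())):
        # zero-clipped kinship estimates are routinely indefinite; bend to the
        # nearest PSD matrix by clipping negative eigenvalues
        warnings.warn(
            f"bending kinship to PSD (min eigenvalue {d.min():.3g} clipped to 0)",
            stacklevel=2,
        )
    d = np.clip(d, 0.0, None)
    k = (u * d) @ u.T
    yt = u.T @ y
    xt = u.T @ x0
    grid = np.linspace(-10.0, 10.0, 61)
    vals = [_reml_neg_loglik(g, d, yt, xt) for g in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(d, yt, xt), method="bounded",
        options={"xatol": 1e-10},
    )
    delta = math.exp(float(res.x))
    w = 1.0 / (d + delta)
    rss, _ = _weighted_rss(xt, yt, w)
    sigma_a2 = rss / (n - x0.shape[1])
    return P3DContext(
        line_ids=tuple(line_ids),
        eigvecs=u,
        eigvals=d,
        delta=delta,
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_a2 * delta),
        y_rot=yt,
        x0_rot=xt,
        y=y,
        x0=x0,
        kinship=k,
    )


@dataclasses.dataclass(frozen=True)
class MLMFit:
    f_stat: float
    p_value: float
    df1: int
    df2: int
    effects: np.ndarray  # marker-column coefficients


def mlm_fit(context: P3DContext, marker: np.ndarray) -> MLMFit:
    """F-test on the marker columns with P3D variance components.

    ``marker`` is (n,) or (n, q); rows with NaN are omitted for this marker
    (exact GLS on the line subset, with the ratio delta held fixed).
    """
    m = np.asarray(marker, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    missing = np.isnan(m).any(axis=1)
    if not missing.any():
        w = context.weights
        mt = context.eigvecs.T @ m
        x_full = np.column_stack([context.x0_rot, mt])
        rss1, beta = _weighted_rss(x_full, context.y_rot, w)
        rss0, _ = _weighted_rss(context.x0_rot, context.y_rot, w)
        n = context.n
    else:
        keep = ~missing
        n = int(keep.sum())
        v = context.kinship[np.ix_(keep, keep)] + context.delta * np.eye(n)
        d, u = np.linalg.eigh(v)
        d = np.clip(d, 1e-12, None)
        w = 1.0 / d
        yt = u.T @ context.y[keep]
        x0t = u.T @ context.x0[keep]
        mt = u.T @ m[keep]
        x_full = np.column_stack([x0t, mt])
        rss1, beta = _weighted_rss(x_full, yt, w)
        rss0, _ = _weighted_rss(x0t, yt, w)
    q = m.shape[1]
    df2 = n - context.x0.shape[1] - q
    if df2 <= 0:
        raise PanelError("not enough lines for the marker test")
    num = max(rss0 - rss1, 0.0) / q
    den = rss1 / df2
    f = num / den if den > 0 else np.inf
    p = float(stats.f.sf(f, q, df2)) if np.isfinite(f) else 0.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return MLMFit(float(f), p, q, df2, beta[-q:])


# --------------------------------------------------------------------------- #
# alignment helpers


def _align(panel: GenotypePanel, phenotype: pd.Series,
           covariates: pd.DataFrame | None, kinship: KinshipMatrix | None):
    pheno = phenotype.dropna()
    lines = [l for l in panel.line_ids if l in set(pheno.index)]
    if kinship is not None:
        have = set(kinship.line_ids)
        lines = [l for l in lines if l in have]
    if covariates is not None:
        have = set(covariates.index)
        lines = [l for l in lines if l in have]
    if len(lines) < 3:
        raise PanelError("fewer than 3 lines shared by phenotype/genotype inputs")
    y = pheno.loc[lines].to_numpy(dtype=float)
    qmat = None if covariates is None else covariates.loc[lines].to_numpy(dtype=float)
    if kinship is None:
        kmat = np.eye(len(lines))
    else:
        pos = {l: i for i, l in enumerate(kinship.line_ids)}
        idx = [pos[l] for l in lines]
        kmat = kinship.values[np.ix_(idx, idx)]
    return lines, y, qmat, kmat


# --------------------------------------------------------------------------- #
# SNP GWAS


def snp_gwas(
    panel: GenotypePanel,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    kinship: KinshipMatrix | None = None,
    maf: float = 0.05,
    trait: str = "trait",
    environment: str = "BLUP",
    higher_is_favorable: bool = True,
    het_as_missing: bool = True,
) -> tuple[pd.DataFrame, SignificanceRule]:
    """Single-SNP mixed-model scan.

    Markers are biallelic 0/1 dosages over the inbred lines; heterozygous
    and missing calls are omitted per marker.  Monomorphic markers and
    markers below the MAF threshold are excluded, and the P < 1/n rule uses
    n = markers actually tested.
    """
    lines, y, qmat, kmat = _align(panel, phenotype, covariates, kinship)
    sub = panel.subset(lines=lines)
    x = sub.haploid_calls(het_as_missing)
    with np.errstate(invalid="ignore"):
        p_all = np.nanmean(x, axis=0)
    mafs = np.minimum(p_all, 1 - p_all)
    testable = np.flatnonzero(np.nan_to_num(mafs, nan=-1) >= maf)
    testable = [j for j in testable if 0 < p_all[j] < 1]
    if not testable:
        raise PanelError("no marker passes the MAF filter among phenotyped lines")
    context = p3d_null(y, qmat, kmat, lines)
    rows = []
    for j in testable:
        dosage = x[:, j]
        fit = mlm_fit(context, dosage)
        ok = ~np.isnan(dosage)
        r2 = marker_r2(y[ok], dosage[ok])
        effect = float(fit.effects[0])
        if higher_is_favorable:
            favorable = 1 if effect > 0 else 0
        else:
            favorable = 1 if effect < 0 else 0
        alleles = sub.alleles[j] if sub.alleles is not None else ("0", "1")
        rows.append(
            {
                "marker": sub.snp_ids[j],
                "trait": trait,
                "environment": environment,
                "chrom": sub.genetic_map.iloc[j]["chrom"],
                "cm": float(sub.genetic_map.iloc[j]["cm"]),
                "f_stat": fit.f_stat,
                "p_value": fit.p_value,
                "neglog10p": -math.log10(fit.p_value),
                "r2": r2,
                "effect": effect,
                "effects": f"{alleles[1]}:{effect:+.6g}",
                "favorable": str(alleles[favorable]),
                "n_lines": int(ok.sum()),
            }
        )
    result = pd.DataFrame(rows)
    rule = significance_rule(len(result))
    result["significant"] = result["p_value"] < rule.threshold
    return result, rule


# --------------------------------------------------------------------------- #
# haplotype GWAS


def _block_classes(haps: BlockHaplotypes, line_idx: np.ndarray,
                   rare_freq: float):
    """Per-line haplotype class labels among assigned lines, with rare
    haplotypes (< rare_freq among assigned phenotyped lines) pooled into
    'other'.  Returns (labels array with None for unassigned, class order
    by descending count)."""
    assign = haps.assignments[line_idx]
    assigned = assign > 0
    n = int(assigned.sum())
    labels = np.array([None] * line_idx.size, dtype=object)
    if n == 0:
        return labels, []
    counts: dict[int, int] = {}
    for a in assign[assigned]:
        counts[int(a)] = counts.get(int(a), 0) + 1
    rare = {a for a, c in counts.items() if c / n < rare_freq}
    for i in np.flatnonzero(assigned):
        a = int(assign[i])
        labels[i] = "other" if a in rare else str(a)
    merged: dict[str, int] = {}
    for lbl in labels[assigned]:
        merged[lbl] = merged.get(lbl, 0) + 1
    # most common first; 'other' ranks after named classes on count ties
    order = sorted(merged, key=lambda l: (-merged[l], l == "other", l))
    return labels, order


def haplotype_gwas(
    haplotypes: Mapping[str, BlockHaplotypes],
    blocks: Sequence[Block],
    phenotype: pd.Series,
    panel: GenotypePanel,
    covariates: pd.DataFrame | None = None,
    kinship: KinshipMatrix | None = None,
    maf: float = 0.05,
    rare_freq: float = RARE_HAPLOTYPE_FREQ,
    trait: str = "trait",
    environment: str = "BLUP",
    higher_is_favorable: bool = True,
) -> tuple[pd.DataFrame, SignificanceRule]:
    """Haplotype-block mixed-model scan.

    A block's MAF is the frequency of its second-most-common haplotype among
    the phenotyped, assigned lines; blocks below the threshold are excluded
    (n in the P < 1/n rule counts tested blocks).  Haplotypes rarer than
    ``rare_freq`` are pooled into an 'other' class; the block is coded as
    indicator columns against the most common haplotype (baseline) and
    tested jointly by F-test.  The favorable haplotype is the class with the
    largest trait-increasing effect (or decreasing, per trait orientation).
    """
    lines, y, qmat, kmat = _align(panel, phenotype, covariates, kinship)
    pos = {l: i for i, l in enumerate(panel.line_ids)}
    line_idx = np.array([pos[l] for l in lines])
    context = p3d_null(y, qmat, kmat, lines)

    candidates = []
    for block in sorted(blocks, key=lambda b: (b.chromosome, b.first)):
        haps = haplotypes[block.block_id]
        if haps.n_assigned == 0:
            continue
        labels, order = _block_classes(haps, line_idx, rare_freq)
        if len(order) < 2:
            continue
        assigned = labels != None  # noqa: E711  (elementwise object compare)
        counts = pd.Series(labels[assigned]).value_counts()
        freqs = counts / counts.sum()
        if float(freqs.iloc[1]) < maf:  # block MAF: 2nd most common class
            continue
        candidates.append((block, haps, labels, order))
    if not candidates:
        raise PanelError("no block passes the MAF filter among phenotyped lines")

    rows = []
    for block, haps, labels, order in candidates:
        baseline = order[0]
        others = order[1:]
        design = np.full((line_idx.size, len(others)), np.nan)
        for i, lbl in enumerate(labels):
            if lbl is None:
                continue
            design[i] = [1.0 if lbl == o else 0.0 for o in others]
        fit = mlm_fit(context, design)
        ok = labels != None  # noqa: E711
        r2 = marker_r2(y[ok], labels[ok].astype(str))
        effects = {baseline: 0.0}
        effects.update({o: float(b) for o, b in zip(others, fit.effects)})
        sign = 1.0 if higher_is_favorable else -1.0
        favorable = max(effects, key=lambda c: sign * effects[c])
        fav_label = (
            "other" if favorable == "other" else haps.haplotype_label(int(favorable))
        )
        cm = panel.positions_cm(block.snp_ids)
        rows.append(
            {
                "marker": block.block_id,
                "trait": trait,
                "environment": environment,
                "chrom": block.chromosome,
                "cm": float(np.mean(cm)),
                "n_classes": len(order),
                "f_stat": fit.f_stat,
                "p_value": fit.p_value,
                "neglog10p": -math.log10(fit.p_value),
                "r2": r2,
                "effects": ";".join(
                    f"{c if c == 'other' else haps.haplotype_label(int(c))}:"
                    f"{effects[c]:+.6g}"
                    for c in order
                ),
                "favorable": fav_label,
                "n_lines": int(ok.sum()),
            }
        )
    result = pd.DataFrame(rows)
    rule = significance_rule(len(result))
    result["significant"] = result["p_value"] < rule.threshold
    return result, rule
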