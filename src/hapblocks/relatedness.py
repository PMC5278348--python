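"""Loiselle kinship, PCA structure covariates, and multi-environment BLUP.

The kinship coefficient between lines *i* and *j* follows the Loiselle
moment estimator, averaged over loci (pairwise-complete on missing data):

.. math::

    f_{ij} = \\frac{\\sum_l \\big[(x_{il} - p_l)(x_{jl} - p_l)
                    + p_l (1 - p_l) / (n_l - 1)\\big]}
                  {\\sum_l p_l (1 - p_l)}

where :math:`x_{il} \\in \\{0, 1\\}` is the line's haploid-equivalent allele
state, :math:`p_l` the panel allele frequency and :math:`n_l` the number of
informative lines at locus *l* (the second term is the small-sample bias
correction).  Negative pair estimates are set to 0 — less related than two
random lines carries no information for the mixed model — and the diagonal
is set to 1 by convention (the estimator is defined for pairs).

Population structure covariates are the top principal-component scores of
the centred allele-dosage matrix; they stand in for model-based ancestry
proportions as fixed covariates in the Q+K association model.

Multi-environment genotypic values are REML BLUPs from the model

    value = grand mean + environment (fixed) + line (random) + error

with broad-sense heritability h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .panel import GenotypePanel, PanelError, validate_phenotypes


@dataclasses.dataclass(frozen=True)
class KinshipMatrix:
    line_ids: tuple
    values: np.ndarray  # symmetric, clipped at 0, diagonal 1
    diagonal_convention: str = "unity"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def loiselle_kinship(panel: GenotypePanel, het_as_missing: bool = True) -> KinshipMatrix:
    """Pairwise Loiselle kinship over all polymorphic SNPs."""
    x = panel.haploid_calls(het_as_missing)
    p = np.nanmean(x, axis=0)
    n_l = np.sum(~np.isnan(x), axis=0).astype(float)
    poly = (p > 0) & (p < 1) & (n_l >= 2)
    if not poly.any():
        raise PanelError("no polymorphic SNP with >= 2 informative lines")
    x = x[:, poly]
    p = p[poly]
    n_l = n_l[poly]
    pq = p * (1 - p)
    corr = pq / (n_l - 1.0)
    mask = (~np.isnan(x)).astype(float)
    z = np.nan_to_num(x - p, nan=0.0)
    num = z @ z.T + mask @ (corr[:, None] * mask.T)
    den = mask @ (pq[:, None] * mask.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = num / den
    k = np.where(den > 0, k, 0.0)
    k = (k + k.T) / 2.0
    k = np.clip(k, 0.0, None)  # negatives -> 0
    np.fill_diagonal(k, 1.0)
    return KinshipMatrix(tuple(panel.line_ids), k)


def pca_covariates(panel: GenotypePanel, q: int, het_as_missing: bool = True) -> pd.DataFrame:
    """Top-``q`` principal-component scores of the centred dosage matrix.

    Missing dosages are mean-imputed for the decomposition only.  Columns
    have mean zero by construction; returned as a DataFrame indexed by line.
    """
    if q <= 0:
        raise PanelError(f"q must be positive, got {q}")
    if q >= min(panel.n_lines, panel.n_snps):
        raise PanelError(f"q={q} must be < min(n_lines, n_snps)")
    x = panel.haploid_calls(het_as_missing)
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    filled = np.where(np.isnan(x), col_mean, x)
    centred = filled - filled.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = u[:, :q] * s[:q]
    scores -= scores.mean(axis=0)
    return pd.DataFrame(
        scores, index=list(panel.line_ids), columns=[f"PC{k+1}" for k in range(q)]
    )


@dataclasses.dataclass(frozen=True)
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        total = self.sigma_a2 + self.sigma_e2
        return float(self.sigma_a2 / total) if total > 0 else np.nan


def blup_across_envs(
    phenotypes: pd.DataFrame, trait: str
) -> tuple[pd.Series, VarianceComponents]:
    """REML BLUPs of line genotypic value across environments for one trait.

    Returns (blups indexed by line, variance components).  Lines never
    observed for the trait are absent from the result.  The degenerate
    single-observation-per-line design (one environment, no replicates) is
    not REML-identifiable; there the no-shrinkage limit (sigma_e2 -> 0,
    BLUP = centred observation) is returned with a warning.
    """
    table = validate_phenotypes(phenotypes)
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise PanelError(f"no records for trait {trait!r}")
    if sub["line"].nunique() < 2:
        raise PanelError("need >= 2 lines with observations")
    counts = sub.groupby("line").size()
    if counts.max() == 1 and sub["environment"].nunique() == 1:
        warnings.warn(
            "one observation per line in a single environment: variance "
            "components are not identifiable; returning centred observations "
            "(sigma_e2 -> 0 limit)",
            stacklevel=2,
        )
        vals = sub.set_index("line")["value"]
        blups = vals - vals.mean()
        return blups, VarianceComponents(float(vals.var(ddof=1)), 0.0)
    data = sub.rename(columns={"environment": "env"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(env)", data, groups=data["line"])
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:
            raise PanelError("mixed-model REML failed to converge")
    sigma_a2 = float(np.asarray(fit.cov_re)[0, 0])
    sigma_e2 = float(fit.scale)
    re = fit.random_effects
    blups = pd.Series({line: float(np.asarray(v)[0]) for line, v in re.items()})
    blups.index.name = "line"
    return blups.sort_index(), VarianceComponents(sigma_a2, sigma_e2)


def blup_table(phenotypes: pd.DataFrame, traits=None) -> pd.DataFrame:
    """BLUPs for several traits side by side (lines x traits)."""
    table = validate_phenotypes(phenotypes)
    if traits is None:
        traits = sorted(table["trait"].unique())
    cols = {}
    for t in traits:
        cols[t], _ = blup_across_envs(table, t)
    return pd.DataFrame(cols)
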