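"""Canned whole-pipeline experiments on synthetic panels.

These bundle the study-shaped simulation scenarios with the full analysis
chain (kinship, PCA covariates, block detection, per-SNP and per-block
mixed-model scans) so that calibration and power properties can be measured
reproducibly from a single seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .association import haplotype_gwas, snp_gwas
from .blocks import detect_blocks_genome, enumerate_haplotypes
from .relatedness import loiselle_kinship, pca_covariates
from .simulate import (
    haplotype_power_scenario,
    null_gwas_scenario,
    simulate_panel,
    simulate_phenotypes,
)


def type_i_error(seed: int, n_markers: int = 2000, alpha: float = 0.05) -> dict:
    """Fraction of markers below ``alpha`` in a null structured-panel scan.

    Simulates two differentiated subpopulations with a polygenic phenotype
    and no QTL, then runs the Q + K mixed-model SNP scan.  A calibrated test
    keeps the fraction near ``alpha``.
    """
    config = null_gwas_scenario(seed, n_markers=n_markers)
    panel, _, truth = simulate_panel(config)
    pheno, _ = simulate_phenotypes(panel, truth, config)
    y = pheno.set_index("line")["value"]
    kinship = loiselle_kinship(panel)
    covariates = pca_covariates(panel, 1)
    result, _ = snp_gwas(panel, y, covariates, kinship, maf=0.05)
    return {
        "fraction_below_alpha": float((result["p_value"] < alpha).mean()),
        "n_tested": len(result),
        "alpha": alpha,
    }


@dataclasses.dataclass(frozen=True)
class BlockPowerResult:
    block_p: float
    member_snp_p: float
    block_threshold: float
    snp_threshold: float

    @property
    def block_significant(self) -> bool:
        return self.block_p < self.block_threshold

    @property
    def member_snp_significant(self) -> bool:
        return self.member_snp_p < self.snp_threshold

    @property
    def success(self) -> bool:
        """Block found, no member SNP over its own genome-wide bar."""
        return self.block_significant and not self.member_snp_significant


def block_power_replicate(seed: int) -> BlockPowerResult:
    """One replicate of the block-beats-SNP experiment.

    Simulates the planted 3-haplotype causal-block panel, detects blocks
    from scratch, runs both scans, and reports the causal block's p-value
    against the block-count P < 1/n rule and the best member-SNP p-value
    against the SNP-count rule.
    """
    config = haplotype_power_scenario(seed)
    panel, _, truth = simulate_panel(config)
    pheno, _ = simulate_phenotypes(panel, truth, config)
    y = pheno.set_index("line")["value"]
    kinship = loiselle_kinship(panel)
    covariates = pca_covariates(panel, 1)
    by_chrom = detect_blocks_genome(panel)
    flat = [b for bs in by_chrom.values() for b in bs]
    haps = enumerate_haplotypes(panel, flat)
    causal_snps = set(truth["blocks"][0]["snp_ids"])
    hres, hrule = haplotype_gwas(haps, flat, y, panel, covariates, kinship)
    sres, srule = snp_gwas(panel, y, covariates, kinship)
    causal_ids = [b.block_id for b in flat if causal_snps & set(b.snp_ids)]
    return BlockPowerResult(
        block_p=float(hres[hres["marker"].isin(causal_ids)]["p_value"].min()),
        member_snp_p=float(sres[sres["marker"].isin(causal_snps)]["p_value"].min()),
        block_threshold=hrule.threshold,
        snp_threshold=srule.threshold,
    )


def block_power_rate(seeds) -> float:
    """Fraction of replicates where the causal block beats its member SNPs."""
    results = [block_power_replicate(int(s)) for s in seeds]
    return float(np.mean([r.success for r in results]))
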