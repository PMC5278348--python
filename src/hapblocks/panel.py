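"""Core data containers for inbred-line SNP panels.

A :class:`GenotypePanel` holds biallelic SNP calls for a set of homozygous
inbred lines together with a genetic map (chromosome, position in cM).  Calls
are stored as small integer codes per (line, SNP):

====  =======================================
code  meaning
====  =======================================
0     homozygous for the first allele
1     homozygous for the second allele
2     heterozygous
-1    missing
====  =======================================

The panel is the substrate of every downstream stage (LD, block detection,
diversity, kinship, GWAS, painting).  Because the lines are fully inbred,
each line carries a single independent haplotype per locus: frequencies count
every line once ("haploid-equivalent" convention) and heterozygous calls —
rare artefacts on such material — are treated as missing by default wherever a
phase-free haplotype is required.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CALL_A0 = 0
CALL_A1 = 1
CALL_HET = 2
CALL_MISSING = -1

_VALID_CODES = frozenset({CALL_A0, CALL_A1, CALL_HET, CALL_MISSING})


class PanelError(ValueError):
    """Raised for malformed genotype panels or invalid panel operations."""


@dataclasses.dataclass(frozen=True)
class GenotypePanel:
    """Lines x SNPs allele-call matrix with a genetic map.

    Parameters
    ----------
    line_ids :
        Ordered line names (unique).
    snp_ids :
        Ordered SNP names (unique), sorted by (chromosome, cM, snp_id).
    calls :
        ``(n_lines, n_snps)`` int8 matrix of call codes.
    genetic_map :
        DataFrame indexed by snp_id with columns ``chrom`` (str) and
        ``cm`` (float); one row per SNP (a SNP mapping to two chromosomes
        is rejected).
    alleles :
        Optional ``(n_snps, 2)`` array of allele symbols; purely cosmetic
        (codes are authoritative).
    """

    line_ids: tuple
    snp_ids: tuple
    calls: np.ndarray
    genetic_map: pd.DataFrame
    alleles: np.ndarray | None = None

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if len(set(self.line_ids)) != len(self.line_ids):
            raise PanelError("duplicate line ids")
        dup = pd.Index(self.snp_ids).duplicated()
        if dup.any():
            first = self.snp_ids[int(np.flatnonzero(dup)[0])]
            raise PanelError(f"duplicate SNP id: {first!r}")
        if calls.shape != (len(self.line_ids), len(self.snp_ids)):
            raise PanelError(
                f"calls shape {calls.shape} != "
                f"({len(self.line_ids)}, {len(self.snp_ids)})"
            )
        bad = ~np.isin(calls, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"invalid call code {calls[i, j]} at line "
                f"{self.line_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )
        gmap = self.genetic_map
        if not isinstance(gmap, pd.DataFrame) or not {"chrom", "cm"} <= set(gmap.columns):
            raise PanelError("genetic_map must have columns 'chrom' and 'cm'")
        if set(gmap.index) != set(self.snp_ids) or len(gmap) != len(self.snp_ids):
            raise PanelError("genetic_map must have exactly one row per SNP")
        gmap = gmap.loc[list(self.snp_ids), ["chrom", "cm"]].copy()
        gmap.index.name = None
        gmap["cm"] = gmap["cm"].astype(float)
        gmap["chrom"] = gmap["chrom"].astype(str)
        if not np.isfinite(gmap["cm"].to_numpy()).all():
            raise PanelError("non-finite cM position in genetic map")
        object.__setattr__(self, "genetic_map", gmap)
        # map order invariant: within each chromosome, cM non-decreasing
        for chrom, sub in gmap.groupby("chrom", sort=False):
            cm = sub["cm"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise PanelError(f"SNPs on chromosome {chrom} not sorted by cM")

    # ------------------------------------------------------------------ #
    # construction helpers

    @classmethod
    def from_unsorted(
        cls,
        line_ids: Sequence[str],
        snp_ids: Sequence[str],
        calls: np.ndarray,
        genetic_map: pd.DataFrame,
        alleles: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Build a panel, sorting SNPs by (chromosome, cM, snp_id)."""
        snp_ids = list(snp_ids)
        dup = pd.Index(snp_ids).duplicated()
        if dup.any():
            raise PanelError(f"duplicate SNP id: {snp_ids[int(np.flatnonzero(dup)[0])]!r}")
        missing = [s for s in snp_ids if s not in genetic_map.index]
        if missing:
            raise PanelError(f"unmapped SNP: {missing[0]!r}")
        gmap = genetic_map.loc[snp_ids]
        order = np.lexsort(
            (np.asarray(snp_ids), gmap["cm"].to_numpy(), gmap["chrom"].to_numpy())
        )
        snp_sorted = [snp_ids[k] for k in order]
        calls = np.asarray(calls, dtype=np.int8)[:, order]
        alle = None if alleles is None else np.asarray(alleles)[order]
        return cls(tuple(line_ids), tuple(snp_sorted), calls, gmap.loc[snp_sorted], alle)

    # ------------------------------------------------------------------ #
    # basic properties

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def chromosomes(self) -> tuple:
        """Chromosome labels in map order (first appearance)."""
        return tuple(dict.fromkeys(self.genetic_map["chrom"]))

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(line_id)
        except ValueError:
            raise PanelError(f"unknown line id {line_id!r}") from None

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise PanelError(f"unknown SNP id {snp_id!r}") from None

    def chrom_snp_indices(self, chromosome: str) -> np.ndarray:
        idx = np.flatnonzero((self.genetic_map["chrom"] == str(chromosome)).to_numpy())
        if idx.size == 0:
            raise PanelError(f"chromosome {chromosome!r} not present")
        return idx

    def positions_cm(self, snp_ids: Iterable[str] | None = None) -> np.ndarray:
        if snp_ids is None:
            return self.genetic_map["cm"].to_numpy()
        return self.genetic_map.loc[list(snp_ids), "cm"].to_numpy()

    # ------------------------------------------------------------------ #
    # views

    def subset(
        self,
        lines: Sequence[str] | None = None,
        snps: Sequence[str] | None = None,
    ) -> "GenotypePanel":
        """Sub-panel restricted to the given lines and/or SNPs (order kept as
        in the parent panel)."""
        li = (
            np.arange(self.n_lines)
            if lines is None
            else np.array([self.line_index(l) for l in lines])
        )
        if snps is None:
            sj = np.arange(self.n_snps)
        else:
            want = set(snps)
            sj = np.array([j for j, s in enumerate(self.snp_ids) if s in want])
            if sj.size != len(want):
                unknown = want - set(self.snp_ids)
                raise PanelError(f"unknown SNP id {sorted(unknown)[0]!r}")
        snp_sub = [self.snp_ids[j] for j in sj]
        return GenotypePanel(
            tuple(self.line_ids[i] for i in li),
            tuple(snp_sub),
            self.calls[np.ix_(li, sj)],
            self.genetic_map.loc[snp_sub],
            None if self.alleles is None else self.alleles[sj],
        )

    def haploid_calls(self, het_as_missing: bool = True) -> np.ndarray:
        """Float matrix with 0/1 haploid-equivalent calls and NaN elsewhere.

        Heterozygous calls become NaN when ``het_as_missing`` (the default for
        this selfing-crop data model) else 0.5.
        """
        x = self.calls.astype(float)
        x[self.calls == CALL_MISSING] = np.nan
        x[self.calls == CALL_HET] = np.nan if het_as_missing else 0.5
        return x

    # ------------------------------------------------------------------ #
    # frequencies and filters

    def allele_frequency(self, het_as_missing: bool = True) -> np.ndarray:
        """Per-SNP frequency of the second allele (code 1), counting each
        inbred line once over non-missing calls.  NaN where no informative
        call exists."""
        x = self.haploid_calls(het_as_missing)
        informative = ~np.isnan(x)
        count = informative.sum(axis=0)
        total = np.where(informative, x, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    def minor_allele_frequency(
        self, snp_id: str | None = None, het_as_missing: bool = True
    ) -> np.ndarray | float:
        """MAF per SNP (or for one SNP), ``min(p, 1 - p)`` of the haploid
        allele frequency; NaN when every call is missing."""
        p = self.allele_frequency(het_as_missing)
        maf = np.minimum(p, 1.0 - p)
        if snp_id is None:
            return maf
        return float(maf[self.snp_index(snp_id)])

    def filter_maf(self, threshold: float, het_as_missing: bool = True) -> "GenotypePanel":
        """Retain SNPs with MAF >= ``threshold`` (order preserved).

        SNPs with undefined MAF (all calls missing) are dropped.  Raises if
        nothing survives.
        """
        if not 0.0 <= threshold <= 0.5:
            raise PanelError(f"MAF threshold must be in [0, 0.5], got {threshold}")
        maf = self.minor_allele_frequency(het_as_missing=het_as_missing)
        keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= threshold)
        if keep.size == 0:
            raise PanelError(
                f"no SNP passes MAF >= {threshold}; lower the threshold"
            )
        return self.subset(snps=[self.snp_ids[j] for j in keep])


@dataclasses.dataclass(frozen=True)
class PopulationPartition:
    """Mapping line_id -> population label (e.g. landrace vs modern)."""

    labels: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "labels", dict(self.labels))

    @property
    def populations(self) -> tuple:
        return tuple(dict.fromkeys(self.labels.values()))

    def lines_in(self, population: str) -> list:
        return [l for l, p in self.labels.items() if p == population]

    def validate_against(self, panel: GenotypePanel) -> None:
        unknown = [l for l in self.labels if l not in set(panel.line_ids)]
        if unknown:
            raise PanelError(f"partition labels unknown line {unknown[0]!r}")
        for pop in self.populations:
            if not self.lines_in(pop):
                raise PanelError(f"population {pop!r} has no lines")


#: Trait codes used in the multi-environment phenotype table.
TRAIT_CODES = ("HD", "MD", "SL", "SN", "PH", "KN", "ETN", "TKW", "KL", "KW", "KT")


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table (line, trait, environment, value).

    Each (line, trait, environment) may appear at most once; values must be
    finite or NaN (NaN rows are dropped).
    """
    required = {"line", "trait", "environment", "value"}
    if not required <= set(table.columns):
        raise PanelError(f"phenotype table needs columns {sorted(required)}")
    out = table.copy()
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    out = out.dropna(subset=["value"])
    if np.isinf(out["value"].to_numpy()).any():
        raise PanelError("non-finite phenotype value")
    key = out[["line", "trait", "environment"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise PanelError(
            f"duplicate phenotype record for {tuple(row)} (line, trait, environment)"
        )
    return out.reset_index(drop=True)
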