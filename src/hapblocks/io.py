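"""Readers and writers for genotype panels, maps, phenotypes and partitions.

Three genotype dialects are supported:

``tsv``
    A genotype matrix (rows = lines, header row of SNP ids, first column
    ``line``) plus a side map file with columns ``snp_id``, ``chrom``, ``cm``.
    Cell values are a single allele symbol for a homozygous call (e.g. ``A``),
    ``X/Y`` for a heterozygous call, and ``NA`` or ``-`` for missing.
``hapmap``
    HapMap-style text: ``rs#  alleles  chrom  pos`` then one column per line,
    with diploid genotypes (``AA``, ``BB``, ``AB``, ``NN`` missing) and the
    ``pos`` column carrying the genetic position in cM.
``vcf``
    VCF with GT fields (``0/0``, ``1/1``, ``0/1``, ``./.``) read via pysam; a
    side map file supplies chromosome and cM (VCF POS is base pairs, which the
    genetic-map pipeline does not use).

Allele symbols are ordered alphabetically per SNP, so writing then re-reading
a panel with alphabetical allele pairs (the package default) reproduces the
call codes exactly.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd
import pysam

from .panel import (
    CALL_A0,
    CALL_A1,
    CALL_HET,
    CALL_MISSING,
    GenotypePanel,
    PanelError,
    PopulationPartition,
    validate_phenotypes,
)

_TSV_MISSING = {"NA", "-", ""}


def read_map(path) -> pd.DataFrame:
    """Read a genetic-map TSV (snp_id, chrom, cm) into a DataFrame indexed by
    snp_id.  A SNP listed on two chromosomes (or twice at all) is an error."""
    gmap = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    if not {"snp_id", "chrom", "cm"} <= set(gmap.columns):
        raise PanelError(f"map file {path} needs columns snp_id, chrom, cm")
    dup = gmap["snp_id"].duplicated()
    if dup.any():
        snp = gmap.loc[dup, "snp_id"].iloc[0]
        raise PanelError(f"SNP {snp!r} mapped to more than one location")
    gmap = gmap.set_index("snp_id")
    gmap["cm"] = gmap["cm"].astype(float)
    return gmap[["chrom", "cm"]]


def write_map(gmap: pd.DataFrame, path) -> None:
    out = gmap.reset_index()
    out.columns = ["snp_id", "chrom", "cm"]
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# allele-symbol handling


def _codes_from_symbols(column, snp_id, line_ids, het_symbols=True):
    """Map a column of per-line genotype strings to call codes.

    Returns (codes int8 array, (allele0, allele1)).  Symbols are ordered
    alphabetically.  More than two distinct allele symbols is an error naming
    the offending line/SNP.
    """
    observed: list[str] = []
    parsed = []
    for line_id, raw in zip(line_ids, column):
        val = str(raw).strip()
        if val in _TSV_MISSING:
            parsed.append(None)
            continue
        if "/" in val:
            a, b = val.split("/", 1)
            parsed.append((a, b))
            for s in (a, b):
                if s not in observed:
                    observed.append(s)
        else:
            parsed.append((val, val))
            if val not in observed:
                observed.append(val)
    alleles = sorted(observed)
    if len(alleles) > 2:
        bad_idx = next(
            i
            for i, p in enumerate(parsed)
            if p is not None and (p[0] == alleles[2] or p[1] == alleles[2])
        )
        raise PanelError(
            f"unknown allele symbol {alleles[2]!r} at line "
            f"{line_ids[bad_idx]!r}, SNP {snp_id!r} (more than two alleles)"
        )
    while len(alleles) < 2:
        alleles.append("B" if alleles and alleles[0] != "B" else "A")
    codes = np.full(len(parsed), CALL_MISSING, dtype=np.int8)
    for i, p in enumerate(parsed):
        if p is None:
            continue
        a, b = p
        if a != b:
            codes[i] = CALL_HET
        else:
            codes[i] = CALL_A0 if a == alleles[0] else CALL_A1
    return codes, (alleles[0], alleles[1])


# --------------------------------------------------------------------------- #
# TSV


def read_tsv(path, map_path) -> GenotypePanel:
    gmap = read_map(map_path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    if table.columns[0] != "line":
        raise PanelError("genotype TSV must start with a 'line' column")
    line_ids = table["line"].tolist()
    snp_ids = list(table.columns[1:])
    calls = np.empty((len(line_ids), len(snp_ids)), dtype=np.int8)
    alleles = np.empty((len(snp_ids), 2), dtype=object)
    for j, snp in enumerate(snp_ids):
        codes, pair = _codes_from_symbols(table[snp].tolist(), snp, line_ids)
        calls[:, j] = codes
        alleles[j] = pair
    return GenotypePanel.from_unsorted(line_ids, snp_ids, calls, gmap, alleles)


def write_tsv(panel: GenotypePanel, path, map_path) -> None:
    alleles = panel.alleles
    if alleles is None:
        alleles = np.array([("A", "B")] * panel.n_snps, dtype=object)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["line", *panel.snp_ids])
        for i, line_id in enumerate(panel.line_ids):
            row = [line_id]
            for j in range(panel.n_snps):
                c = panel.calls[i, j]
                if c == CALL_MISSING:
                    row.append("NA")
                elif c == CALL_HET:
                    row.append(f"{alleles[j][0]}/{alleles[j][1]}")
                else:
                    row.append(alleles[j][c])
            w.writerow(row)
    write_map(panel.genetic_map, map_path)


# --------------------------------------------------------------------------- #
# HapMap-style


def read_hapmap(path) -> GenotypePanel:
    table = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["rs#", "alleles", "chrom", "pos"]
    if list(table.columns[:4]) != fixed:
        raise PanelError(f"HapMap file must start with columns {fixed}")
    line_ids = list(table.columns[4:])
    snp_ids = table["rs#"].tolist()
    gmap = pd.DataFrame(
        {"chrom": table["chrom"].astype(str).tolist(),
         "cm": table["pos"].astype(float).tolist()},
        index=snp_ids,
    )
    if pd.Index(snp_ids).duplicated().any():
        dup = table["rs#"][table["rs#"].duplicated()].iloc[0]
        raise PanelError(f"SNP {dup!r} mapped to more than one location")
    calls = np.empty((len(line_ids), len(snp_ids)), dtype=np.int8)
    alleles = np.empty((len(snp_ids), 2), dtype=object)
    for j, snp in enumerate(snp_ids):
        column = []
        for g in table.iloc[j, 4:]:
            g = str(g).strip()
            if g in {"NN", "N"} or g in _TSV_MISSING:
                column.append("NA")
            elif len(g) == 2:
                column.append(g[0] if g[0] == g[1] else f"{g[0]}/{g[1]}")
            else:
                column.append(g)
        codes, pair = _codes_from_symbols(column, snp, line_ids)
        calls[:, j] = codes
        alleles[j] = pair
    return GenotypePanel.from_unsorted(line_ids, snp_ids, calls, gmap, alleles)


def write_hapmap(panel: GenotypePanel, path) -> None:
    alleles = panel.alleles
    if alleles is None:
        alleles = np.array([("A", "B")] * panel.n_snps, dtype=object)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["rs#", "alleles", "chrom", "pos", *panel.line_ids])
        for j, snp in enumerate(panel.snp_ids):
            a0, a1 = alleles[j]
            row = [snp, f"{a0}/{a1}", panel.genetic_map.iloc[j]["chrom"],
                   repr(float(panel.genetic_map.iloc[j]["cm"]))]
            for i in range(panel.n_lines):
                c = panel.calls[i, j]
                row.append(
                    "NN" if c == CALL_MISSING
                    else f"{a0}{a1}" if c == CALL_HET
                    else (a0 * 2 if c == CALL_A0 else a1 * 2)
                )
            w.writerow(row)


# --------------------------------------------------------------------------- #
# VCF (GT only, cM in side map)


def read_vcf(path, map_path) -> GenotypePanel:
    gmap = read_map(map_path)
    with pysam.VariantFile(str(path)) as vf:
        line_ids = list(vf.header.samples)
        snp_ids, rows, alleles = [], [], []
        for rec in vf:
            snp_ids.append(rec.id)
            ref = rec.ref or "A"
            alt = rec.alts[0] if rec.alts else "B"
            alleles.append((ref, alt))
            codes = np.full(len(line_ids), CALL_MISSING, dtype=np.int8)
            for i, sample in enumerate(line_ids):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                if all(a == 0 for a in gt):
                    codes[i] = CALL_A0
                elif all(a == 1 for a in gt):
                    codes[i] = CALL_A1
                else:
                    codes[i] = CALL_HET
            rows.append(codes)
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(line_ids), 0), np.int8)
    return GenotypePanel.from_unsorted(
        line_ids, snp_ids, calls, gmap, np.array(alleles, dtype=object)
    )


def write_vcf(panel: GenotypePanel, path, map_path) -> None:
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for chrom in panel.chromosomes:
        header.contigs.add(str(chrom))
    for line_id in panel.line_ids:
        header.add_sample(str(line_id))
    alleles = panel.alleles
    if alleles is None:
        alleles = np.array([("A", "B")] * panel.n_snps, dtype=object)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, snp in enumerate(panel.snp_ids):
            rec = vf.new_record(
                contig=str(panel.genetic_map.iloc[j]["chrom"]),
                start=j,  # synthetic bp position; the cM map is authoritative
                stop=j + 1,
                id=str(snp),
                alleles=(str(alleles[j][0]), str(alleles[j][1])),
            )
            for i, line_id in enumerate(panel.line_ids):
                c = panel.calls[i, j]
                rec.samples[str(line_id)]["GT"] = (
                    (None, None) if c == CALL_MISSING
                    else (0, 0) if c == CALL_A0
                    else (1, 1) if c == CALL_A1
                    else (0, 1)
                )
            vf.write(rec)
    write_map(panel.genetic_map, map_path)


# --------------------------------------------------------------------------- #
# front door


def load_genotypes(path, fmt: str, map_path=None) -> GenotypePanel:
    """Load a genotype panel in one of the supported dialects.

    ``tsv`` and ``vcf`` require ``map_path`` (cM map); HapMap carries cM in
    its ``pos`` column.
    """
    fmt = fmt.lower()
    if fmt == "tsv":
        if map_path is None:
            raise PanelError("tsv format requires a map file")
        return read_tsv(path, map_path)
    if fmt == "hapmap":
        return read_hapmap(path)
    if fmt == "vcf":
        if map_path is None:
            raise PanelError("vcf format requires a map file (cM positions)")
        return read_vcf(path, map_path)
    raise PanelError(f"unknown genotype format {fmt!r}")


def write_genotypes(panel: GenotypePanel, path, fmt: str, map_path=None) -> None:
    fmt = fmt.lower()
    if fmt == "tsv":
        write_tsv(panel, path, map_path)
    elif fmt == "hapmap":
        write_hapmap(panel, path)
    elif fmt == "vcf":
        write_vcf(panel, path, map_path)
    else:
        raise PanelError(f"unknown genotype format {fmt!r}")


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype TSV (line, trait, environment, value)."""
    return validate_phenotypes(pd.read_csv(path, sep="\t", dtype={"line": str}))


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_partition(path) -> PopulationPartition:
    """Population-label TSV with columns line, population."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"line", "population"} <= set(table.columns):
        raise PanelError("partition file needs columns line, population")
    return PopulationPartition(dict(zip(table["line"], table["population"])))


def write_partition(partition: PopulationPartition, path) -> None:
    pd.DataFrame(
        {"line": list(partition.labels), "population": list(partition.labels.values())}
    ).to_csv(path, sep="\t", index=False)
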