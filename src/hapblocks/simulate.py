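"""Synthetic inbred-line panels with planted haplotype blocks, population
structure, selection sweeps and block-resident QTLs.

The generator produces the statistical structure every analysis stage
assumes, without any external data:

* **Blocks.**  Each planted block carries a small pool of founder haplotypes
  built on a random perfect phylogeny (every SNP marks one clade of the
  pool), so within a block at most three of the four two-locus gametes occur
  and |D'| = 1 between member SNPs — the signature the solid-spine detector
  looks for.  Lines are haploid-equivalent mosaics: haplotypes are drawn
  independently per block (free recombination between blocks, none within,
  unless a within-block breakpoint rate is set).
* **Structure.**  Subpopulation allele/haplotype frequencies derive from the
  ancestral frequencies through the Balding–Nichols model with
  differentiation parameter ``F``: Dirichlet with concentration
  ``p * (1 - F) / F`` (Beta for biallelic loci outside blocks).
* **Selection.**  A selection plan fixes one pool haplotype for a named
  interval in a named population, emulating a breeding-fixed region.
* **Phenotypes.**  value = grand mean + environment effect + QTL effects
  (by the line's haplotype or allele) + a polygenic term built from
  genome-wide small SNP effects (so it covaries with kinship) scaled to a
  target heritability + Gaussian residual.

Identical seeds give byte-identical output; the single scenario seed fans
out to independent substreams for the panel and the phenotypes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError, PopulationPartition


@dataclasses.dataclass(frozen=True)
class ChromosomePlan:
    name: str
    length_cm: float
    n_snps: int


@dataclasses.dataclass(frozen=True)
class BlockPlan:
    """Planted block: SNPs [first..last] (0-based, inclusive) on a chromosome
    share a founder-haplotype pool of ``n_haplotypes``.

    ``pool`` may give the founder haplotypes explicitly as 0/1 strings over
    the member SNPs (it overrides ``n_haplotypes``); ``ancestral_freqs``
    fixes the ancestral haplotype frequencies instead of drawing them."""

    chrom: str
    first: int
    last: int
    n_haplotypes: int = 4
    pool: tuple | None = None
    ancestral_freqs: tuple | None = None

    def __post_init__(self):
        if self.pool is not None:
            object.__setattr__(self, "pool", tuple(self.pool))
            object.__setattr__(self, "n_haplotypes", len(self.pool))
            if any(len(h) != self.n_snps or set(h) - {"0", "1"} for h in self.pool):
                raise PanelError("pool haplotypes must be 0/1 strings over the members")
        if self.ancestral_freqs is not None:
            f = tuple(float(v) for v in self.ancestral_freqs)
            if len(f) != self.n_haplotypes or abs(sum(f) - 1) > 1e-9 or min(f) <= 0:
                raise PanelError("ancestral_freqs must be a positive simplex over the pool")
            object.__setattr__(self, "ancestral_freqs", f)

    @property
    def n_snps(self) -> int:
        return self.last - self.first + 1


@dataclasses.dataclass(frozen=True)
class SelectionPlan:
    """Fix pool haplotype ``haplotype`` (1-based) of one planted block in one
    population — a breeding-fixed interval."""

    population: str
    chrom: str
    block: int  # index into the chromosome's planted blocks (0-based)
    haplotype: int


@dataclasses.dataclass(frozen=True)
class QtlPlan:
    """A causal effect resident in a planted block (on one pool haplotype)
    or on a single non-block SNP."""

    kind: str  # "block" or "snp"
    chrom: str
    block: int | None = None
    haplotype: int | None = None  # 1-based pool haplotype carrying the effect
    snp: int | None = None  # chromosome-local SNP index for kind="snp"
    effect: float = 0.0


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study."""

    seed: int
    populations: dict  # name -> n_lines
    chromosomes: tuple
    blocks: tuple = ()
    differentiation_f: float = 0.06
    selection: tuple = ()
    qtls: tuple = ()
    environments: dict = dataclasses.field(
        default_factory=lambda: {"02LY": 0.0, "05LY": 1.5, "06LY": -1.0, "10SY": 2.0}
    )
    trait: str = "TKW"
    grand_mean: float = 35.0
    residual_variance: float = 16.0
    heritability: float = 0.6
    within_block_breakpoint_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.differentiation_f < 1.0:
            raise PanelError(
                f"differentiation F must be in (0,1), got {self.differentiation_f}"
            )
        if not 0.0 <= self.heritability < 1.0:
            raise PanelError(f"heritability must be in [0,1), got {self.heritability}")
        if self.residual_variance <= 0:
            raise PanelError("residual variance must be positive")
        chroms = {c.name: c for c in self.chromosomes}
        for b in self.blocks:
            if b.chrom not in chroms:
                raise PanelError(f"block on unknown chromosome {b.chrom!r}")
            if not (0 <= b.first < b.last < chroms[b.chrom].n_snps):
                raise PanelError(f"block interval {b.first}..{b.last} outside {b.chrom}")
            if b.n_haplotypes < 2:
                raise PanelError("founder pool needs >= 2 haplotypes")
        blocks_by_chrom = {}
        for b in self.blocks:
            blocks_by_chrom.setdefault(b.chrom, []).append(b)
        for bs in blocks_by_chrom.values():
            bs = sorted(bs, key=lambda b: b.first)
            for a, b in zip(bs, bs[1:]):
                if b.first <= a.last:
                    raise PanelError("planted blocks overlap")
        for s in self.selection:
            if s.population not in self.populations:
                raise PanelError(f"selection names unknown population {s.population!r}")
            bs = blocks_by_chrom.get(s.chrom, [])
            if not 0 <= s.block < len(bs):
                raise PanelError(f"selection names missing block {s.block} on {s.chrom}")
            if not 1 <= s.haplotype <= sorted(bs, key=lambda b: b.first)[s.block].n_haplotypes:
                raise PanelError("selection fixes a haplotype outside the pool")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _perfect_phylogeny_pool(rng, n_hap: int, n_snps: int) -> np.ndarray:
    """Founder haplotypes (n_hap x n_snps, 0/1) on a random perfect phylogeny:
    each SNP's derived allele marks one clade, so all pairwise |D'| = 1."""
    clades = []

    required: list = []

    def split(members):
        if len(members) <= 1:
            return
        cut = int(rng.integers(1, len(members)))
        left, right = members[:cut], members[cut:]
        required.append(left if rng.random() < 0.5 else right)
        for part in (left, right):
            if 0 < len(part) < n_hap:
                clades.append(part)
            split(part)

    members = list(rng.permutation(n_hap))
    split(members)
    # one SNP per split (when the block is wide enough) makes the pool
    # haplotypes pairwise distinct; remaining SNPs mark random clades
    pool = np.zeros((n_hap, n_snps), dtype=np.int8)
    cols = list(rng.permutation(n_snps))
    for i, clade in enumerate(required):
        if i >= n_snps:
            break
        pool[clade, cols[i]] = 1
    for s in cols[len(required):]:
        clade = clades[int(rng.integers(len(clades)))]
        pool[clade, s] = 1
    return pool


def _bn_dirichlet(rng, ancestral: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols draw of subpopulation frequencies from ancestral ones."""
    conc = ancestral * (1.0 - f) / f
    return rng.dirichlet(np.maximum(conc, 1e-8))


def simulate_panel(config: ScenarioConfig):
    """Generate (GenotypePanel, PopulationPartition, truth dict).

    The truth record stores everything the planted structure implies: block
    boundaries and member SNPs, founder pools, ancestral and per-population
    haplotype/allele frequencies, per-line haplotype assignments, applied
    selection, and F.
    """
    rng = _rng(config.seed, 0)
    pops = list(config.populations)
    line_ids, line_pop = [], []
    for pop in pops:
        for i in range(config.populations[pop]):
            line_ids.append(f"{pop}_{i+1:03d}")
            line_pop.append(pop)
    n_lines = len(line_ids)

    snp_ids, chrom_col, cm_col = [], [], []
    chrom_offset = {}
    for cp in config.chromosomes:
        chrom_offset[cp.name] = len(snp_ids)
        pos = np.sort(rng.uniform(0.0, cp.length_cm, size=cp.n_snps))
        for k in range(cp.n_snps):
            snp_ids.append(f"{cp.name}_s{k+1:04d}")
            chrom_col.append(cp.name)
            cm_col.append(float(pos[k]))
    gmap = pd.DataFrame({"chrom": chrom_col, "cm": cm_col}, index=snp_ids)

    calls = np.zeros((n_lines, len(snp_ids)), dtype=np.int8)
    in_block = np.zeros(len(snp_ids), dtype=bool)
    truth_blocks = []
    blocks_by_chrom: dict[str, list] = {}
    for b in sorted(config.blocks, key=lambda b: (b.chrom, b.first)):
        blocks_by_chrom.setdefault(b.chrom, []).append(b)

    selection_lookup = {
        (s.chrom, s.block): s for s in config.selection
    }

    for chrom, bs in blocks_by_chrom.items():
        for bi, bp in enumerate(bs):
            cols = np.arange(chrom_offset[chrom] + bp.first,
                             chrom_offset[chrom] + bp.last + 1)
            in_block[cols] = True
            if bp.pool is not None:
                pool = np.array([[int(c) for c in h] for h in bp.pool], dtype=np.int8)
            else:
                pool = _perfect_phylogeny_pool(rng, bp.n_haplotypes, bp.n_snps)
            if bp.ancestral_freqs is not None:
                anc = np.array(bp.ancestral_freqs)
            else:
                anc = rng.dirichlet(np.ones(bp.n_haplotypes))
            pop_freqs = {
                pop: _bn_dirichlet(rng, anc, config.differentiation_f) for pop in pops
            }
            assignment = np.zeros(n_lines, dtype=int)
            sel = selection_lookup.get((chrom, bi))
            for i in range(n_lines):
                pop = line_pop[i]
                if sel is not None and pop == sel.population:
                    h = sel.haplotype - 1
                else:
                    h = rng.choice(bp.n_haplotypes, p=pop_freqs[pop])
                hap = pool[h].copy()
                if (
                    config.within_block_breakpoint_rate > 0
                    and bp.n_snps > 1
                    and rng.random() < config.within_block_breakpoint_rate
                ):
                    h2 = rng.choice(bp.n_haplotypes, p=pop_freqs[pop])
                    cut = rng.integers(1, bp.n_snps)
                    hap[cut:] = pool[h2, cut:]
                    assignment[i] = 0  # recombinant: no single pool index
                else:
                    assignment[i] = h + 1
                calls[i, cols] = hap
            truth_blocks.append(
                {
                    "chrom": chrom,
                    "block_index": bi,
                    "first": int(bp.first),
                    "last": int(bp.last),
                    "snp_ids": [snp_ids[c] for c in cols],
                    "pool": ["".join(map(str, row)) for row in pool],
                    "ancestral_freqs": anc.tolist(),
                    "population_freqs": {p: f.tolist() for p, f in pop_freqs.items()},
                    "assignments": assignment.tolist(),
                    "selection": None if sel is None else dataclasses.asdict(sel),
                }
            )

    loose = np.flatnonzero(~in_block)
    anc_p = rng.uniform(0.1, 0.9, size=loose.size)
    pop_p = {
        pop: np.array(
            [
                rng.beta(
                    max(p * (1 - config.differentiation_f) / config.differentiation_f, 1e-8),
                    max((1 - p) * (1 - config.differentiation_f) / config.differentiation_f, 1e-8),
                )
                for p in anc_p
            ]
        )
        for pop in pops
    }
    for i in range(n_lines):
        calls[i, loose] = (rng.random(loose.size) < pop_p[line_pop[i]]).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = -1

    panel = GenotypePanel.from_unsorted(line_ids, snp_ids, calls, gmap)
    partition = PopulationPartition(dict(zip(line_ids, line_pop)))
    truth = {
        "seed": config.seed,
        "differentiation_f": config.differentiation_f,
        "blocks": truth_blocks,
        "loose_snps": {
            "snp_ids": [snp_ids[c] for c in loose],
            "ancestral_p": anc_p.tolist(),
            "population_p": {p: v.tolist() for p, v in pop_p.items()},
        },
        "line_ids": line_ids,
        "line_pop": line_pop,
    }
    return panel, partition, truth


def simulate_phenotypes(panel: GenotypePanel, truth: dict, config: ScenarioConfig):
    """Generate a long-format phenotype table plus a truth-effects record."""
    rng = _rng(config.seed, 1)
    n = panel.n_lines
    g_qtl = np.zeros(n)
    qtl_records = []
    blocks_by_key = {(b["chrom"], b["block_index"]): b for b in truth["blocks"]}
    for q in config.qtls:
        if q.kind == "block":
            b = blocks_by_key.get((q.chrom, q.block))
            if b is None:
                raise PanelError(f"QTL names missing block {q.block} on {q.chrom}")
            carrier = np.array(b["assignments"]) == q.haplotype
            g_qtl += q.effect * carrier
            qtl_records.append({**dataclasses.asdict(q), "carrier_freq": float(carrier.mean())})
        elif q.kind == "snp":
            snp_id = f"{q.chrom}_s{q.snp+1:04d}"
            dosage = panel.haploid_calls()[:, panel.snp_index(snp_id)]
            g_qtl += q.effect * np.nan_to_num(dosage, nan=0.0)
            qtl_records.append({**dataclasses.asdict(q), "snp_id": snp_id})
        else:
            raise PanelError(f"unknown QTL kind {q.kind!r}")

    # polygenic term from genome-wide small SNP effects: covaries with kinship.
    # SNPs inside QTL-carrying blocks are excluded from the basis so the
    # planted effect is the only genetic signal resident in those blocks.
    h2 = config.heritability
    sigma_e2 = config.residual_variance
    target_genetic = h2 / (1 - h2) * sigma_e2 if h2 > 0 else 0.0
    var_qtl = float(np.var(g_qtl))
    poly_var = max(target_genetic - var_qtl, 0.0)
    qtl_block_snps = {
        s
        for q in config.qtls
        if q.kind == "block"
        for s in blocks_by_key[(q.chrom, q.block)]["snp_ids"]
    }
    x = panel.haploid_calls()
    x = np.nan_to_num(x - np.nanmean(x, axis=0), nan=0.0)
    w = rng.normal(size=panel.n_snps)
    if qtl_block_snps:
        w[[j for j, s in enumerate(panel.snp_ids) if s in qtl_block_snps]] = 0.0
    g_poly = x @ w
    sd = g_poly.std()
    g_poly = g_poly / sd * np.sqrt(poly_var) if sd > 0 and poly_var > 0 else np.zeros(n)
    genetic = g_qtl + g_poly

    rows = []
    for env, env_effect in config.environments.items():
        resid = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
        values = config.grand_mean + env_effect + genetic + resid
        for i, line in enumerate(panel.line_ids):
            rows.append((line, config.trait, env, float(values[i])))
    table = pd.DataFrame(rows, columns=["line", "trait", "environment", "value"])
    effects = {
        "qtls": qtl_records,
        "genetic_values": genetic.tolist(),
        "polygenic_variance": float(np.var(g_poly)),
        "qtl_variance": var_qtl,
        "residual_variance": sigma_e2,
        "target_h2": h2,
        "realized_h2": float(
            np.var(genetic) / (np.var(genetic) + sigma_e2)
        ) if np.var(genetic) + sigma_e2 > 0 else np.nan,
    }
    return table, effects


def planted_blocks(truth: dict, panel: GenotypePanel):
    """Materialise the planted blocks of a truth record as
    :class:`~hapblocks.blocks.Block` objects (ids ``HapB-<chrom>-<k>`` in
    planted order), for estimator checks that must not depend on block
    detection."""
    from .blocks import Block

    out = []
    counter: dict[str, int] = {}
    for b in truth["blocks"]:
        chrom = b["chrom"]
        counter[chrom] = counter.get(chrom, 0) + 1
        cm = panel.positions_cm(b["snp_ids"])
        out.append(
            Block(
                block_id=f"HapB-{chrom}-{counter[chrom]}",
                chromosome=chrom,
                first=b["first"],
                last=b["last"],
                snp_ids=tuple(b["snp_ids"]),
                span_cm=float(cm.max() - cm.min()),
            )
        )
    return out


# --------------------------------------------------------------------------- #
# a study-shaped default scenario


def tiled_blocks(
    chrom: str, n_snps: int, block_size: int = 6, gap: int = 1,
    n_haplotypes: int = 5,
) -> tuple:
    """Tile a chromosome with planted blocks of ``block_size`` SNPs separated
    by ``gap`` loose SNPs."""
    out = []
    first = 0
    while first + block_size - 1 < n_snps:
        out.append(BlockPlan(chrom, first, first + block_size - 1, n_haplotypes))
        first += block_size + gap
    return tuple(out)


def null_gwas_scenario(
    seed: int, n_markers: int = 2000, n_per_pop: int = 100, f: float = 0.15,
    heritability: float = 0.5,
) -> ScenarioConfig:
    """Null association study: two differentiated subpopulations, independent
    SNPs (no planted blocks), a genome-wide polygenic phenotype and no QTL —
    the setting for checking mixed-model type-I error control under
    structure confounding."""
    return ScenarioConfig(
        seed=seed,
        populations={"pop1": n_per_pop, "pop2": n_per_pop},
        chromosomes=(ChromosomePlan("1A", 100.0, n_markers),),
        blocks=(),
        differentiation_f=f,
        environments={"E1": 0.0},
        heritability=heritability,
    )


def differentiation_recovery_scenario(
    seed: int, f: float = 0.15, n_loci: int = 500, n_per_pop: int = 100,
    n_pops: int = 10,
) -> ScenarioConfig:
    """Independent loci across several equally sized populations for Gst
    parameter recovery.  Many populations are used because Nei's Gst under
    the Balding–Nichols model converges to F only as the number of
    populations grows (E[Gst] ~ F(1-1/k)/(1-F/k) for k populations)."""
    return ScenarioConfig(
        seed=seed,
        populations={f"pop{i+1}": n_per_pop for i in range(n_pops)},
        chromosomes=(ChromosomePlan("1A", 100.0, n_loci),),
        blocks=(),
        differentiation_f=f,
        environments={"E1": 0.0},
        heritability=0.0,
    )


def haplotype_power_scenario(seed: int, effect: float = 3.0) -> ScenarioConfig:
    """The block-beats-SNP association experiment.

    A 300-line two-subpopulation panel with study-scale marker counts —
    four chromosomes of 1100 SNPs tiled with 6-SNP blocks (~3900 testable
    SNPs, ~660 blocks, so the two P < 1/n thresholds sit near 2.6e-4 and
    1.5e-3, the scale of the motivating study's 4434-SNP / 847-block scan).
    One causal block carries exactly three founder haplotypes over its six
    members (frequencies 0.30/0.35/0.35) and the trait-increasing effect
    rides on the haplotype that no single member SNP separates: each SNP's
    derived allele marks one of the two non-causal haplotypes, so the best
    single-SNP contrast carries only ~23 % of the block test's
    noncentrality.  The effect size (3.0 trait units against a residual SD
    of 4 at heritability 0.4) centres the block statistic inside the window
    where it clears its own threshold while the member SNPs stay below
    theirs.
    """
    causal = BlockPlan(
        "1A", 0, 5, pool=("000000", "111000", "000111"),
        ancestral_freqs=(0.30, 0.35, 0.35),
    )
    chroms, blocks = [], [causal]
    for name in ("1A", "1B", "2A", "2B"):
        chroms.append(ChromosomePlan(name, 160.0, 1100))
        tiles = tiled_blocks(name, 1100, 6, 1, 5)
        blocks.extend(tiles[1:] if name == "1A" else tiles)
    return ScenarioConfig(
        seed=seed,
        populations={"landrace": 180, "modern": 120},
        chromosomes=tuple(chroms),
        blocks=tuple(blocks),
        differentiation_f=0.02,
        qtls=(QtlPlan("block", "1A", 0, 1, None, effect),),
        environments={"E1": 0.0},
        heritability=0.4,
        residual_variance=16.0,
    )


def wheat_like_scenario(seed: int, n_landrace: int = 157, n_modern: int = 88,
                        snps_per_chrom: int = 70, **overrides) -> ScenarioConfig:
    """A two-subpopulation selfing-crop scenario shaped like the study panel:
    landrace and modern subpopulations (157/88 lines), two homoeologous
    chromosomes tiled with 6-SNP blocks drawing on 5-haplotype founder pools,
    modest differentiation (F = 0.06, the landrace-vs-modern scale), and
    four environments."""
    chroms = (ChromosomePlan("1A", 150.0, snps_per_chrom),
              ChromosomePlan("1B", 120.0, snps_per_chrom))
    blocks = tiled_blocks("1A", snps_per_chrom) + tiled_blocks("1B", snps_per_chrom)
    base = dict(
        seed=seed,
        populations={"landrace": n_landrace, "modern": n_modern},
        chromosomes=chroms,
        blocks=blocks,
        differentiation_f=0.06,
    )
    base.update(overrides)
    return ScenarioConfig(**base)
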