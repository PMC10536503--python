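"""Synthetic breed-pedigree simulator with a planted recessive risk locus.

Emulates the statistical structure a carrier-augmented GWAS of a recessive
disease in a closed breeding population assumes: a multi-generation pedigree
with popular-sire skew, blockwise-exchangeable linkage disequilibrium on
founder haplotypes, Mendelian gene dropping with Haldane recombination, a
recessive risk locus with incomplete penetrance and a sporadic (phenocopy)
rate, and clinical annotations (immunophenotype, age at onset) drawn from the
disease profile of canine B-cell lymphoma. Defaults target a population with
effective size on the order of 100, disease prevalence a few percent, ~85%
B-cell immunophenotype, and onset ~Normal(8.7 y, 3.3 y) truncated to (0, 16].

The LD model is blockwise-exchangeable, not coalescent: each chromosome is
partitioned into latent blocks of geometric length, each block carries a
small pool of haplotype variants with Dirichlet frequencies, and founder
haplotypes are drawn i.i.d. blockwise. That is deliberately simple — it gives
planted, exactly known block boundaries against which block detection can be
scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, write_ped_map
from .pedigree import Pedigree, build_pedigree

__all__ = [
    "SimConfig",
    "SimulationError",
    "HaplotypePool",
    "SimDataset",
    "simulate_pedigree",
    "simulate_founder_haplotypes",
    "gene_drop",
    "assign_disease",
    "write_dataset",
    "simulate_dataset",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic study population.

    Mating structure: founders split evenly by sex; every female of the
    previous generation is a dam with a Poisson(mean_litter_size) litter,
    while only a ``sire_fraction`` of males are used as sires, with
    Dirichlet-skewed usage so a minority of sires father a majority of
    offspring (popular-sire effect). Genome: ``n_chromosomes`` chromosomes of
    ``snps_per_chromosome`` SNPs at ``snp_spacing_bp`` intervals, recombining
    at ``recomb_cm_per_mb`` under Haldane's model. The risk locus is a
    (chromosome label, SNP index, founder risk-allele frequency) triple.
    """

    n_generations: int = 6
    n_founders: int = 100
    sire_fraction: float = 0.25
    mean_litter_size: float = 2.2
    n_chromosomes: int = 10
    snps_per_chromosome: int = 1000
    snp_spacing_bp: int = 20_000
    recomb_cm_per_mb: float = 1.0
    block_length_mean: float = 5.0
    haplotypes_per_block: tuple[int, int] = (2, 6)
    maf_floor: float = 0.02
    risk_locus: tuple[str, int, float] = ("1", 500, 0.3)
    penetrance_aa: float = 0.5
    sporadic_rate: float = 0.005
    bcell_fraction: float = 0.85
    untyped_fraction: float = 0.4
    onset_mean_years: float = 8.7
    onset_sd_years: float = 3.3
    onset_max_years: float = 16.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sire_fraction", "penetrance_aa", "sporadic_rate", "bcell_fraction",
            "untyped_fraction", "missing_rate", "maf_floor",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_generations", "n_founders", "n_chromosomes", "snps_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        chrom, idx, freq = self.risk_locus
        if not 0 <= idx < self.snps_per_chromosome:
            raise ValueError("risk locus SNP index outside its chromosome")
        if not 0.0 <= freq <= 1.0:
            raise ValueError("risk-allele founder frequency must be in [0,1]")
        if str(chrom) not in {str(c + 1) for c in range(self.n_chromosomes)}:
            raise ValueError(f"risk locus chromosome {chrom!r} not simulated")
        if self.penetrance_aa < self.sporadic_rate:
            warnings.warn("penetrance below sporadic rate: inverted effect", stacklevel=2)

    @property
    def risk_variant_id(self) -> str:
        chrom, idx, _ = self.risk_locus
        return f"{chrom}:{(idx + 1) * self.snp_spacing_bp}"


class Block(NamedTuple):
    chrom: str
    start: int            # SNP index within chromosome (inclusive)
    stop: int             # exclusive
    variants: np.ndarray  # (K, L) array of 0/1 alleles
    freqs: np.ndarray     # (K,) Dirichlet frequencies


@dataclass
class HaplotypePool:
    """Latent blocks with haplotype variants and their founder frequencies."""

    blocks: list[Block]
    monomorphic_snps: list[str] = field(default_factory=list)

    def block_truth(self) -> pd.DataFrame:
        """Planted block boundaries (SNP index ranges) for scoring detection."""
        return pd.DataFrame(
            [
                {"chrom": b.chrom, "start": b.start, "stop": b.stop, "n_haplotypes": len(b.freqs)}
                for b in self.blocks
            ]
        )


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Generate a generational pedigree with popular-sire skew.

    Founders (generation 0) have unknown parents; every later individual has
    exactly one sire and one dam from the previous generation.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows = []
    males, females = [], []
    for i in range(config.n_founders):
        sex = "M" if i % 2 == 0 else "F"
        iid = f"g0_{i:04d}"
        rows.append({"id": iid, "sire": None, "dam": None, "sex": sex, "year": 2000})
        (males if sex == "M" else females).append(iid)

    for g in range(1, config.n_generations):
        if not males:
            raise SimulationError(f"no males available to sire generation {g}")
        if not females:
            raise SimulationError(f"no females available to produce generation {g}")
        n_sires = max(1, int(round(config.sire_fraction * len(males))))
        sires = list(rng.choice(males, size=n_sires, replace=False))
        # Dirichlet(0.3) weights concentrate matings on a few popular sires.
        weights = rng.dirichlet(np.full(n_sires, 0.3))
        next_males, next_females, new_rows = [], [], []
        k = 0
        for dam in females:
            litter = rng.poisson(config.mean_litter_size)
            for _ in range(litter):
                sire = sires[rng.choice(n_sires, p=weights)]
                sex = "M" if rng.random() < 0.5 else "F"
                iid = f"g{g}_{k:04d}"
                k += 1
                new_rows.append(
                    {"id": iid, "sire": sire, "dam": dam, "sex": sex, "year": 2000 + 2 * g}
                )
                (next_males if sex == "M" else next_females).append(iid)
        if not new_rows:
            raise SimulationError(f"generation {g} produced no offspring")
        rows.extend(new_rows)
        males, females = next_males, next_females
    return build_pedigree(pd.DataFrame(rows))


def _draw_block(rng: np.random.Generator, length: int, k_range: tuple[int, int],
                maf_floor: float, max_tries: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype-variant pool for one block: K variants with Dirichlet freqs.

    Allele columns are drawn site-by-site so that every SNP segregates within
    the pool and its pooled frequency respects the MAF floor. With K=1 the
    block is degenerate (monomorphic, flagged by the caller); with K=2 the
    two variants differ at every site, i.e. within-block r^2 = 1.
    """
    k_lo, k_hi = k_range
    k = int(rng.integers(k_lo, k_hi + 1))
    if k == 1:
        return rng.integers(0, 2, size=(1, length)), np.ones(1)
    for _ in range(max_tries):
        freqs = rng.dirichlet(np.ones(k))
        if freqs.min() >= maf_floor:
            break
    else:
        raise SimulationError(
            f"could not draw {k} haplotype frequencies above MAF floor {maf_floor}"
        )
    variants = np.empty((k, length), dtype=np.int64)
    for j in range(length):
        for _ in range(max_tries):
            col = rng.integers(0, 2, size=k)
            p = float(freqs @ col)
            if 0 < col.sum() < k and maf_floor <= p <= 1 - maf_floor:
                variants[:, j] = col
                break
        else:
            raise SimulationError(
                f"could not draw a block column satisfying MAF floor {maf_floor}"
            )
    return variants, freqs


def simulate_founder_haplotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[HaplotypePool, pd.DataFrame]:
    """Partition each chromosome into latent LD blocks and draw variant pools.

    Returns the pool and a variant map (chrom, bp, id). The risk locus is
    planted as its own single-SNP block at its configured founder frequency.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    blocks: list[Block] = []
    mono: list[str] = []
    map_rows = []
    risk_chrom, risk_idx, risk_freq = config.risk_locus
    risk_chrom = str(risk_chrom)
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        m = config.snps_per_chromosome
        for j in range(m):
            map_rows.append(
                {"chrom": chrom, "bp": (j + 1) * config.snp_spacing_bp,
                 "id": f"{chrom}:{(j + 1) * config.snp_spacing_bp}"}
            )
        boundaries = []
        pos = 0
        while pos < m:
            length = int(rng.geometric(1.0 / config.block_length_mean))
            length = min(length, m - pos)
            boundaries.append((pos, pos + length))
            pos += length
        if chrom == risk_chrom:
            # Split so the risk SNP sits in its own block.
            split: list[tuple[int, int]] = []
            for s, e in boundaries:
                if s <= risk_idx < e:
                    if s < risk_idx:
                        split.append((s, risk_idx))
                    split.append((risk_idx, risk_idx + 1))
                    if risk_idx + 1 < e:
                        split.append((risk_idx + 1, e))
                else:
                    split.append((s, e))
            boundaries = split
        for s, e in boundaries:
            if chrom == risk_chrom and s == risk_idx and e == risk_idx + 1:
                variants = np.array([[1], [0]])
                freqs = np.array([risk_freq, 1.0 - risk_freq])
            else:
                variants, freqs = _draw_block(
                    rng, e - s, config.haplotypes_per_block, config.maf_floor
                )
            blk = Block(chrom, s, e, variants, freqs)
            blocks.append(blk)
            if len(freqs) == 1:
                mono.extend(
                    f"{chrom}:{(j + 1) * config.snp_spacing_bp}" for j in range(s, e)
                )
    vmap = pd.DataFrame(map_rows)
    return HaplotypePool(blocks, monomorphic_snps=mono), vmap


def _draw_founder_haplotype(pool: HaplotypePool, chrom: str, m: int,
                            rng: np.random.Generator) -> np.ndarray:
    hap = np.empty(m, dtype=np.int8)
    for b in pool.blocks:
        if b.chrom != chrom:
            continue
        k = rng.choice(len(b.freqs), p=b.freqs)
        hap[b.start:b.stop] = b.variants[k]
    return hap


def gene_drop(
    pedigree: Pedigree,
    pool: HaplotypePool,
    vmap: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Drop founder haplotypes down the pedigree with Haldane recombination.

    Each offspring receives one recombinant gamete from each parent;
    crossover counts are Poisson with rate set by the chromosome's genetic
    length (``recomb_cm_per_mb``), positions uniform. Phased truth is kept on
    the returned matrix's ``phased`` attribute; exported calls are unphased
    dosages of allele "1" (labelled A), to be minor-allele recoded on read.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms = list(dict.fromkeys(vmap["chrom"]))
    bp = {c: vmap.loc[vmap["chrom"] == c, "bp"].to_numpy() for c in chroms}
    m_per = {c: len(bp[c]) for c in chroms}

    half_known = [
        i for i in pedigree.ids
        if (pedigree.sire(i) is None) != (pedigree.dam(i) is None)
    ]
    if half_known:
        raise SimulationError(
            f"individuals with exactly one known parent: {half_known[:5]}; "
            "complete the pedigree with dummy founders first"
        )

    def gamete(haps: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict[str, np.ndarray]:
        out = {}
        for c in chroms:
            a, b = haps[c]
            length_bp = bp[c][-1]
            morgans = length_bp * config.recomb_cm_per_mb / 1e8
            n_x = rng.poisson(morgans)
            phase = int(rng.integers(2))
            if n_x:
                cuts = np.sort(rng.uniform(0, length_bp, size=n_x))
                switches = np.searchsorted(cuts, bp[c], side="left")
                sel = (phase + switches) % 2
            else:
                sel = np.full(m_per[c], phase)
            out[c] = np.where(sel == 0, a, b).astype(np.int8)
        return out

    phased: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    # Process in an order where parents precede offspring.
    remaining = list(pedigree.ids)
    done: set[str] = set()
    while remaining:
        progressed = False
        still = []
        for iid in remaining:
            s, d = pedigree.parents(iid)
            if s is None and d is None:
                phased[iid] = {
                    c: (
                        _draw_founder_haplotype(pool, c, m_per[c], rng),
                        _draw_founder_haplotype(pool, c, m_per[c], rng),
                    )
                    for c in chroms
                }
                done.add(iid)
                progressed = True
            elif s in done and d in done:
                gs = gamete(phased[s])
                gd = gamete(phased[d])
                phased[iid] = {c: (gs[c], gd[c]) for c in chroms}
                done.add(iid)
                progressed = True
            else:
                still.append(iid)
        remaining = still
        if remaining and not progressed:
            raise SimulationError(f"unresolvable parentage for {remaining[:5]}")

    samples = pedigree.ids
    dosage = np.empty((len(samples), len(vmap)), dtype=float)
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += m_per[c]
    for i, iid in enumerate(samples):
        for c in chroms:
            a, b = phased[iid][c]
            dosage[i, offsets[c]:offsets[c] + m_per[c]] = a + b

    variants = vmap.copy()
    variants["a1"] = "A"  # allele "1"
    variants["a2"] = "G"  # allele "0"
    return GenotypeMatrix(list(samples), variants, dosage, phased=phased)


def assign_disease(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign affection status, immunophenotype, and onset from the risk locus.

    P(affected | aa) = penetrance_aa, P(affected | other) = sporadic_rate.
    Affected dogs receive an onset age from Normal(onset_mean, onset_sd)
    truncated to (0, onset_max], and a B immunophenotype with probability
    ``bcell_fraction`` (T otherwise); a fraction ``untyped_fraction`` of
    affected dogs is then relabelled untyped. Returns (clinical, truth)
    tables; truth records the risk genotype and whether a case is a
    phenocopy.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rid = config.risk_variant_id
    j = genotypes.variant_index([rid])[0]
    # The simulator's raw coding counts allele "1" (= the risk allele).
    risk_dosage = genotypes.dosage[:, j]
    a, b = (0.0, config.onset_max_years)
    mean, sd = config.onset_mean_years, config.onset_sd_years
    tn = stats.truncnorm((a - mean) / sd, (b - mean) / sd, loc=mean, scale=sd)

    clin_rows, truth_rows = [], []
    for i, iid in enumerate(genotypes.samples):
        g = int(risk_dosage[i])
        p_aff = config.penetrance_aa if g == 2 else config.sporadic_rate
        affected = bool(rng.random() < p_aff)
        onset = float(tn.ppf(rng.random())) if affected else None
        if affected:
            pheno = "B" if rng.random() < config.bcell_fraction else "T"
            if rng.random() < config.untyped_fraction:
                pheno = "untyped"
        else:
            pheno = ""
        clin_rows.append(
            {"id": iid, "affected": int(affected),
             "immunophenotype": pheno,
             "onset_years": round(onset, 3) if onset is not None else ""}
        )
        truth_rows.append(
            {"id": iid, "risk_genotype": g, "affected": int(affected),
             "phenocopy": int(affected and g != 2),
             "carrier_truth": int(g == 1)}
        )
    return pd.DataFrame(clin_rows), pd.DataFrame(truth_rows)


def write_dataset(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    clinical: pd.DataFrame,
    truth: pd.DataFrame,
    outdir: str | Path,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write PED/MAP plus pedigree, clinical, and truth CSVs.

    Raises on id collisions between tables referring to distinct rows; a
    read-back of the PED/MAP reproduces the (minor-allele-recoded) matrix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in (("clinical", clinical), ("truth", truth)):
        dups = df["id"][df["id"].duplicated()].tolist()
        if dups:
            raise ValueError(f"duplicate ids in {name} table: {dups[:5]}")
    if genotypes.n_variants == 0 or genotypes.n_samples == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    paths = {
        "ped": outdir / "genotypes.ped",
        "map": outdir / "genotypes.map",
        "pedigree": outdir / "pedigree.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.csv",
    }
    affected = dict(zip(clinical["id"], clinical["affected"]))
    pheno = {i: (2 if affected.get(i) else 1) for i in genotypes.samples}
    write_ped_map(
        genotypes, paths["ped"], paths["map"], pedigree=pedigree,
        phenotype=pheno, missing_rate=missing_rate, rng=rng,
    )
    rec = pedigree.records.copy()
    rec["sire"] = rec["sire"].fillna("")
    rec["dam"] = rec["dam"].fillna("")
    rec.to_csv(paths["pedigree"], index=False)
    clinical.to_csv(paths["clinical"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths


@dataclass
class SimDataset:
    """In-memory bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    variant_map: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    pool: HaplotypePool

    @property
    def case_ids(self) -> list[str]:
        return list(self.clinical.loc[self.clinical["affected"] == 1, "id"])


def simulate_dataset(config: SimConfig) -> SimDataset:
    """End-to-end simulation with a single seed: pedigree, genotypes, disease."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    pool, vmap = simulate_founder_haplotypes(config, rng)
    gm = gene_drop(ped, pool, vmap, config, rng)
    clinical, truth = assign_disease(ped, gm, config, rng)
    return SimDataset(config, ped, gm, vmap, clinical, truth, pool)
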