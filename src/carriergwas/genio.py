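"""Genotype I/O (PLINK text PED/MAP), QC filtering, and allele-frequency tables.

Genotypes are held as minor-allele dosages (0/1/2, NaN = missing) with the
minor (A1) and major (A2) allele recorded per variant, matching the convention
of the association output tables. QC follows the PLINK-style sequence:
individual missingness (``--mind``), then per-SNP missingness (``--geno``),
then minor allele frequency (``--maf``), with frequencies recomputed after
sample removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "read_ped_map",
    "write_ped_map",
    "recode_minor",
    "qc_filter",
    "allele_frequency",
    "genotype_group_table",
    "merge_on_shared_variants",
]

VARIANT_COLUMNS = ["chrom", "bp", "id", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage calls with variant metadata.

    ``variants`` has columns chrom (str), bp (int, 1-based), id ("chr:bp"),
    a1 (minor allele), a2 (major allele). ``dosage`` is float with NaN for
    missing calls. ``phased`` optionally carries simulator truth haplotypes
    and is never written to disk.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    phased: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if (self.variants["a1"] == self.variants["a2"]).any():
            raise ValueError("variant with identical A1 and A2 alleles")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def variant_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"variants not in genotype matrix: {missing[:5]}")
        return np.array([lookup[v] for v in ids], dtype=int)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        dos = self.dosage
        smp = self.samples
        if samples is not None:
            rows = self.sample_index(samples)
            dos = dos[rows]
            smp = list(samples)
        var = self.variants
        if variant_mask is not None:
            dos = dos[:, variant_mask]
            var = var.loc[variant_mask].reset_index(drop=True)
        return GenotypeMatrix(list(smp), var, dos.copy())


@dataclass
class QcReport:
    removed_samples: pd.DataFrame  # id, missingness
    removed_variants: pd.DataFrame  # id, reason in {geno, maf}
    thresholds: dict


def _tie_break_minor(c1: int, c2: int, a1: str, a2: str) -> bool:
    """True if allele 1 is the minor allele (alphabetical on ties)."""
    if c1 != c2:
        return c1 < c2
    return a1 < a2


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read whitespace-delimited PLINK text PED/MAP into a GenotypeMatrix.

    Alleles are recoded per variant so dosage counts the minor allele
    (ties broken alphabetically); "0 0" calls become NaN. Monomorphic
    variants are kept with MAF 0 (A2 set to the placeholder "N" when only
    one allele is ever observed).
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "bp"],
        dtype={"chrom": str, "id": str},
    )
    m = len(map_df)
    samples: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {ln} has {len(parts)} fields, expected {6 + 2 * m}"
                )
            samples.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(samples), m, 2)

    dosage = np.full((len(samples), m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) == 0:
            a1, a2 = "N", "M"
        elif len(uniq) == 1:
            a1, a2 = str(uniq[0]), "N"
        else:
            if len(uniq) > 2:
                raise ValueError(f"variant {map_df['id'][j]} has >2 alleles: {list(uniq)}")
            x, y = str(uniq[0]), str(uniq[1])
            cx, cy = int(counts[0]), int(counts[1])
            a1, a2 = (x, y) if _tie_break_minor(cx, cy, x, y) else (y, x)
        a1_list.append(a1)
        a2_list.append(a2)
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        dosage[called, j] = (col[called, 0] == a1).astype(float) + (
            col[called, 1] == a1
        ).astype(float)

    variants = pd.DataFrame(
        {
            "chrom": map_df["chrom"].astype(str),
            "bp": map_df["bp"].astype(int),
            "id": map_df["id"].astype(str),
            "a1": a1_list,
            "a2": a2_list,
        }
    )
    order = np.lexsort((variants["bp"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    return recode_minor(GenotypeMatrix(samples, variants, dosage[:, order]))


def write_ped_map(
    gm: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    pedigree=None,
    phenotype: Mapping[str, int] | None = None,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Write a GenotypeMatrix as PLINK text PED/MAP.

    Optional completely-at-random missingness (``missing_rate``) is applied
    at write time; pass ``rng`` for reproducibility.
    """
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    if missing_rate and rng is None:
        rng = np.random.default_rng(0)
    with open(map_path, "w") as fh:
        for _, v in gm.variants.iterrows():
            fh.write(f"{v['chrom']}\t{v['id']}\t0\t{v['bp']}\n")
    a1 = gm.variants["a1"].to_numpy()
    a2 = gm.variants["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.samples):
            sire = dam = "0"
            sex_code = "0"
            if pedigree is not None and iid in pedigree:
                sire = pedigree.sire(iid) or "0"
                dam = pedigree.dam(iid) or "0"
                sex_code = {"M": "1", "F": "2"}.get(pedigree.sex(iid) or "", "0")
            pheno = str(phenotype.get(iid, -9)) if phenotype else "-9"
            fields = ["FAM1", iid, sire, dam, sex_code, pheno]
            dos = gm.dosage[i]
            drop = (
                rng.random(gm.n_variants) < missing_rate
                if missing_rate
                else np.zeros(gm.n_variants, dtype=bool)
            )
            for j in range(gm.n_variants):
                if drop[j] or np.isnan(dos[j]):
                    fields += ["0", "0"]
                elif dos[j] == 2:
                    fields += [a1[j], a1[j]]
                elif dos[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def allele_frequency(
    gm: GenotypeMatrix, sample_subset: Sequence[str] | None = None
) -> pd.Series:
    """Per-variant A1 frequency: (2*hom_minor + het) / (2*non-missing)."""
    dos = gm.dosage
    if sample_subset is not None:
        if len(sample_subset) == 0:
            raise ValueError("empty sample subset")
        dos = dos[gm.sample_index(sample_subset)]
    with np.errstate(invalid="ignore"):
        n_called = np.sum(~np.isnan(dos), axis=0)
        total = np.nansum(dos, axis=0)
        freq = np.divide(total, 2.0 * n_called, out=np.zeros(dos.shape[1]), where=n_called > 0)
    return pd.Series(freq, index=gm.variants["id"].to_numpy(), name="a1_freq")


def recode_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip A1/A2 so that A1 is always the minor allele (idempotent)."""
    freq = allele_frequency(gm).to_numpy()
    var = gm.variants.copy()
    dos = gm.dosage.copy()
    a1 = var["a1"].to_numpy().copy()
    a2 = var["a2"].to_numpy().copy()
    flip = (freq > 0.5) | ((freq == 0.5) & (a2 < a1))
    dos[:, flip] = 2.0 - dos[:, flip]
    a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
    var["a1"], var["a2"] = a1, a2
    return GenotypeMatrix(list(gm.samples), var, dos, phased=gm.phased)


def qc_filter(
    gm: GenotypeMatrix,
    mind: float = 0.2,
    geno: float = 0.25,
    maf: float = 0.02,
) -> tuple[GenotypeMatrix, QcReport]:
    """PLINK-style QC: mind -> geno -> maf, frequencies recomputed after
    sample removal. Removal rules: sample missingness > mind; variant
    missingness > geno; MAF strictly < maf (MAF == maf is retained).
    """
    for name, t in (("mind", mind), ("geno", geno), ("maf", maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} threshold must be in [0,1], got {t}")
    miss_s = np.mean(np.isnan(gm.dosage), axis=1)
    keep_samples = miss_s <= mind
    removed_samples = pd.DataFrame(
        {
            "id": [s for s, k in zip(gm.samples, keep_samples) if not k],
            "missingness": miss_s[~keep_samples],
        }
    )
    if not keep_samples.any():
        raise ValueError("all samples removed by --mind filter")
    gm = gm.subset(samples=[s for s, k in zip(gm.samples, keep_samples) if k])

    miss_v = np.mean(np.isnan(gm.dosage), axis=0)
    keep_geno = miss_v <= geno
    removed = [
        {"id": v, "reason": "geno"}
        for v in gm.variants.loc[~keep_geno, "id"]
    ]
    gm = gm.subset(variant_mask=keep_geno)

    gm = recode_minor(gm)
    freq = allele_frequency(gm).to_numpy()
    keep_maf = freq >= maf
    removed += [
        {"id": v, "reason": "maf"} for v in gm.variants.loc[~keep_maf, "id"]
    ]
    gm = gm.subset(variant_mask=keep_maf)
    report = QcReport(
        removed_samples=removed_samples,
        removed_variants=pd.DataFrame(removed, columns=["id", "reason"]),
        thresholds={"mind": mind, "geno": geno, "maf": maf},
    )
    return gm, report


def _fmt(freq: float, count: int) -> str:
    return f"{round(freq, 2):g} ({count})"


def genotype_group_table(
    gm: GenotypeMatrix,
    statuses: Mapping[str, str],
    variant_ids: Sequence[str],
    groups: Sequence[str] = ("case", "carrier", "control"),
) -> pd.DataFrame:
    """Per-variant, per-group frequency and count of A1A1 and A1A2 genotypes.

    Output cells are formatted "0.26 (8)" as in the association summary
    tables; numeric columns are included alongside.
    """
    cols = gm.variant_index(variant_ids)
    rows = []
    for vid, j in zip(variant_ids, cols):
        v = gm.variants.iloc[j]
        row: dict = {"id": vid, "chrom": v["chrom"], "bp": v["bp"], "a1": v["a1"], "a2": v["a2"]}
        for grp in groups:
            members = [s for s in gm.samples if statuses.get(s) == grp]
            n = len(members)
            if n == 0:
                hom = het = 0
            else:
                dos = gm.dosage[gm.sample_index(members), j]
                hom = int(np.sum(dos == 2))
                het = int(np.sum(dos == 1))
            row[f"{grp}_A1A1"] = _fmt(hom / n if n else 0.0, hom)
            row[f"{grp}_A1A2"] = _fmt(het / n if n else 0.0, het)
            row[f"{grp}_n_hom"] = hom
            row[f"{grp}_n_het"] = het
            row[f"{grp}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def merge_on_shared_variants(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two cohorts on their shared variants; refuses allele conflicts."""
    shared = [v for v in a.variants["id"] if v in set(b.variants["id"])]
    if not shared:
        raise ValueError("no shared variants between panels")
    ia, ib = a.variant_index(shared), b.variant_index(shared)
    va = a.variants.iloc[ia].reset_index(drop=True)
    vb = b.variants.iloc[ib].reset_index(drop=True)
    conflict = (
        ((va["a1"] != vb["a1"]) | (va["a2"] != vb["a2"]))
        & ((va["a1"] != vb["a2"]) | (va["a2"] != vb["a1"]))
    )
    if conflict.any():
        bad = list(va.loc[conflict, "id"][:5])
        raise ValueError(f"allele conflict between panels at variants {bad}")
    dup = set(a.samples) & set(b.samples)
    if dup:
        raise ValueError(f"duplicate sample ids across panels: {sorted(dup)[:5]}")
    dos_b = b.dosage[:, ib].copy()
    flipped = va["a1"].to_numpy() != vb["a1"].to_numpy()
    dos_b[:, flipped] = 2.0 - dos_b[:, flipped]
    merged = GenotypeMatrix(
        list(a.samples) + list(b.samples),
        va,
        np.vstack([a.dosage[:, ia], dos_b]),
    )
    return recode_minor(merged)
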