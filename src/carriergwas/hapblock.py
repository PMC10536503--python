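"""Haplotype blocks: D' confidence intervals, Gabriel-style block detection,
EM haplotype-frequency estimation, and per-haplotype association.

Blocks are detected with the confidence-interval criterion of Gabriel et al.:
a SNP pair is in "strong LD" when the 90% interval for |D'| has a lower bound
>= 0.70 and an upper bound >= 0.98, shows "strong evidence of recombination"
when the upper bound is < 0.90, and a candidate span is a block when at least
95% of its informative pairs are in strong LD. Haplotype frequencies within a
block come from an EM algorithm over the diplotypes consistent with each
multilocus genotype (expectation-maximisation phasing); association uses the
expected per-sample haplotype dosage, while the per-group homozygosity tables
use the best (maximum-posterior) diplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genio import GenotypeMatrix

__all__ = [
    "HaplotypeBlock",
    "HaplotypeTable",
    "dprime_ci",
    "find_blocks",
    "em_hap_freqs",
    "hap_association",
    "hap_homozygosity_by_group",
]

MAX_BLOCK_SNPS = 20


@dataclass
class HaplotypeBlock:
    chrom: str
    snp_ids: list[str]
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if len(self.snp_ids) < 2:
            raise ValueError("a haplotype block needs >= 2 SNPs")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def _two_snp_em(gi: np.ndarray, gj: np.ndarray, tol: float = 1e-10,
                max_iter: int = 500) -> np.ndarray:
    """EM haplotype frequencies for two SNPs from 0/1/2 dosages.

    Returns freqs indexed by haplotype bits (allele_i << 1) | allele_j:
    [00, 01, 10, 11]. Only the double heterozygote is phase-ambiguous.
    """
    n = len(gi)
    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((gi == a) & (gj == b))
    # Unambiguous haplotype counts.
    base = np.zeros(4)
    for a in range(3):
        for b in range(3):
            c = counts[a, b]
            if c == 0 or (a == 1 and b == 1):
                continue
            if a == 1 and b != 1:
                bb = 0 if b == 0 else 1
                base[(0 << 1) | bb] += c
                base[(1 << 1) | bb] += c
            elif b == 1 and a != 1:
                aa = 0 if a == 0 else 1
                base[(aa << 1) | 0] += c
                base[(aa << 1) | 1] += c
            else:
                aa = 0 if a == 0 else 1
                bb = 0 if b == 0 else 1
                base[(aa << 1) | bb] += 2 * c
    ndh = counts[1, 1]
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        # Split double hets between coupling (00/11) and repulsion (01/10).
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        x = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = base.copy()
        new[0] += ndh * x
        new[3] += ndh * x
        new[1] += ndh * (1 - x)
        new[2] += ndh * (1 - x)
        new /= 2.0 * n
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def _genotype_probs_from_haps(f: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype probabilities from 4 haplotype frequencies."""
    probs = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            a = (h1 >> 1) + (h2 >> 1)
            b = (h1 & 1) + (h2 & 1)
            probs[a, b] += f[h1] * f[h2]
    return probs


def dprime_ci(
    gm: GenotypeMatrix,
    snp_i: str,
    snp_j: str,
    grid: int = 101,
    mass: float = 0.90,
) -> dict:
    """|D'| point estimate with a 90% highest-density interval.

    Profiles the multinomial likelihood of the observed two-locus genotype
    table over a grid of |D'| values (haplotype frequencies constrained to
    the sample allele frequencies, D in the direction of the EM estimate),
    normalises it to a posterior with a flat prior, and returns the HDI
    endpoints. Pairs with fewer than 10 informative chromosomes are flagged.
    """
    ii, jj = gm.variant_index([snp_i, snp_j])
    gi, gj = gm.dosage[:, ii], gm.dosage[:, jj]
    ok = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[ok], gj[ok]
    uninformative = 2 * len(gi) < 10
    pA = float(np.mean(gi)) / 2.0
    pB = float(np.mean(gj)) / 2.0
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return {"dprime": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "uninformative": True}
    f_em = _two_snp_em(gi, gj)
    D_em = f_em[3] - (f_em[2] + f_em[3]) * (f_em[1] + f_em[3])
    sign = 1.0 if D_em >= 0 else -1.0
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if sign > 0 else min(pA * pB, (1 - pA) * (1 - pB))
    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((gi == a) & (gj == b))
    dgrid = np.linspace(0.0, 1.0, grid)
    ll = np.full(grid, -np.inf)
    eps = 1e-12
    for k, d in enumerate(dgrid):
        D = sign * d * dmax
        f = np.array(
            [
                (1 - pA) * (1 - pB) + D,
                (1 - pA) * pB - D,
                pA * (1 - pB) - D,
                pA * pB + D,
            ]
        )
        if np.any(f < -1e-9):
            continue
        f = np.clip(f, eps, None)
        f /= f.sum()
        probs = np.clip(_genotype_probs_from_haps(f), eps, None)
        ll[k] = float(np.sum(counts * np.log(probs)))
    post = np.exp(ll - np.max(ll))
    post /= post.sum()
    order = np.argsort(post)[::-1]
    acc, included = 0.0, []
    for k in order:
        included.append(k)
        acc += post[k]
        if acc >= mass:
            break
    lo = float(dgrid[min(included)])
    hi = float(dgrid[max(included)])
    point = float(dgrid[int(np.argmax(post))])
    return {"dprime": point, "ci_low": lo, "ci_high": hi, "uninformative": uninformative}


def find_blocks(
    gm: GenotypeMatrix,
    chromosome: str,
    ci_strong_low: float = 0.70,
    ci_strong_high: float = 0.98,
    ci_recomb_high: float = 0.90,
    informative_frac: float = 0.95,
    max_span_kb: float = 200.0,
    maf_floor: float = 0.05,
) -> list[HaplotypeBlock]:
    """Gabriel-style haplotype blocks on one chromosome.

    Pairs are classified from their |D'| 90% interval: strong LD when
    (ci_low >= ci_strong_low and ci_high >= ci_strong_high), recombination
    when ci_high < ci_recomb_high. A candidate span [i, j] is a block when
    its endpoint pair is strong LD and at least ``informative_frac`` of its
    informative pairs are strong LD; candidates are accepted greedily,
    longest (bp span) first, without overlap. SNPs below ``maf_floor`` are
    not considered for block membership.
    """
    mask = (gm.variants["chrom"].astype(str) == str(chromosome)).to_numpy()
    if not mask.any():
        raise KeyError(f"chromosome {chromosome!r} not present")
    sub = gm.subset(variant_mask=mask)
    freqs = np.nanmean(sub.dosage, axis=0) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    keep = maf >= maf_floor
    sub = sub.subset(variant_mask=keep)
    ids = list(sub.variants["id"])
    bps = sub.variants["bp"].to_numpy()
    m = len(ids)
    max_span = max_span_kb * 1000.0

    strong = {}
    recomb = {}
    for i in range(m):
        for j in range(i + 1, m):
            if bps[j] - bps[i] > max_span:
                break
            ci = dprime_ci(sub, ids[i], ids[j])
            if ci["uninformative"] or np.isnan(ci["dprime"]):
                continue
            if ci["ci_low"] >= ci_strong_low and ci["ci_high"] >= ci_strong_high:
                strong[(i, j)] = True
            elif ci["ci_high"] < ci_recomb_high:
                recomb[(i, j)] = True

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if bps[j] - bps[i] > max_span:
                break
            if (i, j) not in strong:
                continue
            n_strong = n_recomb = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    if (a, b) in strong:
                        n_strong += 1
                    elif (a, b) in recomb:
                        n_recomb += 1
            informative = n_strong + n_recomb
            if informative == 0 or n_strong / informative < informative_frac:
                continue
            candidates.append((bps[j] - bps[i], i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for span, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            HaplotypeBlock(str(chromosome), ids[i : j + 1], int(bps[i]), int(bps[j]))
        )
    blocks.sort(key=lambda b: b.start_bp)
    return blocks


@dataclass
class HaplotypeTable:
    """EM haplotype frequencies and per-sample diplotype posteriors.

    ``haplotypes`` are allele strings using each variant's A1/A2 letters;
    ``posteriors`` holds, per sample, a list of ((h1, h2), probability)
    over unordered diplotypes; ``best`` is the maximum-posterior diplotype
    (None for samples with missing calls in the block, which are excluded
    from the EM).
    """

    block: HaplotypeBlock
    haplotypes: list[str]
    freqs: np.ndarray
    samples: list[str]
    posteriors: dict[str, list[tuple[tuple[int, int], float]]]
    best: dict[str, tuple[int, int] | None]
    loglik: float = 0.0
    loglik_trace: list[float] = field(default_factory=list)

    def expected_dosage(self, hap_index: int) -> pd.Series:
        out = {}
        for s in self.samples:
            post = self.posteriors.get(s)
            if post is None:
                out[s] = np.nan
                continue
            out[s] = sum(
                p * ((h1 == hap_index) + (h2 == hap_index)) for (h1, h2), p in post
            )
        return pd.Series(out)


def _compatible_diplotypes(genotype: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with a 0/1/2 genotype vector."""
    het = np.where(genotype == 1)[0]
    fixed1 = genotype == 2
    out = []
    n_het = len(het)
    if n_het == 0:
        h = tuple(int(x) for x in fixed1)
        return [(h, h)]
    # Fix the first het site's allele on haplotype 1 to avoid double counting.
    for assign in range(2 ** (n_het - 1)):
        h1 = fixed1.astype(int).copy()
        h2 = fixed1.astype(int).copy()
        bits = [1] + [(assign >> k) & 1 for k in range(n_het - 1)]
        for site, bit in zip(het, bits):
            h1[site] = bit
            h2[site] = 1 - bit
        out.append((tuple(h1), tuple(h2)))
    return out


def em_hap_freqs(
    gm: GenotypeMatrix,
    block: HaplotypeBlock,
    tol: float = 1e-6,
    max_iter: int = 1000,
    prune: float = 1e-4,
) -> HaplotypeTable:
    """EM haplotype frequencies within a block (enumeration phasing).

    Initialises at linkage-equilibrium products of the allele frequencies,
    iterates expectation/maximisation over the diplotypes consistent with
    each multilocus genotype until the largest frequency change is below
    ``tol``, and prunes haplotypes below ``prune``. The log-likelihood is
    non-decreasing across iterations. Samples with missing calls inside the
    block are excluded from estimation.
    """
    if block.n_snps > MAX_BLOCK_SNPS:
        raise ValueError(
            f"block of {block.n_snps} SNPs exceeds the enumeration bound "
            f"({MAX_BLOCK_SNPS}); split it"
        )
    cols = gm.variant_index(block.snp_ids)
    G = gm.dosage[:, cols]
    var = gm.variants.iloc[cols]
    a1 = var["a1"].to_numpy()
    a2 = var["a2"].to_numpy()

    complete = ~np.isnan(G).any(axis=1)
    patterns: dict[tuple, list[int]] = {}
    for i in np.where(complete)[0]:
        patterns.setdefault(tuple(int(x) for x in G[i]), []).append(i)
    if not patterns:
        raise ValueError("no samples with complete genotypes in block")

    # Haplotype universe: union over compatible diplotypes.
    pattern_pairs = {g: _compatible_diplotypes(np.array(g)) for g in patterns}
    hap_set: dict[tuple, int] = {}
    for pairs in pattern_pairs.values():
        for h1, h2 in pairs:
            for h in (h1, h2):
                hap_set.setdefault(h, len(hap_set))
    haps = sorted(hap_set, key=lambda h: hap_set[h])
    hidx = {h: k for k, h in enumerate(haps)}
    K = len(haps)

    p_allele = np.nanmean(G[complete], axis=0) / 2.0
    f = np.array(
        [np.prod(np.where(np.array(h) == 1, p_allele, 1 - p_allele)) for h in haps]
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    n_weight = np.array([len(patterns[g]) for g in patterns], dtype=float)
    pairs_by_pattern = [
        [(hidx[h1], hidx[h2]) for h1, h2 in pattern_pairs[g]] for g in patterns
    ]
    total = n_weight.sum()

    trace = []
    for _ in range(max_iter):
        counts = np.zeros(K)
        ll = 0.0
        for w, pairs in zip(n_weight, pairs_by_pattern):
            probs = np.array(
                [f[i] * f[j] * (2.0 if i != j else 1.0) for i, j in pairs]
            )
            tot = probs.sum()
            ll += w * np.log(max(tot, 1e-300))
            probs /= max(tot, 1e-300)
            for (i, j), pr in zip(pairs, probs):
                counts[i] += w * pr
                counts[j] += w * pr
        trace.append(ll)
        new = counts / (2.0 * total)
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new

    posteriors: dict[str, list[tuple[tuple[int, int], float]]] = {}
    best: dict[str, tuple[int, int] | None] = {}
    for gpat, members in patterns.items():
        pairs = [(hidx[h1], hidx[h2]) for h1, h2 in pattern_pairs[gpat]]
        probs = np.array([f[i] * f[j] * (2.0 if i != j else 1.0) for i, j in pairs])
        tot = probs.sum()
        probs = probs / tot if tot > 0 else np.full(len(pairs), 1.0 / len(pairs))
        entry = [(pq, float(pr)) for pq, pr in zip(pairs, probs)]
        top = np.max(probs)
        ties = [pairs[k] for k in range(len(pairs)) if probs[k] >= top - 1e-12]
        # On a posterior tie the sample must not count as homozygous: prefer
        # a heterozygous diplotype among the tied maximisers.
        if len(ties) == 1:
            chosen = ties[0]
        else:
            het_ties = [t for t in ties if t[0] != t[1]]
            chosen = het_ties[0] if het_ties else ties[0]
        for i in members:
            sid = gm.samples[i]
            posteriors[sid] = entry
            best[sid] = chosen
    for i in np.where(~complete)[0]:
        posteriors[gm.samples[i]] = None  # type: ignore[assignment]
        best[gm.samples[i]] = None

    keep = f >= prune
    # Keep indices stable for posteriors by not renumbering: zero out pruned.
    f = np.where(keep, f, 0.0)
    s = f.sum()
    if s > 0:
        f = f / s
    strings = ["".join(a1[k] if bit else a2[k] for k, bit in enumerate(h)) for h in haps]
    return HaplotypeTable(
        block=block,
        haplotypes=strings,
        freqs=f,
        samples=list(gm.samples),
        posteriors=posteriors,
        best=best,
        loglik=trace[-1] if trace else np.nan,
        loglik_trace=trace,
    )


def hap_association(
    gm: GenotypeMatrix,
    block: HaplotypeBlock,
    phenotype,
    model: str = "linear",
    table: HaplotypeTable | None = None,
    rare_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-haplotype regression of phenotype on expected haplotype dosage.

    ``model="linear"`` regresses the quantitative code and reports the slope;
    ``model="logistic"`` fits case/control status and reports an odds ratio
    per dosage unit. Haplotypes below ``rare_floor`` frequency are skipped;
    logistic separation is flagged with the p-value omitted.
    """
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    if table is None:
        table = em_hap_freqs(gm, block)
    if isinstance(phenotype, (dict, pd.Series)):
        pheno = pd.Series(phenotype)
    else:
        pheno = pd.Series(phenotype, index=gm.samples)
    rows = []
    for k, (hap, freq) in enumerate(zip(table.haplotypes, table.freqs)):
        if freq < rare_floor:
            continue
        dos = table.expected_dosage(k)
        df = pd.concat([pheno.rename("y"), dos.rename("x")], axis=1, join="inner").dropna()
        if df["x"].std() == 0 or len(df) < 3:
            continue
        X = sm.add_constant(df["x"].to_numpy())
        y = df["y"].to_numpy()
        flagged = False
        if model == "linear":
            fit = sm.OLS(y, X).fit()
            beta = float(fit.params[1])
            pval = float(fit.pvalues[1])
            effect = beta
            or_ = np.nan
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                beta = float(fit.params[1])
                se = float(fit.bse[1])
                if not np.isfinite(se) or se > 50 or abs(beta) > 30:
                    raise np.linalg.LinAlgError("separation")
                pval = float(fit.pvalues[1])
                or_ = float(np.exp(beta))
                effect = beta
            except Exception:
                flagged = True
                beta, pval, or_, effect = np.nan, np.nan, np.nan, np.nan
        rows.append(
            {
                "chrom": block.chrom,
                "start_bp": block.start_bp,
                "end_bp": block.end_bp,
                "n_snps": block.n_snps,
                "haplotype": hap,
                "freq": float(freq),
                "effect": effect,
                "odds_ratio": or_,
                "p": pval,
                "separation": flagged,
            }
        )
    return pd.DataFrame(rows)


def _fmt(freq: float, count: int) -> str:
    return f"{round(freq, 2):g} ({count})"


def hap_homozygosity_by_group(
    table: HaplotypeTable,
    statuses,
    groups=("case", "carrier", "control"),
) -> pd.DataFrame:
    """Per-group frequency and count of best-diplotype homozygotes per haplotype.

    A sample counts as homozygous for haplotype h iff its maximum-posterior
    diplotype is (h, h); a posterior tie is counted as not homozygous.
    """
    statuses = dict(statuses)
    rows = []
    for k, hap in enumerate(table.haplotypes):
        if table.freqs[k] == 0:
            continue
        row: dict = {
            "chrom": table.block.chrom,
            "start_bp": table.block.start_bp,
            "end_bp": table.block.end_bp,
            "haplotype": hap,
            "freq": float(table.freqs[k]),
        }
        for grp in groups:
            members = [s for s in table.samples if statuses.get(s) == grp]
            n = len(members)
            hom = sum(1 for s in members if table.best.get(s) == (k, k))
            row[f"{grp}_hom"] = _fmt(hom / n if n else 0.0, hom)
            row[f"{grp}_n_hom"] = hom
            row[f"{grp}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)
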