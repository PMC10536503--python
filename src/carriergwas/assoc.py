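"""GRM construction, mixed-linear-model association, FDR q-values, LD, stepwise.

The association scan fits, per SNP, the fixed effect b in
``y = mu + b*x + g + e`` with ``g ~ N(0, sigma_g^2 A)``; the variance
components are estimated once under the null (no SNP) by AI-REML and held
fixed, the GCTA-MLMA (non-LOCO) convention, so each per-SNP fit is a
generalized least squares solve. With the GRM eigendecomposed once, the
whole scan reduces to weighted per-SNP regressions and is vectorised.

False discovery rates use Storey's q-value procedure, either genome-wide or
stratified within each chromosome ("chromosome-wise" q-values); strata with
fewer than 100 p-values fall back to pi0 = 1, where the procedure coincides
with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .genio import GenotypeMatrix, allele_frequency
from .herit import VarianceComponents, ai_reml

__all__ = [
    "Grm",
    "StepwiseResult",
    "compute_grm",
    "mlma_scan",
    "qvalues",
    "ld_r2",
    "backward_stepwise",
]


@dataclass
class Grm:
    """SNP-derived genetic relationship matrix over ``ids`` from ``m`` SNPs."""

    ids: list[str]
    matrix: np.ndarray
    m: int


def compute_grm(gm: GenotypeMatrix) -> Grm:
    """GCTA-style GRM.

    Off-diagonal: A_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i));
    diagonal: A_jj = 1 + (1/M) sum_i [x_ij^2 - (1+2p_i)x_ij + 2p_i^2] / (2p_i(1-p_i)).
    Monomorphic SNPs are skipped; missing dosages are mean-imputed per SNP.
    """
    X = gm.dosage.copy()
    p = allele_frequency(gm).to_numpy()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs: cannot build a GRM")
    X = X[:, poly]
    p = p[poly]
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    M = X.shape[1]
    denom = 2.0 * p * (1.0 - p)
    W = (X - 2.0 * p) / np.sqrt(denom)
    A = (W @ W.T) / M
    diag = 1.0 + np.sum((X**2 - (1.0 + 2.0 * p) * X + 2.0 * p**2) / denom, axis=1) / M
    np.fill_diagonal(A, diag)
    return Grm(list(gm.samples), A, M)


def mlma_scan(
    gm: GenotypeMatrix,
    grm: Grm,
    phenotype,
    covariates: np.ndarray | None = None,
    variance: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Mixed-linear-model association scan over every SNP.

    ``phenotype`` is a mapping/Series by sample id (the 2/1/0 quantitative
    code or the 0/1 binary code). Returns a per-SNP frame with columns
    Chr, SNP, bp, A1, Freq, b, se, p. Zero-variance SNPs get b=0, p=1 and
    ``flagged=True``. Pass ``variance`` to reuse an existing null REML fit.
    """
    samples = [s for s in gm.samples if s in set(grm.ids)]
    if isinstance(phenotype, (dict, pd.Series)):
        samples = [s for s in samples if s in phenotype]
        y = np.array([float(phenotype[s]) for s in samples])
    else:
        y = np.asarray(phenotype, dtype=float)
    gmat = grm.matrix[np.ix_(
        [grm.ids.index(s) for s in samples], [grm.ids.index(s) for s in samples]
    )]
    sub = gm.subset(samples=samples)
    X = sub.dosage.copy()
    if np.isnan(X).any():
        col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]

    if variance is None:
        variance = ai_reml(Grm(samples, gmat, grm.m), y, covariates=covariates)
    vg, ve = variance.vg, variance.ve

    # V = vg*A + ve*I = U diag(vg*d + ve) U'; whiten everything once.
    # Negative GRM eigenvalues are clipped as in ai_reml.
    d, U = np.linalg.eigh(gmat)
    d = np.clip(d, 0.0, None)
    w = vg * d + ve
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("singular phenotypic covariance in MLMA")
    s = 1.0 / np.sqrt(w)
    yt = (U.T @ y) * s
    Xt = (U.T @ X) * s[:, None]
    covs = [np.ones(len(y))]
    if covariates is not None:
        cov_arr = np.asarray(covariates, dtype=float)
        covs += [cov_arr[:, k] for k in range(cov_arr.reshape(len(y), -1).shape[1])]
    C = np.column_stack(covs)
    Ct = (U.T @ C) * s[:, None]
    # Project the SNP and phenotype off the whitened covariates, then the
    # per-SNP GLS slope is a simple ratio.
    Q, _ = np.linalg.qr(Ct)
    y_res = yt - Q @ (Q.T @ yt)
    X_res = Xt - Q @ (Q.T @ Xt)
    xx = np.sum(X_res**2, axis=0)
    zero = xx <= 1e-12
    xx_safe = np.where(zero, 1.0, xx)
    b = (X_res.T @ y_res) / xx_safe
    se = np.sqrt(1.0 / xx_safe)  # residual variance is 1 after whitening by V
    chi2 = (b / se) ** 2
    p = stats.chi2.sf(chi2, df=1)
    b[zero] = 0.0
    p[zero] = 1.0
    se[zero] = np.nan

    out = sub.variants[["chrom", "id", "bp", "a1"]].rename(
        columns={"chrom": "Chr", "id": "SNP", "a1": "A1"}
    ).copy()
    out["Freq"] = allele_frequency(sub).to_numpy()
    out["b"] = b
    out["se"] = se
    out["p"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["flagged"] = zero
    out.attrs["variance"] = variance
    return out


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's pi0 estimate: smooth pi0(lambda) over a lambda grid and
    evaluate at the largest lambda; clipped to (0, 1]."""
    lam = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    spline = UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(
    pvals,
    strata=None,
    pi0: float | None = None,
    min_stratum_size: int = 100,
) -> np.ndarray:
    """Storey q-values, optionally stratified (e.g. by chromosome).

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the ordered p-values of the
    stratum. pi0 is estimated by the smoother unless given; strata smaller
    than ``min_stratum_size`` use pi0 = 1, i.e. Benjamini-Hochberg.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = np.empty_like(p)
    if strata is None:
        groups = {None: np.arange(len(p))}
    else:
        strata = np.asarray(strata)
        groups = {s: np.where(strata == s)[0] for s in pd.unique(strata)}
    for _, idx in groups.items():
        ps = p[idx]
        m = len(ps)
        if pi0 is not None:
            pi0_s = pi0
        elif m < min_stratum_size:
            pi0_s = 1.0
        else:
            pi0_s = _storey_pi0(ps)
        order = np.argsort(ps, kind="mergesort")
        ranked = ps[order] * pi0_s * m / np.arange(1, m + 1)
        qs = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.minimum(qs, 1.0)
        out = np.empty(m)
        out[order] = qs
        q[idx] = out
    return q


def ld_r2(gm: GenotypeMatrix, snp_i: str, snp_j: str) -> dict:
    """Two-SNP LD from EM haplotype frequencies: r^2 and D'.

    Raises for a monomorphic member (LD undefined).
    """
    from .hapblock import _two_snp_em  # shared EM core

    ii, jj = gm.variant_index([snp_i, snp_j])
    gi = gm.dosage[:, ii]
    gj = gm.dosage[:, jj]
    ok = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[ok], gj[ok]
    for name, g in ((snp_i, gi), (snp_j, gj)):
        if len(np.unique(g)) < 2:
            raise ValueError(f"variant {name} is monomorphic: LD undefined")
    hap = _two_snp_em(gi, gj)
    pA = hap[2] + hap[3]  # freq of allele 1 at SNP i (index bit 1)
    pB = hap[1] + hap[3]  # freq of allele 1 at SNP j (index bit 0)
    D = hap[3] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D**2 / denom if denom > 0 else np.nan
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D > 0 else min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    return {"r2": float(r2), "dprime": float(dprime), "D": float(D)}


@dataclass
class StepwiseResult:
    retained: list[str]
    rse: float
    df_resid: int
    adj_r2: float
    model_pvalue: float
    aic: float


def _ols_aic(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * (k + 1)  # +1 for the error variance
    return aic, rss


def backward_stepwise(
    gm: GenotypeMatrix,
    phenotype,
    candidate_snps,
    condition_limit: float = 1e10,
) -> StepwiseResult:
    """AIC-guided backward elimination of an ordinary linear model on dosages.

    Starting from all candidate SNPs, repeatedly drops the predictor whose
    removal lowers AIC most, stopping when no removal lowers it. Near-collinear
    predictor groups are thinned (keep-first) before the search, with a warning.
    """
    if isinstance(phenotype, (dict, pd.Series)):
        samples = [s for s in gm.samples if s in phenotype]
        y = np.array([float(phenotype[s]) for s in samples])
        sub = gm.subset(samples=samples)
    else:
        y = np.asarray(phenotype, dtype=float)
        sub = gm
    candidates = list(candidate_snps)
    n = len(y)
    if n <= len(candidates) + 1:
        raise ValueError(
            f"need n > candidates+1 (n={n}, candidates={len(candidates)})"
        )
    cols = sub.variant_index(candidates)
    X = sub.dosage[:, cols].copy()
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]

    # Drop one of each perfectly/near collinear pair up front.
    keep = list(range(X.shape[1]))
    design = np.column_stack([np.ones(n), X])
    while np.linalg.cond(design) > condition_limit and len(keep) > 1:
        # Remove the predictor most explained by the others.
        corr = np.corrcoef(X[:, keep].T)
        np.fill_diagonal(corr, 0.0)
        worst = keep[int(np.argmax(np.max(np.abs(corr), axis=1)))]
        keep.remove(worst)
        warnings.warn(
            f"dropping near-collinear predictor {candidates[worst]}", stacklevel=2
        )
        design = np.column_stack([np.ones(n), X[:, keep]])

    current = list(keep)
    aic, _ = _ols_aic(np.column_stack([np.ones(n), X[:, current]]), y)
    improved = True
    while improved and current:
        improved = False
        best_aic, best_drop = aic, None
        for j in current:
            trial = [c for c in current if c != j]
            a, _ = _ols_aic(np.column_stack([np.ones(n), X[:, trial]]), y)
            if a < best_aic - 1e-9:
                best_aic, best_drop = a, j
        if best_drop is not None:
            current.remove(best_drop)
            aic = best_aic
            improved = True

    Xf = np.column_stack([np.ones(n), X[:, current]])
    k = Xf.shape[1]
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    resid = y - Xf @ beta
    rss = float(resid @ resid)
    df = n - k
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan
    if current and k > 1 and df > 0:
        if r2 >= 1.0:
            pval = 0.0
        else:
            fstat = (r2 / (k - 1)) / ((1 - r2) / df)
            pval = float(stats.f.sf(fstat, k - 1, df))
    else:
        pval = 1.0
    return StepwiseResult(
        retained=[candidates[c] for c in current],
        rse=float(np.sqrt(rss / df)) if df > 0 else np.nan,
        df_resid=df,
        adj_r2=adj,
        model_pvalue=pval,
        aic=aic,
    )
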