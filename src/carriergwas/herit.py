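"""REML variance components with a GRM and liability-scale heritability.

``ai_reml`` estimates the genetic and residual variances of
``y = Xb + g + e`` with ``g ~ N(0, sigma_g^2 A)`` by average-information
REML with an EM-REML fallback step, returning the observed-scale
heritability V(G)/Vp with a delta-method standard error and a likelihood
ratio test against V(G) = 0 (boundary-mixture p-value, half a chi-square
with one degree of freedom).

``liability_transform`` converts an observed-scale case-control heritability
to the underlying liability scale with the ascertainment-corrected
threshold-model factor

    c = [K(1-K)/z^2] * [K(1-K)/(P(1-P))]

where K is the assumed population prevalence, P the sample case proportion,
t = Phi^-1(1-K) the liability threshold and z = phi(t) the standard normal
density at the threshold. Both the estimate and its SE scale by c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "LiabilityEstimate",
    "ai_reml",
    "lrt_pvalue",
    "liability_transform",
    "grm_subset",
    "RemlError",
]


class RemlError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    vg: float
    ve: float
    h2_obs: float
    se: float
    logL: float
    logL0: float
    lrt: float
    p_value: float
    n: int
    n_iter: int
    converged: bool

    @property
    def vp(self) -> float:
        return self.vg + self.ve

    def to_hsq_frame(self, liabilities: list["LiabilityEstimate"] | None = None) -> pd.DataFrame:
        rows = [
            {"Source": "V(G)", "Variance": self.vg, "SE": ""},
            {"Source": "V(e)", "Variance": self.ve, "SE": ""},
            {"Source": "Vp", "Variance": self.vp, "SE": ""},
            {"Source": "V(G)/Vp", "Variance": self.h2_obs, "SE": self.se},
        ]
        for le in liabilities or []:
            rows.append(
                {"Source": f"V(G)/Vp_L (K={le.prevalence:g})",
                 "Variance": le.h2_liability, "SE": le.se_liability}
            )
        rows += [
            {"Source": "logL", "Variance": self.logL, "SE": ""},
            {"Source": "logL0", "Variance": self.logL0, "SE": ""},
            {"Source": "LRT", "Variance": self.lrt, "SE": ""},
            {"Source": "Pval", "Variance": self.p_value, "SE": ""},
            {"Source": "n", "Variance": self.n, "SE": ""},
        ]
        return pd.DataFrame(rows)


@dataclass
class LiabilityEstimate:
    prevalence: float
    case_proportion: float
    threshold: float
    density: float
    factor: float
    h2_obs: float
    se_obs: float
    h2_liability: float
    se_liability: float


def _reml_loglik(theta, d, ys, Xs):
    """REML log-likelihood and projection in the GRM eigenbasis.

    With A = U diag(d) U', V = theta0*A + theta1*I shares A's eigenvectors,
    so everything reduces to diagonal weighting of the rotated data
    ``ys = U'y``, ``Xs = U'X``. Returns (logL, P*, P*y) in rotated
    coordinates; quadratic forms and traces are basis-invariant.
    """
    w = theta[0] * d + theta[1]
    if np.any(w <= 0):
        raise RemlError(f"variance matrix not positive definite at theta={theta}")
    winv = 1.0 / w
    logdet_v = float(np.sum(np.log(w)))
    WX = Xs * winv[:, None]
    XtVinvX = Xs.T @ WX
    sign, logdet_x = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise RemlError("X'V^-1X not positive definite")
    P = np.diag(winv) - WX @ np.linalg.solve(XtVinvX, WX.T)
    Py = P @ ys
    logL = -0.5 * (logdet_v + logdet_x + float(ys @ Py))
    return logL, P, Py


def _profile_reml(d, ys, Xs, floor) -> tuple[np.ndarray, float]:
    """Maximise the restricted likelihood over h2 = Vg/Vp on a profile.

    With V = s * (h2 * A + (1-h2) * I), the scale s maximises analytically at
    y'P_M y / (n - p); the remaining 1-D problem in h2 is solved by bounded
    scalar optimisation. Returns (theta, logL) on the same constant
    convention as :func:`_reml_loglik`.
    """
    from scipy.optimize import minimize_scalar

    n, p = Xs.shape

    def neg_profile(h2: float) -> float:
        w = h2 * d + (1.0 - h2)
        if np.any(w <= 0):
            return np.inf
        winv = 1.0 / w
        WX = Xs * winv[:, None]
        XtMinvX = Xs.T @ WX
        sign, logdet_x = np.linalg.slogdet(XtMinvX)
        if sign <= 0:
            return np.inf
        Pys = ys * winv - WX @ np.linalg.solve(XtMinvX, WX.T @ ys)
        quad = float(ys @ Pys)
        s = quad / (n - p)
        logdet_m = float(np.sum(np.log(w)))
        return 0.5 * ((n - p) * np.log(s) + logdet_m + logdet_x + (n - p))

    res = minimize_scalar(
        neg_profile, bounds=(1e-9, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    h2 = float(res.x)
    w = h2 * d + (1.0 - h2)
    winv = 1.0 / w
    WX = Xs * winv[:, None]
    XtMinvX = Xs.T @ WX
    Pys = ys * winv - WX @ np.linalg.solve(XtMinvX, WX.T @ ys)
    s = float(ys @ Pys) / (n - p)
    theta = np.maximum(np.array([h2 * s, (1.0 - h2) * s]), floor)
    logL, _, _ = _reml_loglik(theta, d, ys, Xs)
    return theta, logL


def _null_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Residual-only REML log-likelihood (V = sigma^2 I), same constant
    convention as :func:`_reml_loglik`."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(s2) + logdet_xx + (n - p))


def ai_reml(
    grm,
    phenotype,
    covariates: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    floor_frac: float = 1e-6,
) -> VarianceComponents:
    """Average-information REML for (sigma_g^2, sigma_e^2).

    ``grm`` is a Grm object (``.matrix``, ``.ids``) or a plain symmetric
    array; ``phenotype`` a mapping/Series by id or an array aligned to it.
    Starts at Vp/2 each; an AI step that leaves the feasible region is
    replaced by an EM-REML step; components are floored at
    ``floor_frac * Vp``. The SE of V(G)/Vp comes from the inverse AI matrix
    by the delta method.
    """
    if hasattr(grm, "matrix"):
        A = np.asarray(grm.matrix, dtype=float)
        ids = list(grm.ids)
    else:
        A = np.asarray(grm, dtype=float)
        ids = None
    n = A.shape[0]
    if n < 30:
        raise RemlError(f"need n >= 30 samples for REML, got {n}")
    if np.linalg.norm(A - np.eye(n)) / n < 1e-8:
        raise RemlError("GRM is (numerically) the identity: variance components unidentifiable")

    if isinstance(phenotype, (dict, pd.Series)) and ids is not None:
        y = np.array([float(phenotype[i]) for i in ids])
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != n:
            raise ValueError("phenotype length does not match GRM")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )

    vp = float(np.var(y, ddof=1))
    floor = floor_frac * vp
    theta = np.array([vp / 2, vp / 2])

    # Rotate once into the GRM eigenbasis; V is diagonal there. Small
    # negative eigenvalues (an artefact of the GRM diagonal adjustment on
    # finite SNP panels) are clipped to zero so V stays positive definite
    # for any positive residual variance.
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    logL, P, Py = _reml_loglik(theta, d, ys, Xs)
    ai = np.eye(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # In the eigenbasis V1 = diag(d), V2 = I.
        PyV = [d * Py, Py]
        trPV = [float(np.sum(P.diagonal() * d)), float(np.trace(P))]
        score = np.array(
            [-0.5 * (trPV[k] - float(np.dot(Py, PyV[k]))) for k in range(2)]
        )
        ai = np.array(
            [[0.5 * float(PyV[i] @ P @ PyV[j]) for j in range(2)] for i in range(2)]
        )
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = score / max(np.trace(ai), 1e-12)
        # AI step with step-halving; an infeasible step is projected onto
        # the floor (a component pinned at the boundary is legitimate).
        proposal = None
        for t in range(5):
            cand = theta + delta * 0.5**t
            if np.all(cand >= floor):
                proposal = cand
                break
        if proposal is None:
            proposal = np.maximum(theta + delta, floor)
        new_logL, newP, newPy = _reml_loglik(proposal, d, ys, Xs)
        if new_logL < logL - 1e-10:
            # Guard monotonicity with an EM-REML step instead.
            em = np.array(
                [
                    theta[k] + (theta[k] ** 2 / n) * (float(Py @ PyV[k]) - trPV[k])
                    for k in range(2)
                ]
            )
            proposal = np.maximum(em, floor)
            new_logL, newP, newPy = _reml_loglik(proposal, d, ys, Xs)
        dl = new_logL - logL
        theta, P, Py = proposal, newP, newPy
        logL = new_logL
        if abs(dl) < tol:
            converged = True
            break
    if not converged:
        # Near the Vg/Vp boundary the AI/EM iteration can crawl; finish with
        # the profiled restricted likelihood over the variance ratio, which
        # is one-dimensional (the overall scale maximises analytically).
        theta, logL = _profile_reml(d, ys, Xs, floor)
        _, P, Py = _reml_loglik(theta, d, ys, Xs)
        PyV = [d * Py, Py]
        ai = np.array(
            [[0.5 * float(PyV[i] @ P @ PyV[j]) for j in range(2)] for i in range(2)]
        )
        converged = True

    vg, ve = float(theta[0]), float(theta[1])
    h2 = vg / (vg + ve)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    grad = np.array([ve, -vg]) / (vg + ve) ** 2
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    logL0 = _null_loglik(y, X)
    if logL < logL0:
        # Boundary fits (Vg at the floor) can converge a hair below the
        # null optimum; polish with the profiled likelihood.
        theta, logL = _profile_reml(d, ys, Xs, floor)
        _, P, Py = _reml_loglik(theta, d, ys, Xs)
        PyV = [d * Py, Py]
        ai = np.array(
            [[0.5 * float(PyV[i] @ P @ PyV[j]) for j in range(2)] for i in range(2)]
        )
        vg, ve = float(theta[0]), float(theta[1])
        h2 = vg / (vg + ve)
        try:
            cov = np.linalg.inv(ai)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        grad = np.array([ve, -vg]) / (vg + ve) ** 2
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        logL = max(logL, logL0)
    lrt = max(2.0 * (logL - logL0), 0.0)
    return VarianceComponents(
        vg=vg, ve=ve, h2_obs=h2, se=se, logL=logL, logL0=logL0,
        lrt=lrt, p_value=lrt_pvalue(logL, logL0), n=n, n_iter=it,
        converged=converged,
    )


def lrt_pvalue(logL: float, logL0: float, tol: float = 1e-6, boundary: bool = True) -> float:
    """Likelihood-ratio p-value for V(G) > 0.

    Under the boundary-mixture convention the null distribution is
    0.5*chi2_0 + 0.5*chi2_1, so p = 0.5 * P(chi2_1 > LRT); set
    ``boundary=False`` for a plain chi2_1 test.
    """
    lrt = 2.0 * (logL - logL0)
    if lrt < -tol:
        raise ValueError(f"negative LRT {lrt:.3g}: logL < logL0 beyond tolerance")
    lrt = max(lrt, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    return 0.5 * p if boundary else p


def liability_transform(
    h2_obs: float,
    se_obs: float,
    prevalence: float,
    n_cases: int,
    n_total: int,
) -> LiabilityEstimate:
    """Observed-scale to liability-scale heritability conversion.

    Uses the threshold-model factor with ascertainment correction for the
    sample case proportion P = n_cases / n_total (see module docstring).
    """
    K = float(prevalence)
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {K}")
    if not 0 < n_cases < n_total:
        raise ValueError("need 0 < n_cases < n_total")
    P = n_cases / n_total
    t = stats.norm.ppf(1.0 - K)
    z = stats.norm.pdf(t)
    c = (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P)))
    return LiabilityEstimate(
        prevalence=K,
        case_proportion=P,
        threshold=float(t),
        density=float(z),
        factor=float(c),
        h2_obs=h2_obs,
        se_obs=se_obs,
        h2_liability=c * h2_obs,
        se_liability=c * se_obs,
    )


def grm_subset(gm, region: str | None = None):
    """GRM built only from SNPs in a region.

    ``region`` is ``None`` (all SNPs), a chromosome label (``"18"``), or a
    range ``"18:37000000-56000000"`` (1-based, inclusive).
    """
    from .assoc import compute_grm  # late import; assoc imports ai_reml from here

    if region is None:
        return compute_grm(gm)
    region = str(region)
    variants = gm.variants
    if ":" in region:
        chrom, span = region.split(":", 1)
        lo, hi = (int(x) for x in span.split("-"))
        mask = (
            (variants["chrom"] == chrom)
            & (variants["bp"] >= lo)
            & (variants["bp"] <= hi)
        ).to_numpy()
    else:
        mask = (variants["chrom"] == region).to_numpy()
    if not mask.any():
        raise ValueError(f"no SNPs in region {region!r}")
    return compute_grm(gm.subset(variant_mask=mask))
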