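"""Pairwise IBS distances, method-of-moments IBD (PIHAT), and mutual-kNN graphs.

PIHAT follows the classic --genome-style moment estimator: expected
identity-by-state (IBS) state probabilities given identity-by-descent (IBD)
state are computed from sample allele frequencies, observed IBS counts are
inverted to IBD-state proportions Z0/Z1/Z2, the estimates are truncated to
[0,1] and renormalised, and PIHAT = Z2 + Z1/2. Small-sample bias corrections
of the original implementation are intentionally omitted; the estimator is
validated against pedigree expectations instead.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, allele_frequency

__all__ = ["ibs_distance_matrix", "pihat", "mknn_graph"]


def ibs_distance_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise 1 − (mean IBS / 2) over shared non-missing SNPs.

    IBS per SNP is 2 − |dosage_i − dosage_j| ∈ {0, 1, 2}. A pair with no
    shared non-missing SNP gets a NaN distance with a warning.
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    X = gm.dosage
    called = ~np.isnan(X)
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:])  # (n-i-1, m), NaN where either missing
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_ibs = np.nanmean(2.0 - diff, axis=1)
        shared = (called[i] & called[i + 1:]).sum(axis=1)
        dist = 1.0 - mean_ibs / 2.0
        dist[shared == 0] = np.nan
        D[i, i + 1:] = D[i + 1:, i] = dist
    if np.isnan(D).any():
        warnings.warn("some sample pairs share no non-missing SNPs", stacklevel=2)
    return pd.DataFrame(D, index=gm.samples, columns=gm.samples)


def _ibs_state_expectations(p: np.ndarray) -> np.ndarray:
    """Per-SNP P(IBS=s | IBD=z) for s, z in 0..2; returns sums over SNPs.

    Standard two-allele results with allele frequencies p (A1) and q = 1-p:
    e[s, z] = sum over SNPs of P(IBS=s | IBD=z).
    """
    q = 1.0 - p
    e = np.zeros((3, 3))
    e[0, 0] = np.sum(2 * p**2 * q**2)
    e[1, 0] = np.sum(4 * p**3 * q + 4 * p * q**3)
    e[2, 0] = np.sum(p**4 + q**4 + 4 * p**2 * q**2)
    e[1, 1] = np.sum(2 * p**2 * q + 2 * p * q**2)
    e[2, 1] = np.sum(p**3 + q**3 + p**2 * q + p * q**2)
    e[2, 2] = float(len(p))
    return e


def pihat(gm: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments IBD estimates for all sample pairs.

    Returns columns ID1, ID2, Z0, Z1, Z2, PI_HAT. Allele frequencies for the
    expectations are computed on the full cohort. Raises if every variant is
    monomorphic (expectations undefined).
    """
    p = allele_frequency(gm).to_numpy()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all variants monomorphic; IBD expectations undefined")
    X = gm.dosage[:, poly]
    p = p[poly]
    n, m = X.shape
    called = ~np.isnan(X)

    if called.all():
        return _pihat_complete(gm.samples, X, p)

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                rows.append({"ID1": gm.samples[i], "ID2": gm.samples[j],
                             "Z0": np.nan, "Z1": np.nan, "Z2": np.nan, "PI_HAT": np.nan})
                continue
            diff = np.abs(X[i, both] - X[j, both])
            n2 = int(np.sum(diff == 0))
            n1 = int(np.sum(diff == 1))
            n0 = int(np.sum(diff == 2))
            e = _ibs_state_expectations(p[both])
            m_eff = both.sum()
            # Scale per-SNP expectations to counts.
            z0 = n0 / e[0, 0] if e[0, 0] > 0 else 0.0
            z1 = (n1 - z0 * e[1, 0]) / e[1, 1] if e[1, 1] > 0 else 0.0
            z2 = (n2 - z0 * e[2, 0] - z1 * e[2, 1]) / m_eff
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            s = z.sum()
            z = z / s if s > 0 else np.array([1.0, 0.0, 0.0])
            rows.append(
                {"ID1": gm.samples[i], "ID2": gm.samples[j],
                 "Z0": z[0], "Z1": z[1], "Z2": z[2], "PI_HAT": z[2] + z[1] / 2}
            )
    return pd.DataFrame(rows)


def _pihat_complete(samples: list[str], X: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    """Vectorised moment estimator for the no-missing-data case.

    Pairwise IBS-state counts come from indicator matrix products; the
    expectation terms are shared by every pair.
    """
    n, m = X.shape
    A0 = (X == 0).astype(float)
    A1 = (X == 1).astype(float)
    A2 = (X == 2).astype(float)
    N0 = A0 @ A2.T + A2 @ A0.T                      # opposite homozygotes
    N1 = A1 @ (A0 + A2).T + (A0 + A2) @ A1.T        # het vs hom
    N2 = m - N0 - N1
    e = _ibs_state_expectations(p)
    Z0 = N0 / e[0, 0] if e[0, 0] > 0 else np.zeros_like(N0)
    Z1 = (N1 - Z0 * e[1, 0]) / e[1, 1] if e[1, 1] > 0 else np.zeros_like(N1)
    Z2 = (N2 - Z0 * e[2, 0] - Z1 * e[2, 1]) / m
    Z = np.stack([Z0, Z1, Z2])
    Z = np.clip(Z, 0.0, 1.0)
    tot = Z.sum(axis=0)
    bad = tot <= 0
    Z = np.divide(Z, np.where(bad, 1.0, tot))
    Z[0][bad] = 1.0
    Z[1][bad] = Z[2][bad] = 0.0
    iu = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "ID1": [samples[i] for i in iu[0]],
            "ID2": [samples[j] for j in iu[1]],
            "Z0": Z[0][iu],
            "Z1": Z[1][iu],
            "Z2": Z[2][iu],
            "PI_HAT": (Z[2] + Z[1] / 2)[iu],
        }
    )


def mknn_graph(dist: pd.DataFrame, k: int = 10) -> nx.Graph:
    """Mutual k-nearest-neighbour graph from a symmetric distance matrix.

    Edge (i, j) exists iff j is among i's k nearest neighbours AND i is among
    j's. Distance ties are broken by sample-id order. Isolated nodes are
    retained. ``k >= n`` yields the complete mutual graph with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(dist.index)
    n = len(ids)
    if k >= n:
        warnings.warn(f"k={k} >= n={n}: mutual kNN graph is complete", stacklevel=2)
    D = dist.to_numpy()
    neighbours: list[set[int]] = []
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i and not np.isnan(D[i, j])),
            key=lambda j: (D[i, j], ids[j]),
        )
        neighbours.append(set(order[:k]))
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(n):
        for j in neighbours[i]:
            if j > i and i in neighbours[j]:
                g.add_edge(ids[i], ids[j], distance=float(D[i, j]))
    return g
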