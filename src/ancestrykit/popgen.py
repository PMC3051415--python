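"""Genotype-distance statistics: identity-by-state (IBS) distance matrices,
Kruskal non-metric multidimensional scaling, and one-level AMOVA with a
permutation test.

The IBS distance between two diploid genotypes at one locus is
``|d1 - d2| / 2`` (0, 0.5 or 1), averaged over loci typed in both
individuals; exact-zero off-diagonal distances are replaced by a small
constant so downstream ordination never sees coincident points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

def ibs_distance_matrix(
    g: GenotypeMatrix, zero_fill: float = 0.001
) -> np.ndarray:
    """Pairwise 1 - mean IBS sharing over loci typed in both individuals.

    Raises when a pair shares no typed locus; exact-zero off-diagonal
    distances are replaced by ``zero_fill``.
    """
    n = g.n_individuals
    if n < 2:
        raise ValueError("at least 2 individuals are required")
    d = g.dosages.astype(float)
    obs = d != MISSING
    dz = np.where(obs, d, 0.0)
    obs_f = obs.astype(float)
    # sum over co-typed loci of |d_i - d_j| / 2, computed blockwise
    dist = np.zeros((n, n))
    co = obs_f @ obs_f.T
    if (co[~np.eye(n, dtype=bool)] == 0).any():
        i, j = np.argwhere((co == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"individuals {g.individual_ids[i]} and {g.individual_ids[j]} "
            "share no typed locus"
        )
    block = 256
    for s in range(0, n, block):
        e = min(s + block, n)
        diff = np.abs(dz[s:e, None, :] - dz[None, :, :])  # (b, n, L)
        both = obs[s:e, None, :] & obs[None, :, :]
        dist[s:e] = (diff * both).sum(axis=2) / (2.0 * co[s:e])
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    off = ~np.eye(n, dtype=bool)
    dist[off & (dist == 0.0)] = zero_fill
    np.fill_diagonal(dist, 0.0)
    return dist


# ---------------------------------------------------------------------------
# non-metric MDS (Kruskal / SMACOF with isotonic disparities)
# ---------------------------------------------------------------------------

@dataclass
class MdsResult:
    coordinates: np.ndarray  # n x dims (defined up to rotation/reflection)
    stress: float            # Kruskal stress-1
    converged: bool
    n_iter: int
    stress_trace: np.ndarray


def nmds(
    dist: np.ndarray,
    dims: int = 3,
    n_starts: int = 8,
    max_iter: int = 500,
    tol: float = 1e-6,
    random_state: int | None = 0,
) -> MdsResult:
    """Kruskal non-metric MDS.

    Each SMACOF iteration fits disparities by monotone (pool-adjacent-
    violators) regression of configuration distances on dissimilarity
    ranks, rescales them to the current distance norm, and applies the
    Guttman transform. Stress-1 = sqrt(sum (d̂ - d)² / sum d²). The best of
    ``n_starts`` random initializations is returned; a start terminates
    when the stress change drops below ``tol`` (and is cut short if stress
    ever increases, keeping the trace non-increasing). Random
    initialization depends only on the seed and the matrix size, so the
    embedding is invariant under any monotone transform of the input
    distances.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(random_state)

    best: MdsResult | None = None
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    xs = np.arange(len(delta), dtype=float)
    for _ in range(max(1, n_starts)):
        X = rng.standard_normal((n, dims))
        trace = []
        prev = np.inf
        converged = False
        for it in range(max_iter):
            d = _pdist(X)[iu]
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(xs, d[order])
            denom = (d ** 2).sum()
            if denom <= 0:
                break
            # scale disparities to the configuration's distance norm
            scale = np.sqrt(denom / max((dhat ** 2).sum(), 1e-300))
            dhat *= scale
            stress = float(np.sqrt(((dhat - d) ** 2).sum() / denom))
            if stress > prev:  # keep the monotone trace; stop this start
                break
            trace.append(stress)
            if prev - stress < tol:
                converged = True
                prev = stress
                break
            prev = stress
            X = _guttman(X, dhat, d, iu, n)
        res = MdsResult(
            coordinates=X,
            stress=prev if np.isfinite(prev) else np.inf,
            converged=converged,
            n_iter=len(trace),
            stress_trace=np.asarray(trace),
        )
        if best is None or res.stress < best.stress:
            best = res
    return best


def _pdist(X: np.ndarray) -> np.ndarray:
    sq = (X ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    return np.sqrt(d2)


def _guttman(X, dhat, d, iu, n):
    w = np.zeros((n, n))
    ratio = np.where(d > 1e-12, dhat / np.maximum(d, 1e-12), 0.0)
    w[iu] = ratio
    w += w.T
    B = -w
    np.fill_diagonal(B, w.sum(axis=1))
    return B @ X / n


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi_st: float
    pct_among: float
    perm_p: float
    n_permutations: int
    ss_among: float
    ss_within: float


def genotype_squared_distances(g: GenotypeMatrix) -> np.ndarray:
    """Squared molecular distance between individuals: the number of allele
    differences summed over loci typed in both (|d_i - d_j| per locus)."""
    d = g.dosages.astype(float)
    obs = d != MISSING
    dz = np.where(obs, d, 0.0)
    n = g.n_individuals
    out = np.zeros((n, n))
    block = 256
    for s in range(0, n, block):
        e = min(s + block, n)
        diff = np.abs(dz[s:e, None, :] - dz[None, :, :])
        both = obs[s:e, None, :] & obs[None, :, :]
        out[s:e] = (diff * both).sum(axis=2)
    return (out + out.T) / 2.0


def haplogroup_squared_distances(labels) -> np.ndarray:
    """0/1 identity distance between haplogroup labels."""
    arr = np.asarray(labels)
    return (arr[:, None] != arr[None, :]).astype(float)


def amova_from_distances(
    d2: np.ndarray,
    groups,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """One-level AMOVA on a matrix of squared inter-individual distances.

    Sums of squares follow the standard decomposition
    SS_total = (1/N) Σ_{i<j} d²_ij and SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²;
    variance components come from the mean squares with the unequal-size
    coefficient n' = (N - Σ n_g²/N)/(G-1), Φ_ST = σ²_a/(σ²_a+σ²_w), and the
    permutation p-value is (1 + #{permuted Φ ≥ observed})/(n_perm + 1) with
    individuals permuted among groups.
    """
    d2 = np.asarray(d2, dtype=float)
    groups = np.asarray(groups)
    N = d2.shape[0]
    if len(groups) != N:
        raise ValueError("one group label per individual")
    names, counts = np.unique(groups, return_counts=True)
    if len(names) < 2:
        raise ValueError("at least 2 groups are required")
    if (counts < 2).any():
        small = names[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 individuals")
    rng = np.random.default_rng() if rng is None else rng

    iu = np.triu_indices(N, 1)
    ss_total = d2[iu].sum() / N

    def ss_within(lbl: np.ndarray) -> float:
        tot = 0.0
        for g in names:
            idx = np.flatnonzero(lbl == g)
            sub = d2[np.ix_(idx, idx)]
            tot += sub.sum() / (2.0 * len(idx))
        return tot

    def phi(lbl: np.ndarray) -> float:
        ssw = ss_within(lbl)
        ssa = ss_total - ssw
        G = len(names)
        df_a, df_w = G - 1, N - G
        ms_a, ms_w = ssa / df_a, ssw / df_w
        nprime = (N - (np.square(counts).sum() / N)) / df_a
        sig_w = ms_w
        sig_a = (ms_a - ms_w) / nprime
        tot = sig_a + sig_w
        return sig_a / tot if tot > 0 else 0.0, sig_a, sig_w, ssa, ssw

    obs_phi, sig_a, sig_w, ssa, ssw = phi(groups)
    hits = 0
    lbl = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(lbl)
        if phi(lbl)[0] >= obs_phi:
            hits += 1
    perm_p = (1 + hits) / (n_perm + 1)
    total = sig_a + sig_w
    return AmovaResult(
        sigma_among=sig_a,
        sigma_within=sig_w,
        phi_st=obs_phi,
        pct_among=100.0 * sig_a / total if total > 0 else 0.0,
        perm_p=perm_p,
        n_permutations=n_perm,
        ss_among=ssa,
        ss_within=ssw,
    )


def amova(
    g: GenotypeMatrix,
    groups=None,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """AMOVA on genotype data with allele-difference squared distances."""
    if groups is None:
        groups = g.labels
    if groups is None:
        raise ValueError("group labels are required")
    return amova_from_distances(
        genotype_squared_distances(g), groups, n_perm=n_perm, rng=rng
    )
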