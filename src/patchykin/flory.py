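"""Flory--Stockmayer statistics for the bicomponent A_fA + B_fB mixture.

Step-growth aggregation with random, independent bond formation maps onto a
bipartite random-graph / branching-process ensemble: an A site is reacted
with probability ``p_A``, a B site with ``p_B = r p_A`` where
``r = f_A N_A / (f_B N_B)`` is the stoichiometric imbalance.  The gel point
follows from criticality of the branching process,
``p_A p_B (f_A - 1)(f_B - 1) = 1``, giving ``p_gel = 1/2`` for the
stoichiometric A_2 + B_5 mixture.  The sol cluster-size distribution is
computed from the bipartite tree generating functions by truncated series
convolution (stable up to s ~ 10^3, where closed-form factorial expressions
overflow), and cross-checked by an explicit random-bond Monte-Carlo oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.signal import convolve2d
from scipy.sparse.csgraph import connected_components

from .observables import ClusterDistribution

__all__ = [
    "FloryMixtureSpec",
    "gel_point",
    "flory_cluster_distribution",
    "random_graph_oracle",
    "gel_point_scan",
]


@dataclass(frozen=True)
class FloryMixtureSpec:
    f_A: int = 2
    f_B: int = 5
    N_A: int = 1200
    N_B: int = 480

    def __post_init__(self) -> None:
        if self.f_A < 1 or self.f_B < 1:
            raise ValueError("functionalities must be >= 1")
        if self.N_A < 1 or self.N_B < 1:
            raise ValueError("counts must be >= 1")

    @property
    def r(self) -> float:
        """Stoichiometric ratio f_A N_A / (f_B N_B)."""
        return self.f_A * self.N_A / (self.f_B * self.N_B)


def gel_point(spec: FloryMixtureSpec) -> float:
    """Critical A-site conversion for gelation; ``inf`` if no gel forms.

    Solves ``p_A p_B (f_A - 1)(f_B - 1) = 1`` with ``p_B = r p_A``.
    """
    branch = (spec.f_A - 1) * (spec.f_B - 1)
    if branch < 1:
        return float("inf")
    p = 1.0 / np.sqrt(spec.r * branch)
    if p > 1.0:
        return float("inf")
    return float(p)


def _trunc_mul(a: np.ndarray, b: np.ndarray, s_max: int) -> np.ndarray:
    out = convolve2d(a, b)[: s_max + 1, : s_max + 1]
    return out


def _trunc_pow(a: np.ndarray, k: int, s_max: int) -> np.ndarray:
    out = np.zeros((s_max + 1, s_max + 1))
    out[0, 0] = 1.0
    for _ in range(k):
        out = _trunc_mul(out, a, s_max)
    return out


def flory_cluster_distribution(p: float, spec: FloryMixtureSpec,
                               s_max: int) -> ClusterDistribution:
    """Expected number n(s) of s-particle tree clusters, s = 1..s_max.

    Valid on both sides of the gel point: the coefficient formulas count
    finite trees, which post-gel is the sol branch (the smallest-root
    extinction-probability convention).
    """
    if s_max < 1:
        raise ValueError("s_max must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    pA = p
    pB = spec.r * p
    if pB > 1.0 + 1e-12:
        raise ValueError("B-site conversion r*p exceeds 1")
    qA, qB = 1.0 - pA, 1.0 - pB

    # bivariate series in (a, b) = (# A particles, # B particles)
    shape = (s_max + 1, s_max + 1)
    x = np.zeros(shape)
    x[1, 0] = 1.0
    y = np.zeros(shape)
    y[0, 1] = 1.0
    tA = np.zeros(shape)
    tB = np.zeros(shape)
    one = np.zeros(shape)
    one[0, 0] = 1.0
    for _ in range(s_max + 1):
        tA = _trunc_mul(x, _trunc_pow(qA * one + pA * tB, spec.f_A - 1, s_max),
                        s_max)
        tB = _trunc_mul(y, _trunc_pow(qB * one + pB * tA, spec.f_B - 1, s_max),
                        s_max)
    cA = _trunc_mul(x, _trunc_pow(qA * one + pA * tB, spec.f_A, s_max), s_max)
    cB = _trunc_mul(y, _trunc_pow(qB * one + pB * tA, spec.f_B, s_max), s_max)

    n_s = np.zeros(s_max + 1)
    for a in range(s_max + 1):
        for b in range(s_max + 1 - a):
            s = a + b
            if s < 1 or s > s_max:
                continue
            if a > 0:
                n_ab = spec.N_A * cA[a, b] / a
            else:
                n_ab = spec.N_B * cB[a, b] / b
            n_s[s] += n_ab
    sizes = np.arange(1, s_max + 1)
    return ClusterDistribution(sizes=sizes, counts=n_s[1:],
                               n_particles=0,  # truncated: skip conservation
                               p=p)


def random_graph_oracle(p: float, spec: FloryMixtureSpec, rng,
                        n_scale: int = 1):
    """Empirical n(s) from uniformly random A-B site pairing (no geometry).

    Scales the mixture by *n_scale*, bonds ``round(p f_A N_A)`` uniformly
    random free-site pairs and returns ``(ClusterDistribution,
    giant_fraction)`` where the giant fraction is the largest component's
    share of all particles.
    """
    nA, nB = spec.N_A * n_scale, spec.N_B * n_scale
    sitesA = np.repeat(np.arange(nA), spec.f_A)
    sitesB = np.repeat(np.arange(nB), spec.f_B) + nA
    n_bonds = int(round(p * spec.f_A * nA))
    if n_bonds > min(len(sitesA), len(sitesB)):
        raise ValueError("requested more bonds than available site pairs")
    a = rng.permutation(sitesA)[:n_bonds]
    b = rng.permutation(sitesB)[:n_bonds]
    n = nA + nB
    adj = sparse.coo_matrix((np.ones(n_bonds), (a, b)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    _, csizes = np.unique(labels, return_counts=True)
    sizes, counts = np.unique(csizes, return_counts=True)
    dist = ClusterDistribution(sizes=sizes, counts=counts, n_particles=n, p=p)
    return dist, float(csizes.max()) / n


def gel_point_scan(spec: FloryMixtureSpec, rng, n_scale: int = 100,
                   p_grid=None, n_reps: int = 1) -> float:
    """Locate the gel point from the susceptibility peak of the oracle.

    The mean cluster size excluding the largest component,
    ``chi = sum' s^2 n(s) / sum' s n(s)``, peaks at the finite-size
    percolation threshold; *n_reps* independent draws per grid point damp
    the finite-size jitter of the peak position.
    """
    if p_grid is None:
        p_grid = np.linspace(0.30, 0.70, 41)
    chi = np.zeros(len(p_grid))
    for k, p in enumerate(p_grid):
        for _ in range(n_reps):
            dist, _ = random_graph_oracle(float(p), spec, rng,
                                          n_scale=n_scale)
            s, c = dist.sizes.astype(float), dist.counts.astype(float)
            imax = np.argmax(s)
            c = c.copy()
            c[imax] -= 1  # drop one largest cluster
            denom = np.sum(s * c)
            chi[k] += np.sum(s * s * c) / denom if denom > 0 else 0.0
    return float(p_grid[np.argmax(chi)])
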