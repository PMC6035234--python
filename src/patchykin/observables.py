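"""Bond fraction, cluster statistics, diffusion and structure observables.

Clusters are groups of particles connected by bonds; the extent of reaction
``p`` is the number of bonds over the maximum possible, ``f_A N_A``.
Diffusion at fixed p uses the frozen-bond protocol: the bonding pattern is
frozen (infinite wall replaces the finite entry barrier for all unbonded
site pairs) so clusters diffuse without reacting, and D is read from the
asymptotic slope of the mean-squared displacement, ``D = <dr^2>/6t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .state import F_A, F_B, InteractionParams, SystemState

__all__ = [
    "KineticCurve",
    "ClusterDistribution",
    "DiffusionEstimate",
    "StructureFactor",
    "bond_fraction",
    "find_clusters",
    "cluster_size_distribution",
    "percolating_clusters",
    "frozen_bond_diffusion",
    "structure_factor",
]


@dataclass
class KineticCurve:
    """Extent of reaction versus reduced time, with run-to-run dispersion."""

    times: np.ndarray
    p: np.ndarray
    sem: np.ndarray | None = None
    n_replicas: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if np.any(self.sem < 0):
                raise ValueError("SEM must be non-negative")
        if len(self.times) != len(self.p):
            raise ValueError("times and p must have equal length")

    def dpdt(self, window: int = 5, order: int = 2):
        """Smoothed local-polynomial derivative estimate; see meanfield."""
        from .meanfield import smoothed_derivative

        return smoothed_derivative(self.times, self.p, window=window,
                                   order=order)


@dataclass
class ClusterDistribution:
    """Histogram n(s) of cluster sizes s (in particles)."""

    sizes: np.ndarray      # distinct s values
    counts: np.ndarray     # n(s), same length
    n_particles: int
    p: float

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        self.counts = np.asarray(self.counts, dtype=float)
        total = float(np.sum(self.sizes * self.counts))
        if self.n_particles and abs(total - self.n_particles) > 1e-6:
            raise ValueError(
                f"particle conservation violated: sum s*n(s) = {total}, "
                f"expected {self.n_particles}")

    def as_array(self, s_max: int | None = None) -> np.ndarray:
        smax = int(s_max or self.sizes.max())
        out = np.zeros(smax + 1)
        for s, c in zip(self.sizes, self.counts):
            if s <= smax:
                out[int(s)] += c
        return out


@dataclass
class DiffusionEstimate:
    p: float
    D: float                 # sigma^2 per reduced time
    fit_window: tuple        # (t_lo, t_hi), reduced time
    msd_times: np.ndarray
    msd: np.ndarray


@dataclass
class StructureFactor:
    q: np.ndarray            # shell-averaged wave-vector moduli, sigma^-1
    S: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.S < 0):
            raise ValueError("S(q) must be non-negative")


def bond_fraction(registry, n_A: int, n_B: int = 0) -> float:
    """p = bonds / (f_A N_A); equals bonds/(f_B N_B) at stoichiometry."""
    if n_A <= 0 and n_B <= 0:
        raise ValueError("empty system has no bond fraction")
    if n_A == 0:
        return len(registry) / (F_B * n_B)
    return len(registry) / (F_A * n_A)


def find_clusters(bond_pairs, site_owner, n_particles: int) -> np.ndarray:
    """Connected-component labels of the particle-bond graph.

    *bond_pairs* is an iterable of (site_a, site_b) global site indices;
    *site_owner* maps sites to particles.  Labels are contiguous integers,
    stable under permutation of the bond list.
    """
    rows, cols = [], []
    for sa, sb in bond_pairs:
        ia, ib = int(site_owner[sa]), int(site_owner[sb])
        if ia >= n_particles or ib >= n_particles:
            raise ValueError(f"bond references unknown particle ({ia}, {ib})")
        rows.append(ia)
        cols.append(ib)
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_particles, n_particles))
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_size_distribution(labels: np.ndarray,
                              p: float) -> ClusterDistribution:
    """Histogram of component sizes from :func:`find_clusters` labels."""
    _, csizes = np.unique(labels, return_counts=True)
    sizes, counts = np.unique(csizes, return_counts=True)
    return ClusterDistribution(sizes=sizes, counts=counts,
                               n_particles=len(labels), p=p)


def state_clusters(state: SystemState) -> np.ndarray:
    return find_clusters(state.registry.pairs, state.site_owner,
                         state.n_particles)


def percolating_clusters(state: SystemState) -> list[int]:
    """Labels of clusters whose unwrapped extent exceeds a box edge.

    Standard span criterion for a percolating (gel) network: with unwrapped
    coordinates, a cluster wider than the periodic box in any dimension
    connects to its own image.
    """
    labels = state_clusters(state)
    out = []
    for lab in np.unique(labels):
        pts = state.pos[labels == lab]
        if len(pts) < 2:
            continue
        extent = pts.max(axis=0) - pts.min(axis=0)
        if np.any(extent > state.box.edges):
            out.append(int(lab))
    return out


def frozen_bond_diffusion(state: SystemState, horizon: float, rng=None,
                          *, n_samples: int = 60, hardcore: bool = True,
                          params: InteractionParams | None = None,
                          linear_fraction: float = 0.5,
                          slope_tol: float = 0.25) -> DiffusionEstimate:
    """Diffusion coefficient at the state's current p (frozen-bond protocol).

    The state is cloned, bonding is disabled (infinite entry wall), and the
    clone is evolved for *horizon* reduced time units while the
    mean-squared displacement ``<sum_i |r_i(t) - r_i(0)|^2 / N>`` is
    accumulated from unwrapped coordinates.  D is the least-squares slope/6
    over the trailing *linear_fraction* of the horizon, where the local
    log-log slope must be within *slope_tol* of 1 (sub-diffusive transient
    over); otherwise a window error is raised.

    ``hardcore=False`` removes excluded volume (free-flight test mode).
    """
    from .simulate import advance

    if params is None:
        params = InteractionParams()
    clone = state.copy()
    clone.time = 0.0
    times = np.linspace(0.0, horizon, n_samples + 1)
    r0 = clone.pos.copy()
    msd = np.zeros(n_samples + 1)
    n_bonds0 = len(clone.registry)
    for k in range(1, n_samples + 1):
        advance(clone, params, times[k], frozen=True, hardcore=hardcore,
                rng=rng)
        msd[k] = float(np.mean(np.sum((clone.pos - r0) ** 2, axis=1)))
    assert len(clone.registry) == n_bonds0, "frozen run formed a bond"

    k_lo = int(np.searchsorted(times, horizon * (1.0 - linear_fraction)))
    k_lo = max(1, k_lo)
    tw, mw = times[k_lo:], msd[k_lo:]
    # local log-log slope over the fit window
    logslope = np.polyfit(np.log(tw), np.log(np.maximum(mw, 1e-300)), 1)[0]
    if abs(logslope - 1.0) > slope_tol:
        raise ValueError(
            f"no linear MSD regime in window (log-log slope {logslope:.3f}); "
            "increase the horizon")
    slope = np.polyfit(tw, mw, 1)[0]
    return DiffusionEstimate(p=state.p, D=max(0.0, slope / 6.0),
                             fit_window=(float(tw[0]), float(tw[-1])),
                             msd_times=times, msd=msd)


def structure_factor(positions: np.ndarray, box_edges, q_max: float,
                     n_shells: int = 30) -> StructureFactor:
    """Static structure factor on the box-commensurate wave-vector grid.

    ``S(q) = <|sum_j exp(i q . r_j)|^2> / N`` with ``q = 2 pi n / L``,
    averaged over shells of equal |q|.
    """
    positions = np.asarray(positions, dtype=float)
    box_edges = np.asarray(box_edges, dtype=float)
    n = len(positions)
    if n == 0:
        raise ValueError("need at least one particle")
    qcell = 2.0 * np.pi / box_edges
    nmax = np.floor(q_max / qcell).astype(int)
    if np.any(nmax < 1):
        raise ValueError("q_max below the smallest commensurate wave vector")
    grids = [np.arange(-m, m + 1) for m in nmax]
    nx, ny, nz = np.meshgrid(*grids, indexing="ij")
    qvecs = np.stack([nx * qcell[0], ny * qcell[1], nz * qcell[2]], axis=-1)
    qvecs = qvecs.reshape(-1, 3)
    qmod = np.linalg.norm(qvecs, axis=1)
    keep = (qmod > 1e-12) & (qmod <= q_max)
    qvecs, qmod = qvecs[keep], qmod[keep]
    rho = np.exp(1j * positions @ qvecs.T).sum(axis=0)
    sq = np.abs(rho) ** 2 / n
    edges = np.linspace(0, q_max, n_shells + 1)
    idx = np.digitize(qmod, edges) - 1
    qs, ss = [], []
    for sh in range(n_shells):
        m = idx == sh
        if np.any(m):
            qs.append(qmod[m].mean())
            ss.append(sq[m].mean())
    return StructureFactor(q=np.array(qs), S=np.array(ss))
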