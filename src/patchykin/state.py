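"""System state, bond registry and run parameters.

Internally everything is stored in natural units (sigma = m = k_B T = 1);
the public time axis is the reduced unit ``sqrt(10 m sigma^2 / k_B T)`` of
the source model, i.e. ``t_reduced = t_natural / sqrt(10)``.  Positions are
kept unwrapped (minimum-image convention is applied when distances are
computed), which makes mean-squared displacements trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BoxSpec, build_species

#: natural time units per reduced time unit
TIME_UNIT = float(np.sqrt(10.0))

F_A = 2  #: valence of species A
F_B = 5  #: valence of species B


@dataclass
class InteractionParams:
    """Site-site interaction: square well behind an autocatalytic barrier.

    Parameters
    ----------
    u0 : float
        Well depth in k_BT (the net kinetic-energy gain on bond formation).
    delta : float
        Site interaction range in sigma.
    dU0 : float
        Entry barrier at p = 0, in k_BT.
    xi : float
        Autocatalytic strength; the barrier decreases as
        ``dU = dU0 - ln(1 + xi p) / beta`` (floored at zero).
    beta : float
        Inverse temperature, 1/k_BT.
    crossing_mode : {"energetic", "stochastic"}
        Energetic: a site pair crosses the barrier iff the radial relative
        kinetic energy along the inter-site line exceeds dU.  Stochastic:
        crossing with probability exp(-beta dU), velocities untouched.
    """

    u0: float = 0.1
    delta: float = 0.2
    dU0: float = 0.0
    xi: float = 0.0
    beta: float = 1.0
    crossing_mode: str = "energetic"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.xi < 0:
            raise ValueError("autocatalytic strength xi must be >= 0")
        if self.u0 < 0:
            raise ValueError("well depth u0 must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.crossing_mode not in ("energetic", "stochastic"):
            raise ValueError("crossing_mode must be 'energetic' or 'stochastic'")


class BondRegistry:
    """Irreversible A-B site bonds; each site engages in at most one bond."""

    def __init__(self, n_sites: int):
        self.partner = np.full(n_sites, -1, dtype=np.int64)
        self._pairs: list[tuple[int, int]] = []

    def __len__(self) -> int:
        return len(self._pairs)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(self._pairs)

    def is_bonded(self, site: int) -> bool:
        return self.partner[site] >= 0

    def add(self, site_a: int, site_b: int) -> None:
        if self.partner[site_a] >= 0 or self.partner[site_b] >= 0:
            raise ValueError("site already engaged in a bond")
        self.partner[site_a] = site_b
        self.partner[site_b] = site_a
        self._pairs.append((site_a, site_b))

    def copy(self) -> "BondRegistry":
        new = BondRegistry(len(self.partner))
        new.partner = self.partner.copy()
        new._pairs = list(self._pairs)
        return new


def site_tables(species_id: np.ndarray):
    """Global site bookkeeping for a particle array.

    Returns ``(site_owner, site_local, site_is_A, site_start)`` where sites of
    particle i occupy the contiguous global range
    ``site_start[i] : site_start[i + 1]``.
    """
    spA, spB = build_species("A"), build_species("B")
    counts = np.where(species_id == 0, F_A, F_B)
    site_start = np.concatenate([[0], np.cumsum(counts)])
    n_sites = int(site_start[-1])
    site_owner = np.empty(n_sites, dtype=np.int64)
    site_local = np.empty((n_sites, 3))
    site_is_A = np.empty(n_sites, dtype=np.bool_)
    for i, sid in enumerate(species_id):
        lo, hi = site_start[i], site_start[i + 1]
        site_owner[lo:hi] = i
        sp = spA if sid == 0 else spB
        site_local[lo:hi] = sp.site_local_positions
        site_is_A[lo:hi] = sid == 0
    return site_owner, site_local, site_is_A, site_start


@dataclass
class SystemState:
    """Poses, velocities and bond registry of the particle mixture."""

    pos: np.ndarray          # (N, 3) unwrapped centers, sigma
    quat: np.ndarray         # (N, 4) scalar-first unit quaternions
    vel: np.ndarray          # (N, 3) natural units
    angmom: np.ndarray       # (N, 3) space-frame angular momenta, natural
    species_id: np.ndarray   # (N,) 0 = A, 1 = B
    box: BoxSpec
    time: float = 0.0        # reduced units
    registry: BondRegistry = None  # type: ignore[assignment]
    dU: float = 0.0          # current entry barrier, k_BT

    def __post_init__(self) -> None:
        (self.site_owner, self.site_local,
         self.site_is_A, self.site_start) = site_tables(self.species_id)
        if self.registry is None:
            self.registry = BondRegistry(len(self.site_owner))

    @property
    def n_particles(self) -> int:
        return len(self.pos)

    @property
    def n_A(self) -> int:
        return int(np.sum(self.species_id == 0))

    @property
    def n_B(self) -> int:
        return int(np.sum(self.species_id == 1))

    @property
    def p(self) -> float:
        """Extent of reaction: bonds / (f_A N_A)."""
        if self.n_A == 0:
            return 0.0
        return len(self.registry) / (F_A * self.n_A)

    @property
    def masses(self) -> np.ndarray:
        return np.where(self.species_id == 0, 3.4, 1.0)

    @property
    def moments(self) -> np.ndarray:
        spA, spB = build_species("A"), build_species("B")
        return np.where((self.species_id == 0)[:, None],
                        spA.principal_moments, spB.principal_moments)

    def kinetic_energy(self) -> tuple[float, float]:
        """(translational, rotational) kinetic energy in k_BT."""
        from scipy.spatial.transform import Rotation

        trans = 0.5 * float(np.sum(self.masses * np.sum(self.vel**2, axis=1)))
        rots = Rotation.from_quat(self.quat[:, [1, 2, 3, 0]])
        L_body = rots.apply(self.angmom, inverse=True)
        rot = 0.5 * float(np.sum(L_body**2 / self.moments))
        return trans, rot

    def wrapped_positions(self) -> np.ndarray:
        return self.pos - np.floor(self.pos / self.box.edges) * self.box.edges

    def copy(self) -> "SystemState":
        return SystemState(
            pos=self.pos.copy(), quat=self.quat.copy(), vel=self.vel.copy(),
            angmom=self.angmom.copy(), species_id=self.species_id.copy(),
            box=BoxSpec(self.box.edges.copy(), self.box.periodic.copy()),
            time=self.time, registry=self.registry.copy(), dU=self.dU,
        )


@dataclass
class SimulationConfig:
    """Run-level settings for :func:`patchykin.simulate.run_reaction`.

    ``dt`` is the barrier-refresh / event-scan step and ``thermostat_interval``
    the velocity-rescale cadence, both in reduced time units (defaults 0.05
    and 0.1 as in the source model).
    """

    n_A: int = 1200
    n_B: int = 480
    phi: float = 0.30
    dt: float = 0.05
    thermostat_interval: float = 0.1
    t_max: float = 100.0
    seed: int = 0
    n_replicas: int = 1
    snapshot_every: float = 1.0   # p-recording cadence, reduced time
    t_equil: float = 1.0          # bond-free equilibration, reduced time
    thermostat_rotational: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_A < 0 or self.n_B < 0:
            raise ValueError("particle counts must be non-negative")

    @property
    def stoichiometric(self) -> bool:
        return F_A * self.n_A == F_B * self.n_B
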