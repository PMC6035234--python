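"""Thermostatted dynamics of the bonding hard-ellipsoid mixture.

The engine is a hybrid event scheme: exact torque-free rigid-body flight on a
fine sub-step grid, with hard-core collisions and site-shell crossings
bracketed at sub-step boundaries and refined by bisection (see
``patchykin._kernels``).  Bonds form when a free A site and a free B site
approach within the interaction range ``delta`` and the entry barrier is
crossed; bonds are irreversible (an infinite wall confines bonded sites to
``r <= delta``).  The barrier decreases autocatalytically with the extent of
reaction p and is refreshed every ``dt`` (0.05 reduced time units by
default); a velocity-rescale thermostat acts every ``thermostat_interval``
(0.1 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .geometry import build_species, random_packing
from .state import (F_A, F_B, TIME_UNIT, InteractionParams, SimulationConfig,
                    SystemState)

__all__ = [
    "IntegratorError",
    "EventStats",
    "advance",
    "site_barrier_event",
    "autocatalytic_barrier_update",
    "thermostat_rescale",
    "run_reaction",
    "crossing_statistics",
    "ReactionResult",
]

#: default event-scan sub-step, natural time units (0.05 sigma sqrt(m/kT))
DEFAULT_SUBSTEP = 0.05


class IntegratorError(RuntimeError):
    pass


@dataclass
class EventStats:
    """Event counts accumulated during :func:`advance`."""

    attempts: int = 0          # barrier collisions of free A-B site pairs
    crossings: int = 0         # successful barrier crossings (bonds formed)
    core_collisions: int = 0
    wall_reflections: int = 0  # bonded-pair confinement reflections
    substeps: int = 0

    def accumulate(self, counters: np.ndarray) -> None:
        self.attempts += int(counters[0])
        self.crossings += int(counters[1])
        self.core_collisions += int(counters[2])
        self.wall_reflections += int(counters[3])
        self.substeps += int(counters[4])


def _species_arrays():
    spA, spB = build_species("A"), build_species("B")
    masses = np.array([spA.mass, spB.mass])
    moments = np.stack([spA.principal_moments, spB.principal_moments])
    semiaxes = np.stack([spA.semiaxes, spB.semiaxes])
    brad = np.array([spA.bounding_radius, spB.bounding_radius])
    return masses, moments, semiaxes, brad


def autocatalytic_barrier_update(state: SystemState,
                                 params: InteractionParams) -> float:
    """Refresh the entry barrier from the current extent of reaction.

    ``dU = dU0 - ln(1 + xi p) / beta``, floored at zero (a negative entry
    barrier is not defined by the model).  The value is stored on the state
    and governs all subsequent barrier events until the next refresh.
    """
    if params.xi < 0:
        raise ValueError("xi must be >= 0")
    p = state.p
    dU = params.dU0 - np.log1p(params.xi * p) / params.beta
    state.dU = max(0.0, float(dU))
    return state.dU


def thermostat_rescale(state: SystemState, T_target: float = 1.0,
                       rotational: bool = True) -> SystemState:
    """Rescale velocities by one common factor to the equipartition energy.

    Targets ``(3/2) N kT`` translational plus, if *rotational*, the same
    rotational share; directions are unchanged.
    """
    trans, rot = state.kinetic_energy()
    n = state.n_particles
    if rotational:
        ke, target = trans + rot, 3.0 * n * T_target
    else:
        ke, target = trans, 1.5 * n * T_target
    if ke <= 0.0:
        raise ValueError("cannot thermostat a state with zero kinetic energy")
    factor = np.sqrt(target / ke)
    state.vel *= factor
    if rotational:
        state.angmom *= factor
    return state


def advance(state: SystemState, params: InteractionParams, until_time: float,
            *, dt: float = 0.05, thermostat_interval: float | None = 0.1,
            T_target: float = 1.0, thermostat_rotational: bool = True,
            frozen: bool = False, hardcore: bool = True,
            substep: float = DEFAULT_SUBSTEP, rng=None,
            stats: EventStats | None = None,
            on_block=None) -> SystemState:
    """Evolve *state* in place to reduced time *until_time*.

    ``frozen=True`` switches the finite entry barrier to an infinite wall for
    all unbonded site pairs (no new bonds; existing clusters move freely) --
    the frozen-bond protocol used for diffusion measurements.
    ``hardcore=False`` disables excluded volume (ideal-gas test mode).
    ``thermostat_interval=None`` turns the thermostat off (NVE segments).
    *on_block* is called as ``on_block(state)`` after every barrier-refresh
    block.
    """
    if until_time < state.time:
        raise ValueError("until_time precedes the state's current time")
    masses, moments, semiaxes, brad = _species_arrays()
    mode = 0 if params.crossing_mode == "energetic" else 1
    if mode == 1:
        seed = 0 if rng is None else int(rng.integers(2**31 - 1))
        K._seed(seed)

    max_new = len(state.site_owner) // 2 + 1
    new_bonds = np.empty((max_new, 2), dtype=np.int64)
    counters = np.zeros(13, dtype=np.int64)
    if stats is None:
        stats = EventStats()

    t_nat = state.time * TIME_UNIT
    t_end = until_time * TIME_UNIT
    dt_nat = dt * TIME_UNIT
    thermo_nat = None if thermostat_interval is None \
        else thermostat_interval * TIME_UNIT
    since_thermo = 0.0

    autocatalytic_barrier_update(state, params)
    while t_nat < t_end - 1e-12:
        block = min(dt_nat, t_end - t_nat)
        counters[:] = 0
        n_new, err = K.advance_block(
            state.pos, state.quat, state.vel, state.angmom,
            state.species_id, masses, moments, semiaxes, brad,
            state.site_owner, state.site_local, state.site_is_A,
            state.site_start, state.registry.partner,
            state.box.edges, block, substep,
            params.delta, params.u0, state.dU, params.beta, mode,
            frozen, hardcore, new_bonds, counters)
        if err == K.ERR_OVERLAP_START:
            raise IntegratorError(
                "missed-event watchdog: hard-core overlap at a sub-step "
                "boundary; reduce the sub-step")
        if err == K.ERR_EVENT_LOOP:
            raise IntegratorError("event cascade did not terminate in block")
        if err == K.ERR_BOND_ESCAPE:
            raise IntegratorError(
                "bonded site pair escaped its confinement well; reduce the "
                "sub-step")
        for b in range(n_new):
            sa, sb = int(new_bonds[b, 0]), int(new_bonds[b, 1])
            state.registry._pairs.append((sa, sb))  # partner[] set in kernel
        stats.accumulate(counters)
        t_nat += block
        state.time = t_nat / TIME_UNIT
        autocatalytic_barrier_update(state, params)
        if thermo_nat is not None:
            since_thermo += block
            if since_thermo >= thermo_nat - 1e-12:
                thermostat_rescale(state, T_target,
                                   rotational=thermostat_rotational)
                since_thermo = 0.0
        if on_block is not None:
            on_block(state)
    return state


def site_barrier_event(state: SystemState, site_pair, params: InteractionParams,
                       rng=None) -> str:
    """Resolve one entry-barrier event for an unbonded A-B site pair.

    The pair is assumed to be at the interaction range and approaching.
    Energetic mode: the pair crosses iff the radial relative kinetic energy
    along the inter-site line exceeds the current barrier; on crossing the
    radial velocity is remapped for a net potential change ``-u0`` and the
    bond registered.  Stochastic mode: crossing with probability
    ``exp(-beta dU)``, velocities untouched.  Returns ``"crossed"`` or
    ``"reflected"``.
    """
    sa, sb = site_pair
    if state.registry.is_bonded(sa) or state.registry.is_bonded(sb):
        raise ValueError("site already bonded")
    if state.site_is_A[sa] == state.site_is_A[sb]:
        raise ValueError("barrier events require an A-B site pair")
    if not state.site_is_A[sa]:
        sa, sb = sb, sa
    i, j = int(state.site_owner[sa]), int(state.site_owner[sb])
    masses, moments, semiaxes, _ = _species_arrays()
    si, sj = state.species_id[i], state.species_id[j]

    Ra = K.q_to_mat(state.quat[i])
    Rb = K.q_to_mat(state.quat[j])
    xa = state.pos[i] + Ra @ state.site_local[sa]
    d_cent = state.box.minimum_image(state.pos[j] - state.pos[i])
    shift = d_cent - (state.pos[j] - state.pos[i])
    xb = state.pos[j] + shift + Rb @ state.site_local[sb]
    e = xb - xa
    e = e / np.linalg.norm(e)
    xb_real = xb - shift
    u = K._point_rel_velocity(i, j, xa, xb_real, state.pos, state.vel,
                              state.quat, state.angmom, state.species_id,
                              moments)
    ue = float(u @ e)
    ra, rb = xa - state.pos[i], xb - (state.pos[j] + shift)
    Keff = K._effective_inv_mass(e, ra, rb, masses[si], masses[sj],
                                 state.quat[i], state.quat[j],
                                 moments[si], moments[sj])
    if params.crossing_mode == "energetic":
        crossed = 0.5 * ue * ue / Keff > state.dU
    else:
        if rng is None:
            raise ValueError("stochastic mode needs an rng")
        crossed = rng.random() < np.exp(-params.beta * state.dU)
    if crossed:
        state.registry.add(sa, sb)
        if params.crossing_mode == "energetic" and params.u0 > 0:
            ue_new = np.sign(ue) * np.sqrt(ue * ue + 2.0 * Keff * params.u0)
            K._apply_impulse(i, j, e, (ue_new - ue) / Keff, xa, xb_real,
                             state.pos, state.vel, state.angmom,
                             masses, state.species_id)
        return "crossed"
    K._apply_impulse(i, j, e, -2.0 * ue / Keff, xa, xb_real,
                     state.pos, state.vel, state.angmom,
                     masses, state.species_id)
    return "reflected"


@dataclass
class ReactionResult:
    """Output of :func:`run_reaction`."""

    curve: "KineticCurve"                      # mean +- SEM over replicas
    replicas: list                             # per-replica KineticCurve
    states_at_p: list = field(default_factory=list)  # per replica: {p: state}
    stats: list = field(default_factory=list)  # per-replica EventStats


def run_reaction(config: SimulationConfig, params: InteractionParams,
                 *, keep_states_at=(), substep: float = DEFAULT_SUBSTEP,
                 progress: bool = False) -> ReactionResult:
    """Run ``config.n_replicas`` independent reaction simulations.

    Each replica starts from an independently packed, bond-free configuration
    equilibrated at ``k_BT = 1``, then reacts until ``t_max`` with the
    barrier refreshed every ``dt`` and the thermostat applied every
    ``thermostat_interval``.  The extent of reaction is recorded every
    ``snapshot_every`` reduced time units; *keep_states_at* lists p values at
    which a deep copy of the state is retained (first crossing).
    """
    from .observables import KineticCurve

    if config.n_A > 0 and not config.stoichiometric:
        warnings.warn("non-stoichiometric mixture: p is normalized by f_A N_A",
                      stacklevel=2)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_replicas)
    t_grid = np.arange(0.0, config.t_max + 1e-9, config.snapshot_every)

    curves, all_states, all_stats = [], [], []
    for rep in range(config.n_replicas):
        rng = np.random.default_rng(children[rep])
        state = random_packing((config.n_A, config.n_B), config.phi, rng)
        if config.t_equil > 0:
            advance(state, params, config.t_equil, dt=config.dt,
                    thermostat_interval=config.thermostat_interval,
                    frozen=True, substep=substep, rng=rng,
                    thermostat_rotational=config.thermostat_rotational)
            state.time = 0.0
        stats = EventStats()
        p_vals = np.empty_like(t_grid)
        p_vals[0] = state.p
        kept: dict[float, SystemState] = {}
        targets = sorted(keep_states_at)

        def keeper(s):
            while targets and s.p >= targets[0]:
                kept[targets.pop(0)] = s.copy()

        for k in range(1, len(t_grid)):
            advance(state, params, t_grid[k], dt=config.dt,
                    thermostat_interval=config.thermostat_interval,
                    frozen=False, substep=substep, rng=rng, stats=stats,
                    thermostat_rotational=config.thermostat_rotational,
                    on_block=keeper if targets else None)
            p_vals[k] = state.p
            if progress:
                print(f"replica {rep} t={t_grid[k]:.1f} p={state.p:.4f}",
                      flush=True)
        curves.append(KineticCurve(times=t_grid.copy(), p=p_vals,
                                   n_replicas=1))
        all_states.append(kept)
        all_stats.append(stats)

    pmat = np.stack([c.p for c in curves])
    mean = pmat.mean(axis=0)
    sem = (pmat.std(axis=0, ddof=1) / np.sqrt(len(curves))
           if len(curves) > 1 else np.zeros_like(mean))
    mean_curve = KineticCurve(times=t_grid, p=mean, sem=sem,
                              n_replicas=len(curves))
    return ReactionResult(curve=mean_curve, replicas=curves,
                          states_at_p=all_states, stats=all_stats)


def crossing_statistics(params: InteractionParams, n_events: int, rng,
                        dU: float | None = None) -> np.ndarray:
    """Unsuccessful-attempt counts before a barrier crossing.

    Simulates a thermalized collision ensemble at fixed barrier *dU*
    (defaults to ``params.dU0``).  In energetic mode each collision carries a
    radial kinetic energy drawn from the flux-weighted 1D Maxwell
    distribution (exponential with mean ``1/beta``) and crosses iff it
    exceeds the barrier; in stochastic mode each collision crosses with
    probability ``exp(-beta dU)``.  Either way the attempt count is
    geometric with success probability ``exp(-beta dU)``.

    Returns the number of *unsuccessful* attempts for each of *n_events*
    bonding events.
    """
    if dU is None:
        dU = params.dU0
    if dU < 0:
        raise ValueError("barrier must be non-negative")
    fails = np.zeros(n_events, dtype=np.int64)
    if dU == 0.0:
        return fails
    pending = np.arange(n_events)
    if params.crossing_mode == "energetic":
        while pending.size:
            e_rad = rng.exponential(1.0 / params.beta, size=pending.size)
            failed = e_rad <= dU
            fails[pending[failed]] += 1
            pending = pending[failed]
    else:
        p_cross = np.exp(-params.beta * dU)
        while pending.size:
            failed = rng.random(pending.size) >= p_cross
            fails[pending[failed]] += 1
            pending = pending[failed]
    return fails
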