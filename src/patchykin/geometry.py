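"""Shapes, orientations, overlap tests and bonding-site placement.

The model mixture contains two species of uniaxial hard ellipsoids decorated
with short-range bonding sites on their surface:

* species ``A`` — semiaxes ``(2, 2, 10)`` sigma, mass ``3.4 m``, two sites at
  the tips of the major axis (valence 2);
* species ``B`` — semiaxes ``(1, 1, 5)`` sigma, mass ``m``, five sites: two
  near each tip plus one on the equator (valence 5).

All lengths are in units of sigma, masses in units of m.  Orientations are
unit quaternions (scalar-first ``(w, x, y, z)``) mapping the body frame to the
world frame; the body frame is right-handed with the symmetry (major) axis
along z.  Hard-core overlap is tested with the Perram--Wertheim contact
function: ``F < 1`` means overlap, ``F = 1`` external tangency, ``F > 1``
separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

__all__ = [
    "EllipsoidSpecies",
    "Pose",
    "BoxSpec",
    "build_species",
    "pw_contact",
    "world_sites",
    "random_packing",
]

# Tilt (parametric angle from the major axis, in the x-z body plane) of the
# two sites near each tip of a B particle.  The rendering in the source model
# fixes only "two at each end and one on the equator"; +-30 degrees keeps the
# sites on the surface and mutually farther apart than the bonding range.
B_TIP_SITE_ANGLE = np.deg2rad(30.0)


@dataclass(frozen=True)
class EllipsoidSpecies:
    """Geometry, mass and bonding-site layout of one particle species."""

    label: str
    semiaxes: np.ndarray          # (3,) sigma
    mass: float                   # multiples of m
    principal_moments: np.ndarray  # (3,) m sigma^2, uniform density
    site_local_positions: np.ndarray  # (valence, 3) body frame, sigma

    @property
    def valence(self) -> int:
        return len(self.site_local_positions)

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semiaxes))

    @property
    def bounding_radius(self) -> float:
        return float(np.max(self.semiaxes))


def _uniform_ellipsoid_moments(mass: float, semiaxes: np.ndarray) -> np.ndarray:
    a, b, c = semiaxes
    return mass / 5.0 * np.array([b * b + c * c, a * a + c * c, a * a + b * b])


def build_species(label: str) -> EllipsoidSpecies:
    """Return species ``A`` or ``B`` with the model geometry.

    Raises
    ------
    ValueError
        If *label* is neither ``"A"`` nor ``"B"``.
    """
    if label == "A":
        semiaxes = np.array([2.0, 2.0, 10.0])
        mass = 3.4
        sites = np.array([[0.0, 0.0, 10.0], [0.0, 0.0, -10.0]])
    elif label == "B":
        semiaxes = np.array([1.0, 1.0, 5.0])
        mass = 1.0
        s, c = np.sin(B_TIP_SITE_ANGLE), np.cos(B_TIP_SITE_ANGLE)
        a, cz = semiaxes[0], semiaxes[2]
        sites = np.array(
            [
                [a * s, 0.0, cz * c],
                [-a * s, 0.0, cz * c],
                [a * s, 0.0, -cz * c],
                [-a * s, 0.0, -cz * c],
                [a, 0.0, 0.0],
            ]
        )
    else:
        raise ValueError(f"unknown species label {label!r}; expected 'A' or 'B'")
    return EllipsoidSpecies(
        label=label,
        semiaxes=semiaxes,
        mass=mass,
        principal_moments=_uniform_ellipsoid_moments(mass, semiaxes),
        site_local_positions=sites,
    )


@dataclass
class Pose:
    """Center position plus unit-quaternion orientation (body -> world)."""

    center: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        q = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(q)
        if n == 0.0:
            raise ValueError("orientation quaternion must be nonzero")
        self.orientation = q / n

    def rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self.orientation
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    def compose_rotation(self, other_quat: np.ndarray) -> "Pose":
        """Return a pose rotated by *other_quat* (applied in the world frame)."""
        w1, x1, y1, z1 = other_quat
        w2, x2, y2, z2 = self.orientation
        q = np.array(
            [
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            ]
        )
        return Pose(self.center.copy(), q)


@dataclass
class BoxSpec:
    """Periodic orthorhombic simulation box."""

    edges: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.array([True] * 3))

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if np.any(self.edges <= 0):
            raise ValueError("box edges must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        dr = np.asarray(dr, dtype=float)
        shift = np.where(self.periodic, np.round(dr / self.edges), 0.0)
        return dr - shift * self.edges


def _quadric_matrix(pose: Pose, species: EllipsoidSpecies) -> np.ndarray:
    """World-frame matrix X with (x-r)^T X (x-r) = 1 on the surface."""
    R = pose.rotation_matrix()
    return R @ np.diag(1.0 / species.semiaxes**2) @ R.T


def pw_contact(
    poseA: Pose,
    speciesA: EllipsoidSpecies,
    poseB: Pose,
    speciesB: EllipsoidSpecies,
    box: BoxSpec | None = None,
) -> float:
    """Perram--Wertheim contact function of two hard ellipsoids.

    Maximizes ``G(lam) = lam (1-lam) d^T [(1-lam) XA^-1 + lam XB^-1]^-1 d``
    over ``lam`` in ``[0, 1]``, where ``XA, XB`` are the world-frame quadric
    matrices and ``d`` the (minimum-image) center separation.  ``F < 1`` iff
    the ellipsoids overlap, ``F = 1`` at external tangency.
    """
    if np.any(speciesA.semiaxes <= 0) or np.any(speciesB.semiaxes <= 0):
        raise ValueError("degenerate (non-positive) semiaxis")
    d = poseB.center - poseA.center
    if box is not None:
        d = box.minimum_image(d)
    if np.allclose(d, 0.0):
        return 0.0
    RA, RB = poseA.rotation_matrix(), poseB.rotation_matrix()
    Ainv = RA @ np.diag(speciesA.semiaxes**2) @ RA.T
    Binv = RB @ np.diag(speciesB.semiaxes**2) @ RB.T

    def neg_g(lam: float) -> float:
        M = (1.0 - lam) * Ainv + lam * Binv
        y = np.linalg.solve(M, d)
        return -lam * (1.0 - lam) * float(d @ y)

    res = minimize_scalar(neg_g, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-14})
    return float(-res.fun)


def world_sites(pose: Pose, species: EllipsoidSpecies) -> np.ndarray:
    """Bonding-site positions in the world frame, shape ``(valence, 3)``."""
    R = pose.rotation_matrix()
    return pose.center[None, :] + species.site_local_positions @ R.T


def box_for_packing(counts: tuple[int, int], phi: float) -> BoxSpec:
    """Cubic periodic box realizing packing fraction *phi* exactly."""
    nA, nB = counts
    vol = (build_species("A").volume * nA + build_species("B").volume * nB) / phi
    return BoxSpec(np.full(3, vol ** (1.0 / 3.0)))


def random_packing(counts, box_or_phi, rng):
    """Non-overlapping random configuration with thermal velocities.

    Particles are inserted by random sequential addition (bounding-sphere
    early rejection, then the exact contact function); insertions that keep
    failing are placed anyway and relaxed by a short hard-core-only push-apart
    sweep.  Linear and angular velocities are Maxwell--Boltzmann at
    ``k_B T = 1`` (natural units).  Deterministic given *rng*.

    Parameters
    ----------
    counts : (int, int)
        ``(N_A, N_B)``.
    box_or_phi : BoxSpec or float
        Explicit box, or a target packing fraction (box then cubic).
    rng : numpy.random.Generator

    Returns
    -------
    SystemState with no bonds.
    """
    from .state import SystemState  # deferred: state builds on geometry

    nA, nB = counts
    if nA + nB < 1:
        raise ValueError("need at least one particle")
    if isinstance(box_or_phi, BoxSpec):
        box = box_or_phi
    else:
        phi = float(box_or_phi)
        if not 0 < phi <= 0.35:
            raise ValueError("packing fraction must be in (0, 0.35] for "
                             "rejection insertion; lower phi")
        box = box_for_packing((nA, nB), phi)

    spA, spB = build_species("A"), build_species("B")
    species_id = np.concatenate([np.zeros(nA, np.int8), np.ones(nB, np.int8)])
    n = nA + nB

    # the minimum-image convention requires every pair-contact distance to
    # fit in half the box; A-A tip-tip contacts reach 2 * 10 sigma
    pair_reach = 0.0
    if nA >= 2:
        pair_reach = 4.0 * spA.bounding_radius
    elif nA == 1 and nB >= 1:
        pair_reach = 2.0 * (spA.bounding_radius + spB.bounding_radius)
    elif nB >= 2:
        pair_reach = 4.0 * spB.bounding_radius
    if np.min(box.edges) < pair_reach:
        raise ValueError(
            f"box edge {np.min(box.edges):.1f} sigma is below twice the "
            f"largest pair-contact distance ({pair_reach:.0f} sigma); the "
            "minimum-image convention would break -- use more particles "
            "at this packing fraction")

    from ._kernels import packing_insert, packing_relax

    semi = np.stack([spA.semiaxes, spB.semiaxes])
    brad = np.array([spA.bounding_radius, spB.bounding_radius])
    for attempt in range(4):
        pos, quat, n_bad = packing_insert(
            species_id, semi, brad, box.edges, rng.integers(2**31 - 1))
        if n_bad == 0:
            break
        if packing_relax(pos, quat, species_id, semi, brad, box.edges,
                         rng.integers(2**31 - 1)):
            break
    else:
        raise RuntimeError(
            "packing failed: could not remove residual overlaps; "
            "try a lower packing fraction")

    masses = np.where(species_id == 0, spA.mass, spB.mass)
    vel = rng.normal(size=(n, 3)) / np.sqrt(masses)[:, None]
    if n > 1:  # zero total momentum
        vel -= (masses[:, None] * vel).sum(axis=0) / masses.sum()

    # body-frame angular velocities -> space-frame angular momenta
    moments = np.where(
        (species_id == 0)[:, None], spA.principal_moments, spB.principal_moments
    )
    omega_body = rng.normal(size=(n, 3)) / np.sqrt(moments)
    L_body = moments * omega_body
    rots = Rotation.from_quat(quat[:, [1, 2, 3, 0]])
    L = rots.apply(L_body)

    return SystemState(
        pos=pos, quat=quat, vel=vel, angmom=L,
        species_id=species_id, box=box, time=0.0,
    )
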