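"""Numba kernels for the hard-ellipsoid event engine.

Everything here works in natural units (sigma = m = k_B T = 1).  The
propagation of a uniaxial (symmetric-top) rigid body under no torque is
exact: the space-frame angular momentum L is constant, the body precesses
about L at rate |L|/I1 while spinning about its symmetry axis at rate
L3_body (1/I3 - 1/I1).

Collisions and site events are detected on a fine sub-step grid: the state
is propagated by one sub-step, violations of the hard-core / site-shell
constraints at the endpoint are bisected back in time to the crossing, the
earliest event is resolved by an impulsive velocity update, and the scan
resumes from the event time.  Quaternions are scalar-first (w, x, y, z).
"""

import numpy as np
from numba import njit

# error codes returned by advance_block
ERR_OK = 0
ERR_OVERLAP_START = 1     # invalid state entering a sub-step (missed event)
ERR_EVENT_LOOP = 2        # too many events in one block
ERR_BOND_ESCAPE = 3       # bonded pair far outside its confinement well

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------- quaternions

@njit(cache=True, fastmath=False)
def q_mul(a, b):
    out = np.empty(4)
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]
    return out


@njit(cache=True)
def q_normalize(q):
    n = np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    return q / n


@njit(cache=True)
def q_from_axis_angle(axis, angle):
    out = np.empty(4)
    half = 0.5 * angle
    s = np.sin(half)
    out[0] = np.cos(half)
    out[1] = axis[0] * s
    out[2] = axis[1] * s
    out[3] = axis[2] * s
    return out


@njit(cache=True)
def q_to_mat(q):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R = np.empty((3, 3))
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)
    return R


# -------------------------------------------------------------- rigid flight

@njit(cache=True)
def flight_quat(q, L, I1, I3, dt):
    """Torque-free symmetric-top orientation update (exact)."""
    Lmag = np.sqrt(L[0] * L[0] + L[1] * L[1] + L[2] * L[2])
    if Lmag < 1e-300 or dt == 0.0:
        return q.copy()
    R = q_to_mat(q)
    # body z-component of L
    L3 = R[0, 2] * L[0] + R[1, 2] * L[1] + R[2, 2] * L[2]
    axis = L / Lmag
    q_prec = q_from_axis_angle(axis, (Lmag / I1) * dt)
    zbody = np.empty(3)
    zbody[0] = 0.0
    zbody[1] = 0.0
    zbody[2] = 1.0
    q_spin = q_from_axis_angle(zbody, L3 * (1.0 / I3 - 1.0 / I1) * dt)
    return q_normalize(q_mul(q_prec, q_mul(q, q_spin)))


@njit(cache=True)
def flight_all(pos, quat, vel, L, species, moments, dt):
    n = pos.shape[0]
    for i in range(n):
        s = species[i]
        pos[i, 0] += vel[i, 0] * dt
        pos[i, 1] += vel[i, 1] * dt
        pos[i, 2] += vel[i, 2] * dt
        quat[i] = flight_quat(quat[i], L[i], moments[s, 0], moments[s, 2], dt)


@njit(cache=True)
def omega_world(q, L, I1, I3):
    """Space-frame angular velocity from space-frame angular momentum."""
    R = q_to_mat(q)
    Lb = np.empty(3)
    for k in range(3):
        Lb[k] = R[0, k] * L[0] + R[1, k] * L[1] + R[2, k] * L[2]
    wb = np.empty(3)
    wb[0] = Lb[0] / I1
    wb[1] = Lb[1] / I1
    wb[2] = Lb[2] / I3
    w = np.empty(3)
    for k in range(3):
        w[k] = R[k, 0] * wb[0] + R[k, 1] * wb[1] + R[k, 2] * wb[2]
    return w


# ------------------------------------------------------ contact function (PW)

@njit(cache=True)
def _solve3(M, b):
    """Solve M x = b for symmetric positive-definite 3x3 M (cofactors)."""
    a11, a12, a13 = M[0, 0], M[0, 1], M[0, 2]
    a22, a23 = M[1, 1], M[1, 2]
    a33 = M[2, 2]
    c11 = a22 * a33 - a23 * a23
    c12 = a13 * a23 - a12 * a33
    c13 = a12 * a23 - a13 * a22
    det = a11 * c11 + a12 * c12 + a13 * c13
    c22 = a11 * a33 - a13 * a13
    c23 = a12 * a13 - a11 * a23
    c33 = a11 * a22 - a12 * a12
    x = np.empty(3)
    x[0] = (c11 * b[0] + c12 * b[1] + c13 * b[2]) / det
    x[1] = (c12 * b[0] + c22 * b[1] + c23 * b[2]) / det
    x[2] = (c13 * b[0] + c23 * b[1] + c33 * b[2]) / det
    return x


@njit(cache=True)
def _pw_g(lam, Ainv, Binv, d):
    # allocation-free: blend the inverse quadrics, solve by cofactors
    mu = 1.0 - lam
    a11 = mu * Ainv[0, 0] + lam * Binv[0, 0]
    a12 = mu * Ainv[0, 1] + lam * Binv[0, 1]
    a13 = mu * Ainv[0, 2] + lam * Binv[0, 2]
    a22 = mu * Ainv[1, 1] + lam * Binv[1, 1]
    a23 = mu * Ainv[1, 2] + lam * Binv[1, 2]
    a33 = mu * Ainv[2, 2] + lam * Binv[2, 2]
    c11 = a22 * a33 - a23 * a23
    c12 = a13 * a23 - a12 * a33
    c13 = a12 * a23 - a13 * a22
    det = a11 * c11 + a12 * c12 + a13 * c13
    c22 = a11 * a33 - a13 * a13
    c23 = a12 * a13 - a11 * a23
    c33 = a11 * a22 - a12 * a12
    y0 = (c11 * d[0] + c12 * d[1] + c13 * d[2]) / det
    y1 = (c12 * d[0] + c22 * d[1] + c23 * d[2]) / det
    y2 = (c13 * d[0] + c23 * d[1] + c33 * d[2]) / det
    return lam * mu * (d[0] * y0 + d[1] * y1 + d[2] * y2)


@njit(cache=True)
def pw_value(Ainv, Binv, d):
    """max_lam of the Perram-Wertheim function (golden-section search)."""
    a = 0.0
    b = 1.0
    c = b - _INVPHI * (b - a)
    e = a + _INVPHI * (b - a)
    fc = _pw_g(c, Ainv, Binv, d)
    fe = _pw_g(e, Ainv, Binv, d)
    for _ in range(70):
        if fc > fe:
            b = e
            e = c
            fe = fc
            c = b - _INVPHI * (b - a)
            fc = _pw_g(c, Ainv, Binv, d)
        else:
            a = c
            c = e
            fc = fe
            e = a + _INVPHI * (b - a)
            fe = _pw_g(e, Ainv, Binv, d)
    lam = 0.5 * (a + b)
    return _pw_g(lam, Ainv, Binv, d), lam


@njit(cache=True)
def pw_overlaps(Ainv, Binv, d):
    """True iff the ellipsoids overlap (F < 1), with cheap early exit.

    Any sampled G(lam) is a lower bound on F = max_lam G, so G >= 1 at any
    trial point proves separation without running the full search.
    """
    if _pw_g(0.5, Ainv, Binv, d) >= 1.0:
        return False
    a = 0.0
    b = 1.0
    c = b - _INVPHI * (b - a)
    e = a + _INVPHI * (b - a)
    fc = _pw_g(c, Ainv, Binv, d)
    fe = _pw_g(e, Ainv, Binv, d)
    for _ in range(40):
        if fc >= 1.0 or fe >= 1.0:
            return False
        if fc > fe:
            b = e
            e = c
            fe = fc
            c = b - _INVPHI * (b - a)
            fc = _pw_g(c, Ainv, Binv, d)
        else:
            a = c
            c = e
            fc = fe
            e = a + _INVPHI * (b - a)
            fe = _pw_g(e, Ainv, Binv, d)
    return max(fc, fe) < 1.0


@njit(cache=True)
def pw_contact_geometry(Ainv, Binv, rA, d):
    """Contact point and outward (A -> B) unit normal at near-tangency."""
    F, lam = pw_value(Ainv, Binv, d)
    M = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            M[i, j] = (1.0 - lam) * Ainv[i, j] + lam * Binv[i, j]
    y = _solve3(M, d)
    xc = np.empty(3)
    for k in range(3):
        acc = 0.0
        for m in range(3):
            acc += Ainv[k, m] * y[m]
        xc[k] = rA[k] + (1.0 - lam) * acc
    ny = np.sqrt(y[0] * y[0] + y[1] * y[1] + y[2] * y[2])
    return xc, y / ny


@njit(cache=True)
def world_inv_quadric(q, semiaxes):
    """R diag(semiaxes^2) R^T -- the inverse of the surface quadric."""
    R = q_to_mat(q)
    out = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            acc = 0.0
            for k in range(3):
                acc += R[i, k] * semiaxes[k] * semiaxes[k] * R[j, k]
            out[i, j] = acc
    return out


@njit(cache=True)
def support_separated(Ainv, Binv, d):
    """True if a plane normal to d provably separates the two ellipsoids."""
    dist2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
    if dist2 == 0.0:
        return False
    hA = 0.0
    hB = 0.0
    for i in range(3):
        for j in range(3):
            hA += d[i] * Ainv[i, j] * d[j]
            hB += d[i] * Binv[i, j] * d[j]
    # support widths along unit d are sqrt(h)/|d|; separation iff
    # |d| > sum of widths, i.e. |d|^2 > sqrt(hA) + sqrt(hB)
    return dist2 > np.sqrt(hA) + np.sqrt(hB)


@njit(cache=True)
def min_image(d, edges):
    out = np.empty(3)
    for k in range(3):
        out[k] = d[k] - np.round(d[k] / edges[k]) * edges[k]
    return out


# ------------------------------------------------------- impulse mechanics

@njit(cache=True)
def _rel_point_vel(vi, wi, pi, vj, wj, pj, xa, xb):
    """Velocity of material point xa (body at pi) minus xb (body at pj)."""
    u = np.empty(3)
    ra = np.empty(3)
    rb = np.empty(3)
    for k in range(3):
        ra[k] = xa[k] - pi[k]
        rb[k] = xb[k] - pj[k]
    u[0] = vi[0] + wi[1] * ra[2] - wi[2] * ra[1] - (vj[0] + wj[1] * rb[2] - wj[2] * rb[1])
    u[1] = vi[1] + wi[2] * ra[0] - wi[0] * ra[2] - (vj[1] + wj[2] * rb[0] - wj[0] * rb[2])
    u[2] = vi[2] + wi[0] * ra[1] - wi[1] * ra[0] - (vj[2] + wj[0] * rb[1] - wj[1] * rb[0])
    return u


@njit(cache=True)
def _effective_inv_mass(e, ra, rb, mA, mB, qA, qB, momA, momB):
    """Generalized inverse mass for an impulse along unit e at site points."""
    K = 1.0 / mA + 1.0 / mB
    for body in range(2):
        if body == 0:
            r = ra
            q = qA
            mom = momA
        else:
            r = rb
            q = qB
            mom = momB
        c = np.empty(3)  # r x e
        c[0] = r[1] * e[2] - r[2] * e[1]
        c[1] = r[2] * e[0] - r[0] * e[2]
        c[2] = r[0] * e[1] - r[1] * e[0]
        R = q_to_mat(q)
        cb = np.empty(3)
        for k in range(3):
            cb[k] = R[0, k] * c[0] + R[1, k] * c[1] + R[2, k] * c[2]
        K += cb[0] * cb[0] / mom[0] + cb[1] * cb[1] / mom[1] + cb[2] * cb[2] / mom[2]
    return K


@njit(cache=True)
def _apply_impulse(i, j, e, jmag, xa, xb, pos, vel, L, masses, species):
    """Impulse +jmag*e on body i at xa, -jmag*e on body j at xb."""
    mi = masses[species[i]]
    mj = masses[species[j]]
    for k in range(3):
        vel[i, k] += jmag * e[k] / mi
        vel[j, k] -= jmag * e[k] / mj
    ra = np.empty(3)
    rb = np.empty(3)
    for k in range(3):
        ra[k] = xa[k] - pos[i, k]
        rb[k] = xb[k] - pos[j, k]
    L[i, 0] += ra[1] * jmag * e[2] - ra[2] * jmag * e[1]
    L[i, 1] += ra[2] * jmag * e[0] - ra[0] * jmag * e[2]
    L[i, 2] += ra[0] * jmag * e[1] - ra[1] * jmag * e[0]
    L[j, 0] -= rb[1] * jmag * e[2] - rb[2] * jmag * e[1]
    L[j, 1] -= rb[2] * jmag * e[0] - rb[0] * jmag * e[2]
    L[j, 2] -= rb[0] * jmag * e[1] - rb[1] * jmag * e[0]


@njit(cache=True)
def _point_rel_velocity(i, j, xa, xb, pos, vel, quat, L, species, moments):
    """Relative velocity of material point xa on i w.r.t. xb on j."""
    si, sj = species[i], species[j]
    wi = omega_world(quat[i], L[i], moments[si, 0], moments[si, 2])
    wj = omega_world(quat[j], L[j], moments[sj, 0], moments[sj, 2])
    return _rel_point_vel(vel[i], wi, pos[i], vel[j], wj, pos[j], xa, xb)


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


# --------------------------------------------------------------- event engine
#
# Asynchronous sub-step scheme.  Within one sub-step [0, h] every body flies
# freely and independently, so the engine keeps per-body states (pos0, quat0,
# vel0, L0) valid at per-body local times tau[i], plus cached end-of-substep
# states (position, orientation, quadric, site positions at t = h).  A
# detection pass walks the neighbor lists using the cached endpoint data;
# each constraint crossing (hard-core contact, free A-B site-shell entry,
# bonded-pair shell exit) is bisected to its time and queued.  Events are
# processed in time order; resolving one patches only the two bodies
# involved, refreshes their cached endpoint data and re-scans just their
# neighbor pairs, so the cost is O(detection + events) regardless of how
# often bonded pairs rattle against their confinement wall.

EV_CORE = 0
EV_SITE_IN = 1
EV_WALL_OUT = 2

EV_CAP = 16384


@njit(cache=True)
def _body_pos_at(idx, t, pos0, vel0, tau):
    dt = t - tau[idx]
    out = np.empty(3)
    for k in range(3):
        out[k] = pos0[idx, k] + vel0[idx, k] * dt
    return out


@njit(cache=True)
def _body_quat_at(idx, t, quat0, L0, tau, species, moments):
    s = species[idx]
    return flight_quat(quat0[idx], L0[idx], moments[s, 0], moments[s, 2],
                       t - tau[idx])


@njit(cache=True)
def _flight_q(qw, qx, qy, qz, Lx, Ly, Lz, I1, I3, dt):
    """Scalar torque-free symmetric-top quaternion update (no allocation)."""
    Lmag = np.sqrt(Lx * Lx + Ly * Ly + Lz * Lz)
    if Lmag < 1e-300 or dt == 0.0:
        return qw, qx, qy, qz
    # body z-axis in world frame (third column of R(q))
    zx = 2.0 * (qx * qz + qw * qy)
    zy = 2.0 * (qy * qz - qw * qx)
    zz = 1.0 - 2.0 * (qx * qx + qy * qy)
    L3 = zx * Lx + zy * Ly + zz * Lz
    # precession about L
    half = 0.5 * (Lmag / I1) * dt
    s = np.sin(half) / Lmag
    pw = np.cos(half)
    px = Lx * s
    py = Ly * s
    pz = Lz * s
    # spin about the body axis
    half2 = 0.5 * L3 * (1.0 / I3 - 1.0 / I1) * dt
    sw = np.cos(half2)
    sz = np.sin(half2)
    # q' = p * q * s  (s has only w and z components)
    aw = qw * sw - qz * sz
    ax = qx * sw + qy * sz
    ay = qy * sw - qx * sz
    az = qz * sw + qw * sz
    rw = pw * aw - px * ax - py * ay - pz * az
    rx = pw * ax + px * aw + py * az - pz * ay
    ry = pw * ay - px * az + py * aw + pz * ax
    rz = pw * az + px * ay - py * ax + pz * aw
    norm = np.sqrt(rw * rw + rx * rx + ry * ry + rz * rz)
    return rw / norm, rx / norm, ry / norm, rz / norm


@njit(cache=True)
def _pw_g_s(lam, a11, a12, a13, a22, a23, a33,
            b11, b12, b13, b22, b23, b33, dx, dy, dz):
    mu = 1.0 - lam
    m11 = mu * a11 + lam * b11
    m12 = mu * a12 + lam * b12
    m13 = mu * a13 + lam * b13
    m22 = mu * a22 + lam * b22
    m23 = mu * a23 + lam * b23
    m33 = mu * a33 + lam * b33
    c11 = m22 * m33 - m23 * m23
    c12 = m13 * m23 - m12 * m33
    c13 = m12 * m23 - m13 * m22
    det = m11 * c11 + m12 * c12 + m13 * c13
    c22 = m11 * m33 - m13 * m13
    c23 = m12 * m13 - m11 * m23
    c33 = m11 * m22 - m12 * m12
    y0 = (c11 * dx + c12 * dy + c13 * dz) / det
    y1 = (c12 * dx + c22 * dy + c23 * dz) / det
    y2 = (c13 * dx + c23 * dy + c33 * dz) / det
    return lam * mu * (dx * y0 + dy * y1 + dz * y2)


@njit(cache=True)
def _quadric_elems(qw, qx, qy, qz, s1, s2, s3):
    """Upper triangle of R diag(s^2) R^T from a unit quaternion (scalars)."""
    r11 = 1.0 - 2.0 * (qy * qy + qz * qz)
    r12 = 2.0 * (qx * qy - qw * qz)
    r13 = 2.0 * (qx * qz + qw * qy)
    r21 = 2.0 * (qx * qy + qw * qz)
    r22 = 1.0 - 2.0 * (qx * qx + qz * qz)
    r23 = 2.0 * (qy * qz - qw * qx)
    r31 = 2.0 * (qx * qz - qw * qy)
    r32 = 2.0 * (qy * qz + qw * qx)
    r33 = 1.0 - 2.0 * (qx * qx + qy * qy)
    w1 = s1 * s1
    w2 = s2 * s2
    w3 = s3 * s3
    a11 = r11 * r11 * w1 + r12 * r12 * w2 + r13 * r13 * w3
    a12 = r11 * r21 * w1 + r12 * r22 * w2 + r13 * r23 * w3
    a13 = r11 * r31 * w1 + r12 * r32 * w2 + r13 * r33 * w3
    a22 = r21 * r21 * w1 + r22 * r22 * w2 + r23 * r23 * w3
    a23 = r21 * r31 * w1 + r22 * r32 * w2 + r23 * r33 * w3
    a33 = r31 * r31 * w1 + r32 * r32 * w2 + r33 * r33 * w3
    return a11, a12, a13, a22, a23, a33


@njit(cache=True)
def _pair_overlap_fast(t, i, j, pos0, quat0, vel0, L0, tau, species,
                       moments, semiaxes, edges):
    """Allocation-free overlap predicate for the bisection inner loop."""
    dti = t - tau[i]
    dtj = t - tau[j]
    si = species[i]
    sj = species[j]
    qiw, qix, qiy, qiz = _flight_q(
        quat0[i, 0], quat0[i, 1], quat0[i, 2], quat0[i, 3],
        L0[i, 0], L0[i, 1], L0[i, 2], moments[si, 0], moments[si, 2], dti)
    qjw, qjx, qjy, qjz = _flight_q(
        quat0[j, 0], quat0[j, 1], quat0[j, 2], quat0[j, 3],
        L0[j, 0], L0[j, 1], L0[j, 2], moments[sj, 0], moments[sj, 2], dtj)
    a11, a12, a13, a22, a23, a33 = _quadric_elems(
        qiw, qix, qiy, qiz, semiaxes[si, 0], semiaxes[si, 1], semiaxes[si, 2])
    b11, b12, b13, b22, b23, b33 = _quadric_elems(
        qjw, qjx, qjy, qjz, semiaxes[sj, 0], semiaxes[sj, 1], semiaxes[sj, 2])
    dx = (pos0[j, 0] + vel0[j, 0] * dtj) - (pos0[i, 0] + vel0[i, 0] * dti)
    dy = (pos0[j, 1] + vel0[j, 1] * dtj) - (pos0[i, 1] + vel0[i, 1] * dti)
    dz = (pos0[j, 2] + vel0[j, 2] * dtj) - (pos0[i, 2] + vel0[i, 2] * dti)
    dx -= np.round(dx / edges[0]) * edges[0]
    dy -= np.round(dy / edges[1]) * edges[1]
    dz -= np.round(dz / edges[2]) * edges[2]
    if _pw_g_s(0.5, a11, a12, a13, a22, a23, a33,
               b11, b12, b13, b22, b23, b33, dx, dy, dz) >= 1.0:
        return False
    a = 0.0
    b = 1.0
    c = b - _INVPHI * (b - a)
    e = a + _INVPHI * (b - a)
    fc = _pw_g_s(c, a11, a12, a13, a22, a23, a33,
                 b11, b12, b13, b22, b23, b33, dx, dy, dz)
    fe = _pw_g_s(e, a11, a12, a13, a22, a23, a33,
                 b11, b12, b13, b22, b23, b33, dx, dy, dz)
    for _ in range(40):
        if fc >= 1.0 or fe >= 1.0:
            return False
        if fc > fe:
            b = e
            e = c
            fe = fc
            c = b - _INVPHI * (b - a)
            fc = _pw_g_s(c, a11, a12, a13, a22, a23, a33,
                         b11, b12, b13, b22, b23, b33, dx, dy, dz)
        else:
            a = c
            c = e
            fc = fe
            e = a + _INVPHI * (b - a)
            fe = _pw_g_s(e, a11, a12, a13, a22, a23, a33,
                         b11, b12, b13, b22, b23, b33, dx, dy, dz)
    return max(fc, fe) < 1.0


@njit(cache=True)
def _site_dist_fast(t, i, j, sax, say, saz, sbx, sby, sbz,
                    pos0, quat0, vel0, L0, tau, species, moments, edges):
    """Allocation-free site-site distance for the bisection inner loop."""
    dti = t - tau[i]
    dtj = t - tau[j]
    si = species[i]
    sj = species[j]
    qiw, qix, qiy, qiz = _flight_q(
        quat0[i, 0], quat0[i, 1], quat0[i, 2], quat0[i, 3],
        L0[i, 0], L0[i, 1], L0[i, 2], moments[si, 0], moments[si, 2], dti)
    qjw, qjx, qjy, qjz = _flight_q(
        quat0[j, 0], quat0[j, 1], quat0[j, 2], quat0[j, 3],
        L0[j, 0], L0[j, 1], L0[j, 2], moments[sj, 0], moments[sj, 2], dtj)
    dx = (pos0[j, 0] + vel0[j, 0] * dtj) - (pos0[i, 0] + vel0[i, 0] * dti)
    dy = (pos0[j, 1] + vel0[j, 1] * dtj) - (pos0[i, 1] + vel0[i, 1] * dti)
    dz = (pos0[j, 2] + vel0[j, 2] * dtj) - (pos0[i, 2] + vel0[i, 2] * dti)
    dx -= np.round(dx / edges[0]) * edges[0]
    dy -= np.round(dy / edges[1]) * edges[1]
    dz -= np.round(dz / edges[2]) * edges[2]
    # rotate the local site vectors (rows of R times local)
    r11 = 1.0 - 2.0 * (qiy * qiy + qiz * qiz)
    r12 = 2.0 * (qix * qiy - qiw * qiz)
    r13 = 2.0 * (qix * qiz + qiw * qiy)
    r21 = 2.0 * (qix * qiy + qiw * qiz)
    r22 = 1.0 - 2.0 * (qix * qix + qiz * qiz)
    r23 = 2.0 * (qiy * qiz - qiw * qix)
    r31 = 2.0 * (qix * qiz - qiw * qiy)
    r32 = 2.0 * (qiy * qiz + qiw * qix)
    r33 = 1.0 - 2.0 * (qix * qix + qiy * qiy)
    aix = r11 * sax + r12 * say + r13 * saz
    aiy = r21 * sax + r22 * say + r23 * saz
    aiz = r31 * sax + r32 * say + r33 * saz
    r11 = 1.0 - 2.0 * (qjy * qjy + qjz * qjz)
    r12 = 2.0 * (qjx * qjy - qjw * qjz)
    r13 = 2.0 * (qjx * qjz + qjw * qjy)
    r21 = 2.0 * (qjx * qjy + qjw * qjz)
    r22 = 1.0 - 2.0 * (qjx * qjx + qjz * qjz)
    r23 = 2.0 * (qjy * qjz - qjw * qjx)
    r31 = 2.0 * (qjx * qjz - qjw * qjy)
    r32 = 2.0 * (qjy * qjz + qjw * qjx)
    r33 = 1.0 - 2.0 * (qjx * qjx + qjy * qjy)
    ajx = r11 * sbx + r12 * sby + r13 * sbz
    ajy = r21 * sbx + r22 * sby + r23 * sbz
    ajz = r31 * sbx + r32 * sby + r33 * sbz
    cx = dx + ajx - aix
    cy = dy + ajy - aiy
    cz = dz + ajz - aiz
    return np.sqrt(cx * cx + cy * cy + cz * cz)


@njit(cache=True)
def _segseg_dist2(p1x, p1y, p1z, d1x, d1y, d1z, e1,
                  p2x, p2y, p2z, d2x, d2y, d2z, e2):
    """Squared distance between segments p1 +- e1*d1 and p2 +- e2*d2."""
    # shift to segment-start parametrization s, t in [0, L]
    sx = p1x - e1 * d1x
    sy = p1y - e1 * d1y
    sz = p1z - e1 * d1z
    tx = p2x - e2 * d2x
    ty = p2y - e2 * d2y
    tz = p2z - e2 * d2z
    L1 = 2.0 * e1
    L2 = 2.0 * e2
    rx = sx - tx
    ry = sy - ty
    rz = sz - tz
    a = L1 * L1
    e = L2 * L2
    b = L1 * L2 * (d1x * d2x + d1y * d2y + d1z * d2z)
    c = L1 * (d1x * rx + d1y * ry + d1z * rz)
    f = L2 * (d2x * rx + d2y * ry + d2z * rz)
    if a <= 1e-12 and e <= 1e-12:
        return rx * rx + ry * ry + rz * rz
    if a <= 1e-12:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    elif e <= 1e-12:
        t = 0.0
        s = min(1.0, max(0.0, -c / a))
    else:
        denom = a * e - b * b
        if denom > 1e-12:
            s = min(1.0, max(0.0, (b * f - c * e) / denom))
        else:
            s = 0.0
        t = (b * s + f) / e
        if t < 0.0:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        elif t > 1.0:
            t = 1.0
            s = min(1.0, max(0.0, (b - c) / a))
    cx = rx + s * L1 * d1x - t * L2 * d2x
    cy = ry + s * L1 * d1y - t * L2 * d2y
    cz = rz + s * L1 * d1z - t * L2 * d2z
    return cx * cx + cy * cy + cz * cz


@njit(cache=True)
def _refresh_endpoint(b, h, pos0, quat0, vel0, L0, tau, species, moments,
                      semiaxes, site_local, site_start,
                      pos_h, quat_h, quad_h, site_h, axis_h):
    """Recompute body b's cached state at the sub-step end t = h."""
    pos_h[b] = _body_pos_at(b, h, pos0, vel0, tau)
    quat_h[b] = _body_quat_at(b, h, quat0, L0, tau, species, moments)
    quad_h[b] = world_inv_quadric(quat_h[b], semiaxes[species[b]])
    R = q_to_mat(quat_h[b])
    axis_h[b, 0] = R[0, 2]
    axis_h[b, 1] = R[1, 2]
    axis_h[b, 2] = R[2, 2]
    for s in range(site_start[b], site_start[b + 1]):
        for k in range(3):
            site_h[s, k] = (pos_h[b, k]
                            + R[k, 0] * site_local[s, 0]
                            + R[k, 1] * site_local[s, 1]
                            + R[k, 2] * site_local[s, 2])


@njit(cache=True)
def _pair_overlap_t(t, i, j, pos0, quat0, vel0, L0, tau, species, moments,
                    semiaxes, edges):
    pi = _body_pos_at(i, t, pos0, vel0, tau)
    pj = _body_pos_at(j, t, pos0, vel0, tau)
    qi = _body_quat_at(i, t, quat0, L0, tau, species, moments)
    qj = _body_quat_at(j, t, quat0, L0, tau, species, moments)
    Ainv = world_inv_quadric(qi, semiaxes[species[i]])
    Binv = world_inv_quadric(qj, semiaxes[species[j]])
    d = np.empty(3)
    for k in range(3):
        d[k] = pj[k] - pi[k]
    d = min_image(d, edges)
    return pw_overlaps(Ainv, Binv, d)


@njit(cache=True)
def _pair_F_t(t, i, j, pos0, quat0, vel0, L0, tau, species, moments,
              semiaxes, edges):
    pi = _body_pos_at(i, t, pos0, vel0, tau)
    pj = _body_pos_at(j, t, pos0, vel0, tau)
    qi = _body_quat_at(i, t, quat0, L0, tau, species, moments)
    qj = _body_quat_at(j, t, quat0, L0, tau, species, moments)
    Ainv = world_inv_quadric(qi, semiaxes[species[i]])
    Binv = world_inv_quadric(qj, semiaxes[species[j]])
    d = np.empty(3)
    for k in range(3):
        d[k] = pj[k] - pi[k]
    d = min_image(d, edges)
    F, _ = pw_value(Ainv, Binv, d)
    return F


@njit(cache=True)
def _core_un_t(t, i, j, pos0, quat0, vel0, L0, tau, species, moments,
               semiaxes, edges):
    """Normal approach speed (positive = closing) at time t."""
    pi = _body_pos_at(i, t, pos0, vel0, tau)
    pj = _body_pos_at(j, t, pos0, vel0, tau)
    qi = _body_quat_at(i, t, quat0, L0, tau, species, moments)
    qj = _body_quat_at(j, t, quat0, L0, tau, species, moments)
    si, sj = species[i], species[j]
    Ainv = world_inv_quadric(qi, semiaxes[si])
    Binv = world_inv_quadric(qj, semiaxes[sj])
    d = np.empty(3)
    for k in range(3):
        d[k] = pj[k] - pi[k]
    dmi = min_image(d, edges)
    pj_sh = np.empty(3)
    for k in range(3):
        pj_sh[k] = pi[k] + dmi[k]
    xc, nvec = pw_contact_geometry(Ainv, Binv, pi, dmi)
    wi = omega_world(qi, L0[i], moments[si, 0], moments[si, 2])
    wj = omega_world(qj, L0[j], moments[sj, 0], moments[sj, 2])
    u = _rel_point_vel(vel0[i], wi, pi, vel0[j], wj, pj_sh, xc, xc)
    return u[0] * nvec[0] + u[1] * nvec[1] + u[2] * nvec[2]


@njit(cache=True)
def _site_dist_t(t, i, j, sa_local, sb_local, pos0, quat0, vel0, L0, tau,
                 species, moments, edges):
    pi = _body_pos_at(i, t, pos0, vel0, tau)
    pj = _body_pos_at(j, t, pos0, vel0, tau)
    qi = _body_quat_at(i, t, quat0, L0, tau, species, moments)
    qj = _body_quat_at(j, t, quat0, L0, tau, species, moments)
    Ri = q_to_mat(qi)
    Rj = q_to_mat(qj)
    dc = np.empty(3)
    for k in range(3):
        dc[k] = pj[k] - pi[k]
    dmi = min_image(dc, edges)
    dd = 0.0
    for k in range(3):
        ai = Ri[k, 0] * sa_local[0] + Ri[k, 1] * sa_local[1] + Ri[k, 2] * sa_local[2]
        aj = Rj[k, 0] * sb_local[0] + Rj[k, 1] * sb_local[1] + Rj[k, 2] * sb_local[2]
        c = dmi[k] + aj - ai
        dd += c * c
    return np.sqrt(dd)


@njit(cache=True)
def _site_ue_t(t, i, j, sa_local, sb_local, pos0, quat0, vel0, L0, tau,
               species, moments, edges):
    """Radial speed u.e at time t; closing (distance shrinking) <=> ue > 0."""
    pi = _body_pos_at(i, t, pos0, vel0, tau)
    pj = _body_pos_at(j, t, pos0, vel0, tau)
    qi = _body_quat_at(i, t, quat0, L0, tau, species, moments)
    qj = _body_quat_at(j, t, quat0, L0, tau, species, moments)
    si, sj = species[i], species[j]
    Ri = q_to_mat(qi)
    Rj = q_to_mat(qj)
    dc = np.empty(3)
    for k in range(3):
        dc[k] = pj[k] - pi[k]
    dmi = min_image(dc, edges)
    pj_sh = np.empty(3)
    for k in range(3):
        pj_sh[k] = pi[k] + dmi[k]
    xa = np.empty(3)
    xb = np.empty(3)
    for k in range(3):
        xa[k] = pi[k] + Ri[k, 0] * sa_local[0] + Ri[k, 1] * sa_local[1] + Ri[k, 2] * sa_local[2]
        xb[k] = pj_sh[k] + Rj[k, 0] * sb_local[0] + Rj[k, 1] * sb_local[1] + Rj[k, 2] * sb_local[2]
    e = np.empty(3)
    dd = 0.0
    for k in range(3):
        e[k] = xb[k] - xa[k]
        dd += e[k] * e[k]
    dd = np.sqrt(dd)
    if dd < 1e-12:
        return 0.0
    for k in range(3):
        e[k] /= dd
    wi = omega_world(qi, L0[i], moments[si, 0], moments[si, 2])
    wj = omega_world(qj, L0[j], moments[sj, 0], moments[sj, 2])
    u = _rel_point_vel(vel0[i], wi, pi, vel0[j], wj, pj_sh, xa, xb)
    return u[0] * e[0] + u[1] * e[1] + u[2] * e[2]


@njit(cache=True)
def _ev_append(ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb, ev_valid, n_ev,
               t, kind, i, j, sa, sb):
    if n_ev >= EV_CAP:
        m = 0
        for k in range(n_ev):
            if ev_valid[k]:
                ev_t[m] = ev_t[k]
                ev_kind[m] = ev_kind[k]
                ev_i[m] = ev_i[k]
                ev_j[m] = ev_j[k]
                ev_sa[m] = ev_sa[k]
                ev_sb[m] = ev_sb[k]
                ev_valid[m] = True
                m += 1
        n_ev = m
        if n_ev >= EV_CAP:
            return -1
    ev_t[n_ev] = t
    ev_kind[n_ev] = kind
    ev_i[n_ev] = i
    ev_j[n_ev] = j
    ev_sa[n_ev] = sa
    ev_sb[n_ev] = sb
    ev_valid[n_ev] = True
    return n_ev + 1


@njit(cache=True)
def _scan_core_pair(i, j, h, pos0, quat0, vel0, L0, tau, species, moments,
                    semiaxes, brad, edges, pos_h, quad_h, axis_h,
                    ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb, ev_valid, n_ev,
                    prof):
    """Queue the pair's next hard-core crossing, using cached endpoint data.

    Returns (n_ev, err): err = 1 flags a deep unresolvable penetration.
    """
    dx = pos_h[j, 0] - pos_h[i, 0]
    dy = pos_h[j, 1] - pos_h[i, 1]
    dz = pos_h[j, 2] - pos_h[i, 2]
    dx -= np.round(dx / edges[0]) * edges[0]
    dy -= np.round(dy / edges[1]) * edges[1]
    dz -= np.round(dz / edges[2]) * edges[2]
    rb = brad[species[i]] + brad[species[j]]
    prof[0] += 1
    if dx * dx + dy * dy + dz * dz > rb * rb:
        return n_ev, 0
    # spherocylinder prescreen: a (b, b, c) prolate ellipsoid fits in the
    # spherocylinder of radius b with segment half-length c - b
    si = species[i]
    sj = species[j]
    rmin = semiaxes[si, 0] + semiaxes[sj, 0] + 0.15
    seg2 = _segseg_dist2(
        0.0, 0.0, 0.0, axis_h[i, 0], axis_h[i, 1], axis_h[i, 2],
        semiaxes[si, 2] - semiaxes[si, 0],
        dx, dy, dz, axis_h[j, 0], axis_h[j, 1], axis_h[j, 2],
        semiaxes[sj, 2] - semiaxes[sj, 0])
    if seg2 > rmin * rmin:
        return n_ev, 0
    prof[1] += 1
    d = np.empty(3)
    d[0] = dx
    d[1] = dy
    d[2] = dz
    if support_separated(quad_h[i], quad_h[j], d):
        return n_ev, 0
    if not pw_overlaps(quad_h[i], quad_h[j], d):
        return n_ev, 0
    prof[2] += 1
    t0 = max(tau[i], tau[j])
    if _pair_overlap_fast(t0, i, j, pos0, quat0, vel0, L0, tau, species,
                          moments, semiaxes, edges):
        # already touching at the window start (an earlier graze): bounce
        # now if still closing, else let it clear
        F, _ = pw_value(quad_h[i], quad_h[j], d)
        if F < 0.5:
            return n_ev, 1
        un0 = _core_un_t(t0, i, j, pos0, quat0, vel0, L0, tau, species,
                         moments, semiaxes, edges)
        if un0 > 1e-14:
            n_ev = _ev_append(ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb,
                              ev_valid, n_ev, t0, EV_CORE, i, j, -1, -1)
        return n_ev, 0
    lo = t0
    hi = h
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        if _pair_overlap_fast(mid, i, j, pos0, quat0, vel0, L0, tau, species,
                              moments, semiaxes, edges):
            hi = mid
        else:
            lo = mid
    un = _core_un_t(lo, i, j, pos0, quat0, vel0, L0, tau, species, moments,
                    semiaxes, edges)
    if un <= 1e-14:
        return n_ev, 0
    n_ev = _ev_append(ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb, ev_valid,
                      n_ev, lo, EV_CORE, i, j, -1, -1)
    return n_ev, 0


@njit(cache=True)
def _scan_site_pair(i, j, h, pos0, quat0, vel0, L0, tau, species, moments,
                    edges, site_local, site_start, partner, delta,
                    pos_h, site_h, axis_h, semiaxes,
                    ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb, ev_valid, n_ev,
                    prof):
    """Queue shell crossings of every live site pair of particles (i, j).

    i must be species A, j species B.  Returns (n_ev, err): err = 1 flags a
    bonded pair found far outside its confinement well.
    """
    dx = pos_h[j, 0] - pos_h[i, 0]
    dy = pos_h[j, 1] - pos_h[i, 1]
    dz = pos_h[j, 2] - pos_h[i, 2]
    sx = -np.round(dx / edges[0]) * edges[0]
    sy = -np.round(dy / edges[1]) * edges[1]
    sz = -np.round(dz / edges[2]) * edges[2]
    dx += sx
    dy += sy
    dz += sz
    close = 10.0 + 4.3302 + delta + 0.6
    prof[3] += 1
    if dx * dx + dy * dy + dz * dz > close * close:
        return n_ev, 0
    # sites live on the surfaces, which fit in the spherocylinders
    si = species[i]
    sj = species[j]
    rmin = semiaxes[si, 0] + semiaxes[sj, 0] + delta + 1.2
    seg2 = _segseg_dist2(
        0.0, 0.0, 0.0, axis_h[i, 0], axis_h[i, 1], axis_h[i, 2],
        semiaxes[si, 2] - semiaxes[si, 0],
        dx, dy, dz, axis_h[j, 0], axis_h[j, 1], axis_h[j, 2],
        semiaxes[sj, 2] - semiaxes[sj, 0])
    if seg2 > rmin * rmin:
        return n_ev, 0
    prof[4] += 1
    t0 = max(tau[i], tau[j])
    for sa in range(site_start[i], site_start[i + 1]):
        for sb in range(site_start[j], site_start[j + 1]):
            bonded = partner[sa] == sb
            if not bonded and (partner[sa] >= 0 or partner[sb] >= 0):
                continue
            ddx = site_h[sb, 0] + sx - site_h[sa, 0]
            ddy = site_h[sb, 1] + sy - site_h[sa, 1]
            ddz = site_h[sb, 2] + sz - site_h[sa, 2]
            dist = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            crossed_in = (not bonded) and dist < delta
            crossed_out = bonded and dist > delta
            if not (crossed_in or crossed_out):
                continue
            prof[5] += 1
            d0 = _site_dist_fast(t0, i, j,
                                 site_local[sa, 0], site_local[sa, 1],
                                 site_local[sa, 2], site_local[sb, 0],
                                 site_local[sb, 1], site_local[sb, 2],
                                 pos0, quat0, vel0, L0, tau, species,
                                 moments, edges)
            if crossed_in and d0 < delta:
                continue   # started inside the shell: no crossing event
            if crossed_out and d0 > delta:
                # already outside the wall (a tangential exit skipped
                # earlier): reflect now if still separating.  Tumbling can
                # carry such a pair a few tenths of sigma out before a
                # separating snapshot lets the reflection fire, so only a
                # gross excursion is an integration failure.
                if dist > delta + 1.0:
                    return n_ev, 1
                ue0 = _site_ue_t(t0, i, j, site_local[sa], site_local[sb],
                                 pos0, quat0, vel0, L0, tau, species,
                                 moments, edges)
                if ue0 < -1e-14:
                    n_ev = _ev_append(ev_t, ev_kind, ev_i, ev_j, ev_sa,
                                      ev_sb, ev_valid, n_ev, t0, EV_WALL_OUT,
                                      i, j, sa, sb)
                continue
            lo = t0
            hi = h
            if crossed_in:
                for _ in range(45):
                    mid = 0.5 * (lo + hi)
                    dm = _site_dist_fast(mid, i, j,
                                         site_local[sa, 0], site_local[sa, 1],
                                         site_local[sa, 2], site_local[sb, 0],
                                         site_local[sb, 1], site_local[sb, 2],
                                         pos0, quat0, vel0, L0, tau, species,
                                         moments, edges)
                    if dm >= delta:
                        lo = mid
                    else:
                        hi = mid
            else:
                for _ in range(45):
                    mid = 0.5 * (lo + hi)
                    dm = _site_dist_fast(mid, i, j,
                                         site_local[sa, 0], site_local[sa, 1],
                                         site_local[sa, 2], site_local[sb, 0],
                                         site_local[sb, 1], site_local[sb, 2],
                                         pos0, quat0, vel0, L0, tau, species,
                                         moments, edges)
                    if dm <= delta:
                        lo = mid
                    else:
                        hi = mid
            ue = _site_ue_t(lo, i, j, site_local[sa], site_local[sb],
                            pos0, quat0, vel0, L0, tau, species, moments,
                            edges)
            if crossed_in and ue <= 1e-14:
                continue
            if crossed_out and ue >= -1e-14:
                continue
            kind = EV_SITE_IN if crossed_in else EV_WALL_OUT
            n_ev = _ev_append(ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb,
                              ev_valid, n_ev, lo, kind, i, j, sa, sb)
    return n_ev, 0


@njit(cache=True)
def _build_adjacency(nb, n_pairs, n):
    """CSR adjacency (body -> indices into the pair list)."""
    deg = np.zeros(n + 1, dtype=np.int64)
    for idx in range(n_pairs):
        deg[nb[idx, 0] + 1] += 1
        deg[nb[idx, 1] + 1] += 1
    for b in range(n):
        deg[b + 1] += deg[b]
    adj = np.empty(deg[n], dtype=np.int64)
    fill = deg[:n].copy()
    for idx in range(n_pairs):
        for c in range(2):
            b = nb[idx, c]
            adj[fill[b]] = idx
            fill[b] += 1
    return deg, adj


@njit(cache=True)
def advance_block(pos, quat, vel, L, species, masses, moments, semiaxes, brad,
                  site_owner, site_local, site_isA, site_start, partner,
                  edges, t_block, h_sub,
                  delta, u0, dU, beta, crossing_mode,
                  frozen, hardcore,
                  new_bonds, counters):
    """Advance the whole system by *t_block* (natural units).

    counters: int64[5] -- attempts, crossings, core collisions, wall
    reflections, sub-steps.  new_bonds: int64[(max,2)] output buffer.
    Returns (n_new_bonds, err_code).
    """
    n = pos.shape[0]
    n_sites = site_owner.shape[0]
    p_cross = np.exp(-beta * dU)
    n_new = 0
    t = 0.0

    pos0 = np.empty_like(pos)
    quat0 = np.empty_like(quat)
    vel0 = np.empty_like(vel)
    L0 = np.empty_like(L)
    tau = np.zeros(n)
    pos_h = np.empty_like(pos)
    quat_h = np.empty_like(quat)
    quad_h = np.empty((n, 3, 3))
    site_h = np.empty((n_sites, 3))
    axis_h = np.empty((n, 3))

    ev_t = np.empty(EV_CAP)
    ev_kind = np.empty(EV_CAP, dtype=np.int8)
    ev_i = np.empty(EV_CAP, dtype=np.int64)
    ev_j = np.empty(EV_CAP, dtype=np.int64)
    ev_sa = np.empty(EV_CAP, dtype=np.int64)
    ev_sb = np.empty(EV_CAP, dtype=np.int64)
    ev_valid = np.zeros(EV_CAP, dtype=np.bool_)
    prof = np.zeros(8, dtype=np.int64)

    # neighbor lists, rebuilt once per block; the 3-sigma skin covers any
    # relative motion over one barrier-refresh block
    # the 4-sigma list skin covers translation plus tip swing over a block
    skin = 4.0
    axes0 = np.empty((n, 3))
    for b in range(n):
        R = q_to_mat(quat[b])
        axes0[b, 0] = R[0, 2]
        axes0[b, 1] = R[1, 2]
        axes0[b, 2] = R[2, 2]
    nb_core = np.empty((n * (n - 1) // 2 + 1, 2), dtype=np.int64)
    n_core = 0
    if hardcore:
        for i in range(n):
            for j in range(i + 1, n):
                rb2 = brad[species[i]] + brad[species[j]] + skin
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                dx -= np.round(dx / edges[0]) * edges[0]
                dy -= np.round(dy / edges[1]) * edges[1]
                dz -= np.round(dz / edges[2]) * edges[2]
                if dx * dx + dy * dy + dz * dz > rb2 * rb2:
                    continue
                si = species[i]
                sj = species[j]
                rmin = semiaxes[si, 0] + semiaxes[sj, 0] + skin
                seg2 = _segseg_dist2(
                    0.0, 0.0, 0.0, axes0[i, 0], axes0[i, 1], axes0[i, 2],
                    semiaxes[si, 2] - semiaxes[si, 0],
                    dx, dy, dz, axes0[j, 0], axes0[j, 1], axes0[j, 2],
                    semiaxes[sj, 2] - semiaxes[sj, 0])
                if seg2 <= rmin * rmin:
                    nb_core[n_core, 0] = i
                    nb_core[n_core, 1] = j
                    n_core += 1
    nb_site = np.empty((n * n // 4 + 1, 2), dtype=np.int64)
    n_site_pairs = 0
    for i in range(n):
        if species[i] != 0:
            continue
        for j in range(n):
            if species[j] != 1:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= np.round(dx / edges[0]) * edges[0]
            dy -= np.round(dy / edges[1]) * edges[1]
            dz -= np.round(dz / edges[2]) * edges[2]
            si = species[i]
            sj = species[j]
            rmin = semiaxes[si, 0] + semiaxes[sj, 0] + delta + skin
            if dx * dx + dy * dy + dz * dz > (10.0 + 4.3302 + delta + skin) ** 2:
                continue
            seg2 = _segseg_dist2(
                0.0, 0.0, 0.0, axes0[i, 0], axes0[i, 1], axes0[i, 2],
                semiaxes[si, 2] - semiaxes[si, 0],
                dx, dy, dz, axes0[j, 0], axes0[j, 1], axes0[j, 2],
                semiaxes[sj, 2] - semiaxes[sj, 0])
            if seg2 <= rmin * rmin:
                nb_site[n_site_pairs, 0] = i
                nb_site[n_site_pairs, 1] = j
                n_site_pairs += 1
    core_deg, core_adj = _build_adjacency(nb_core, n_core, n)
    site_deg, site_adj = _build_adjacency(nb_site, n_site_pairs, n)

    while t < t_block - 1e-15:
        h = min(h_sub, t_block - t)
        pos0[:] = pos
        quat0[:] = quat
        vel0[:] = vel
        L0[:] = L
        tau[:] = 0.0
        counters[4] += 1
        n_ev = 0
        for b in range(n):
            _refresh_endpoint(b, h, pos0, quat0, vel0, L0, tau, species,
                              moments, semiaxes, site_local, site_start,
                              pos_h, quat_h, quad_h, site_h, axis_h)

        # full detection pass
        if hardcore:
            for idx in range(n_core):
                n_ev, err = _scan_core_pair(
                    nb_core[idx, 0], nb_core[idx, 1], h, pos0, quat0, vel0,
                    L0, tau, species, moments, semiaxes, brad, edges,
                    pos_h, quad_h, axis_h,
                    ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb, ev_valid, n_ev, prof)
                if err != 0:
                    return n_new, ERR_OVERLAP_START
                if n_ev < 0:
                    return n_new, ERR_EVENT_LOOP
        for idx in range(n_site_pairs):
            n_ev, err = _scan_site_pair(
                nb_site[idx, 0], nb_site[idx, 1], h, pos0, quat0, vel0, L0,
                tau, species, moments, edges, site_local, site_start,
                partner, delta, pos_h, site_h, axis_h, semiaxes,
                ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb, ev_valid, n_ev, prof)
            if err != 0:
                return n_new, ERR_BOND_ESCAPE
            if n_ev < 0:
                return n_new, ERR_EVENT_LOOP

        # process events in time order
        guard = 400 * (n + 10)
        while True:
            m_best = -1
            t_best = h + 1.0
            for m in range(n_ev):
                if ev_valid[m] and ev_t[m] < t_best:
                    t_best = ev_t[m]
                    m_best = m
            if m_best < 0:
                break
            guard -= 1
            prof[6] += 1
            if guard <= 0:
                return n_new, ERR_EVENT_LOOP
            te = ev_t[m_best]
            kind = ev_kind[m_best]
            i = ev_i[m_best]
            j = ev_j[m_best]
            sa = ev_sa[m_best]
            sb = ev_sb[m_best]
            ev_valid[m_best] = False

            # patch both bodies to the event time
            for idx2 in range(2):
                b = i if idx2 == 0 else j
                newp = _body_pos_at(b, te, pos0, vel0, tau)
                newq = _body_quat_at(b, te, quat0, L0, tau, species, moments)
                pos0[b] = newp
                quat0[b] = newq
                tau[b] = te

            si, sj = species[i], species[j]
            d = np.empty(3)
            for k in range(3):
                d[k] = pos0[j, k] - pos0[i, k]
            dmi = min_image(d, edges)
            shift = np.empty(3)
            for k in range(3):
                shift[k] = dmi[k] - d[k]

            changed = False
            if kind == EV_CORE:
                Ainv = world_inv_quadric(quat0[i], semiaxes[si])
                Binv = world_inv_quadric(quat0[j], semiaxes[sj])
                xc, nvec = pw_contact_geometry(Ainv, Binv, pos0[i], dmi)
                wi = omega_world(quat0[i], L0[i], moments[si, 0],
                                 moments[si, 2])
                wj = omega_world(quat0[j], L0[j], moments[sj, 0],
                                 moments[sj, 2])
                pj_sh = np.empty(3)
                for k in range(3):
                    pj_sh[k] = pos0[j, k] + shift[k]
                u = _rel_point_vel(vel0[i], wi, pos0[i], vel0[j], wj, pj_sh,
                                   xc, xc)
                un = u[0] * nvec[0] + u[1] * nvec[1] + u[2] * nvec[2]
                if un > 0.0:
                    ra = np.empty(3)
                    rb = np.empty(3)
                    for k in range(3):
                        ra[k] = xc[k] - pos0[i, k]
                        rb[k] = xc[k] - pj_sh[k]
                    Keff = _effective_inv_mass(nvec, ra, rb, masses[si],
                                               masses[sj], quat0[i],
                                               quat0[j], moments[si],
                                               moments[sj])
                    xb_real = np.empty(3)
                    for k in range(3):
                        xb_real[k] = xc[k] - shift[k]
                    _apply_impulse(i, j, nvec, -2.0 * un / Keff, xc, xb_real,
                                   pos0, vel0, L0, masses, species)
                    counters[2] += 1
                    changed = True
            else:
                Ra = q_to_mat(quat0[i])
                Rb = q_to_mat(quat0[j])
                xa = np.empty(3)
                xb = np.empty(3)
                for k in range(3):
                    xa[k] = (pos0[i, k] + Ra[k, 0] * site_local[sa, 0]
                             + Ra[k, 1] * site_local[sa, 1]
                             + Ra[k, 2] * site_local[sa, 2])
                    xb[k] = (pos0[j, k] + shift[k]
                             + Rb[k, 0] * site_local[sb, 0]
                             + Rb[k, 1] * site_local[sb, 1]
                             + Rb[k, 2] * site_local[sb, 2])
                e = np.empty(3)
                dd = 0.0
                for k in range(3):
                    e[k] = xb[k] - xa[k]
                    dd += e[k] * e[k]
                dd = np.sqrt(dd)
                if dd >= 1e-12:
                    for k in range(3):
                        e[k] /= dd
                    wi = omega_world(quat0[i], L0[i], moments[si, 0],
                                     moments[si, 2])
                    wj = omega_world(quat0[j], L0[j], moments[sj, 0],
                                     moments[sj, 2])
                    pj_sh = np.empty(3)
                    for k in range(3):
                        pj_sh[k] = pos0[j, k] + shift[k]
                    u = _rel_point_vel(vel0[i], wi, pos0[i], vel0[j], wj,
                                       pj_sh, xa, xb)
                    ue = u[0] * e[0] + u[1] * e[1] + u[2] * e[2]
                    ra = np.empty(3)
                    rb = np.empty(3)
                    for k in range(3):
                        ra[k] = xa[k] - pos0[i, k]
                        rb[k] = xb[k] - pj_sh[k]
                    Keff = _effective_inv_mass(e, ra, rb, masses[si],
                                               masses[sj], quat0[i],
                                               quat0[j], moments[si],
                                               moments[sj])
                    xb_real = np.empty(3)
                    for k in range(3):
                        xb_real[k] = xb[k] - shift[k]
                    if kind == EV_WALL_OUT:
                        if partner[sa] == sb and ue < 0.0:
                            _apply_impulse(i, j, e, -2.0 * ue / Keff, xa,
                                           xb_real, pos0, vel0, L0, masses,
                                           species)
                            counters[3] += 1
                            changed = True
                    else:
                        if (ue > 0.0 and partner[sa] < 0 and partner[sb] < 0):
                            counters[0] += 1
                            cross = False
                            if not frozen:
                                if crossing_mode == 0:
                                    cross = 0.5 * ue * ue / Keff > dU
                                else:
                                    cross = np.random.random() < p_cross
                            if cross:
                                counters[1] += 1
                                new_bonds[n_new, 0] = sa
                                new_bonds[n_new, 1] = sb
                                n_new += 1
                                partner[sa] = sb
                                partner[sb] = sa
                                if crossing_mode == 0 and u0 > 0.0:
                                    ue_new = np.sqrt(ue * ue
                                                     + 2.0 * Keff * u0)
                                    _apply_impulse(i, j, e,
                                                   (ue_new - ue) / Keff,
                                                   xa, xb_real, pos0, vel0,
                                                   L0, masses, species)
                                changed = True
                            else:
                                _apply_impulse(i, j, e, -2.0 * ue / Keff,
                                               xa, xb_real, pos0, vel0, L0,
                                               masses, species)
                                changed = True

            if not changed:
                continue
            # refresh the patched bodies' cached endpoint data, drop their
            # stale events, and re-scan only their neighbor pairs
            _refresh_endpoint(i, h, pos0, quat0, vel0, L0, tau, species,
                              moments, semiaxes, site_local, site_start,
                              pos_h, quat_h, quad_h, site_h, axis_h)
            _refresh_endpoint(j, h, pos0, quat0, vel0, L0, tau, species,
                              moments, semiaxes, site_local, site_start,
                              pos_h, quat_h, quad_h, site_h, axis_h)
            for m in range(n_ev):
                if ev_valid[m] and (ev_i[m] == i or ev_j[m] == i
                                    or ev_i[m] == j or ev_j[m] == j):
                    ev_valid[m] = False
            for idx2 in range(2):
                b = i if idx2 == 0 else j
                if hardcore:
                    for a in range(core_deg[b], core_deg[b + 1]):
                        idx = core_adj[a]
                        n_ev, err = _scan_core_pair(
                            nb_core[idx, 0], nb_core[idx, 1], h, pos0,
                            quat0, vel0, L0, tau, species, moments,
                            semiaxes, brad, edges, pos_h, quad_h, axis_h,
                            ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb,
                            ev_valid, n_ev, prof)
                        if err != 0:
                            return n_new, ERR_OVERLAP_START
                        if n_ev < 0:
                            return n_new, ERR_EVENT_LOOP
                for a in range(site_deg[b], site_deg[b + 1]):
                    idx = site_adj[a]
                    n_ev, err = _scan_site_pair(
                        nb_site[idx, 0], nb_site[idx, 1], h, pos0, quat0,
                        vel0, L0, tau, species, moments, edges, site_local,
                        site_start, partner, delta, pos_h, site_h, axis_h,
                        semiaxes,
                        ev_t, ev_kind, ev_i, ev_j, ev_sa, ev_sb, ev_valid,
                        n_ev, prof)
                    if err != 0:
                        return n_new, ERR_BOND_ESCAPE
                    if n_ev < 0:
                        return n_new, ERR_EVENT_LOOP
                if i == j:
                    break

        # finalize: everyone flies to the end of the sub-step
        pos[:] = pos_h
        quat[:] = quat_h
        vel[:] = vel0
        L[:] = L0
        t += h
    if counters.shape[0] >= 13:
        for k in range(8):
            counters[5 + k] = prof[k]
    return n_new, ERR_OK


# ------------------------------------------------------------------- packing

@njit(cache=True)
def _random_quat():
    q = np.empty(4)
    s = 0.0
    for k in range(4):
        q[k] = np.random.normal()
        s += q[k] * q[k]
    return q / np.sqrt(s)


@njit(cache=True)
def _overlaps_any(idx, pos, quat, species, semiaxes, brad, edges, n_placed):
    Ainv = world_inv_quadric(quat[idx], semiaxes[species[idx]])
    for j in range(n_placed):
        if j == idx:
            continue
        d = np.empty(3)
        for k in range(3):
            d[k] = pos[j, k] - pos[idx, k]
        d = min_image(d, edges)
        rb = brad[species[idx]] + brad[species[j]]
        if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] > rb * rb:
            continue
        Binv = world_inv_quadric(quat[j], semiaxes[species[j]])
        if support_separated(Ainv, Binv, d):
            continue
        F, _ = pw_value(Ainv, Binv, d)
        if F < 1.0:
            return True
    return False


@njit(cache=True)
def packing_insert(species, semiaxes, brad, edges, seed):
    np.random.seed(seed)
    n = species.shape[0]
    pos = np.empty((n, 3))
    quat = np.empty((n, 4))
    n_bad = 0
    for i in range(n):
        placed = False
        for _ in range(2000):
            for k in range(3):
                pos[i, k] = np.random.random() * edges[k]
            quat[i] = _random_quat()
            if not _overlaps_any(i, pos, quat, species, semiaxes, brad,
                                 edges, i):
                placed = True
                break
        if not placed:
            n_bad += 1
    return pos, quat, n_bad


@njit(cache=True)
def packing_relax(pos, quat, species, semiaxes, brad, edges, seed):
    """Push-apart relaxation of residual hard-core overlaps."""
    np.random.seed(seed)
    n = pos.shape[0]
    for _ in range(4000):
        n_overlap = 0
        for i in range(n):
            Ainv = world_inv_quadric(quat[i], semiaxes[species[i]])
            for j in range(i + 1, n):
                d = np.empty(3)
                for k in range(3):
                    d[k] = pos[j, k] - pos[i, k]
                d = min_image(d, edges)
                rb = brad[species[i]] + brad[species[j]]
                if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] > rb * rb:
                    continue
                Binv = world_inv_quadric(quat[j], semiaxes[species[j]])
                if support_separated(Ainv, Binv, d):
                    continue
                F, _ = pw_value(Ainv, Binv, d)
                if F >= 1.0:
                    continue
                n_overlap += 1
                dn = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
                step = 0.15 * (1.0 - F) + 0.02
                if dn < 1e-9:
                    for k in range(3):
                        d[k] = np.random.normal()
                    dn = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
                for k in range(3):
                    pos[i, k] -= step * d[k] / dn
                    pos[j, k] += step * d[k] / dn
                # small random reorientation helps wedged elongated pairs
                axis = np.empty(3)
                s = 0.0
                for k in range(3):
                    axis[k] = np.random.normal()
                    s += axis[k] * axis[k]
                axis /= np.sqrt(s)
                dq = q_from_axis_angle(axis, 0.12 * (1.0 - F)
                                       * np.random.random())
                quat[j] = q_normalize(q_mul(dq, quat[j]))
                Ainv = world_inv_quadric(quat[i], semiaxes[species[i]])
        if n_overlap == 0:
            return True
    return False
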