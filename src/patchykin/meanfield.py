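"""Mean-field rate framework for autocatalytic step-growth aggregation.

The second-order rate law ``dp/dt = k_overall (1 - p)^2`` combines a
chemical and a diffusive channel in series,
``k_overall = (1/k_chem + 1/k_diff)^-1``.  An entry barrier dU suppresses
both channels by the Boltzmann factor, but not *only* by it: the barrier
effect adds a chemical correction ``(1 - p)^(n-2)`` with ``n < 2`` and a
diffusive prefactor ``k0 > 1``:

    k_chem = k_c (1 - p)^(n-2) exp(-beta dU)
    k_diff = k_d k0 D exp(-beta dU)

Autocatalysis lowers the barrier with conversion,
``dU(p) = dU0 - ln(1 + xi p)/beta``, so the Boltzmann factor becomes
``(1 + xi p) exp(-beta dU0)`` and the barrier-effect parameters acquire a p
dependence:

    n(p)  = n_inf + (n0 - n_inf)(1 + xi p) exp(-beta dU0)
    k0(p) = (1 + xi p)^(-b) exp(b beta dU0)

All rates are in reduced-time units; energies in k_BT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MeanFieldRateParams",
    "KamalParams",
    "effective_barrier",
    "expected_attempts",
    "rate_constants_fixed",
    "rate_constants_auto",
    "diffusion_model",
    "kamal_rate",
    "integrate_kinetics",
    "smoothed_derivative",
]


@dataclass
class MeanFieldRateParams:
    """Constants of the barrier-effect rate framework.

    ``k_c``/``k_d``: chemical and diffusive prefactors of the barrier-free
    system.  ``n0``/``n_inf``: limits of the chemical barrier-effect
    exponent law ``n(dU) = (n0 - n_inf) exp(-beta dU) + n_inf``; ``b``:
    growth exponent of ``k0 = exp(b beta dU)``.  ``D0, p0, gamma``
    parametrize the diffusion model ``D = D0 [(p0 - p)/p0]^gamma``.
    """

    k_c: float
    k_d: float
    n0: float = 2.0
    n_inf: float = 1.83
    b: float = 0.31
    dU0: float = 0.0
    xi: float = 0.0
    beta: float = 1.0
    D0: float = 1.0
    p0: float = 0.902
    gamma: float = 2.69

    def __post_init__(self) -> None:
        if self.k_c <= 0 or self.k_d <= 0:
            raise ValueError("k_c and k_d must be positive")
        if not 0 < self.n_inf <= self.n0:
            raise ValueError("need 0 < n_inf <= n0")
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def D(self, p):
        return diffusion_model(p, self.D0, self.p0, self.gamma)


@dataclass
class KamalParams:
    """Phenomenological cure-kinetics constants.

    ``k_chem = (k1 + k2 p^M)(1 - p)^(N - 2)``; the ratio ``k2/k1`` is the
    apparent autocatalytic strength.
    """

    k1: float
    k2: float
    M: float = 1.0
    N: float = 2.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("Kamal rate constants must be >= 0")

    @property
    def xi_hat(self) -> float:
        return self.k2 / self.k1


def effective_barrier(p, dU0: float, xi: float, beta: float = 1.0):
    """Autocatalytically decreasing entry barrier, floored at zero.

    ``dU = dU0 - ln(1 + xi p)/beta``; while unfloored the Boltzmann factor
    is exactly ``exp(-beta dU0) (1 + xi p)``.
    """
    if xi < 0:
        raise ValueError("autocatalytic strength xi must be >= 0")
    p = np.asarray(p, dtype=float)
    return np.maximum(0.0, dU0 - np.log1p(xi * p) / beta)


def expected_attempts(beta_dU):
    """Mean number of barrier collisions per formed bond, ``exp(beta dU)``.

    Closed form of the geometric attempt statistics: each collision succeeds
    with probability ``exp(-beta dU)``.
    """
    beta_dU = np.asarray(beta_dU, dtype=float)
    if np.any(beta_dU < 0):
        raise ValueError("beta dU must be >= 0")
    return np.exp(beta_dU)


def rate_constants_fixed(p, D, params: MeanFieldRateParams, beta_dU: float,
                         n: float | None = None, k0: float | None = None):
    """(k_chem, k_diff, k_overall) at a fixed barrier height.

    Unless given explicitly, ``n`` and ``k0`` follow their barrier laws
    ``n = (n0 - n_inf) e^(-beta dU) + n_inf`` and ``k0 = e^(b beta dU)``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p must be in [0, 1)")
    if n is None:
        n = params.n_inf + (params.n0 - params.n_inf) * np.exp(-beta_dU)
    if k0 is None:
        k0 = np.exp(params.b * beta_dU)
    boltz = np.exp(-beta_dU)
    k_chem = params.k_c * (1.0 - p) ** (n - 2.0) * boltz
    k_diff = params.k_d * k0 * np.asarray(D, dtype=float) * boltz
    return k_chem, k_diff, _harmonic(k_chem, k_diff)


def rate_constants_auto(p, D, params: MeanFieldRateParams):
    """(k_chem, k_diff, k_overall) for the autocatalytic reaction.

    Obtained by substituting the decreasing barrier ``dU(p)`` into the
    fixed-barrier forms; the Boltzmann factor turns into
    ``(1 + xi p) exp(-beta dU0)`` and n, k0 become p dependent.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p must be in [0, 1)")
    bdU0 = params.beta * params.dU0
    grow = 1.0 + params.xi * p
    n = params.n_inf + (params.n0 - params.n_inf) * grow * np.exp(-bdU0)
    k0 = grow ** (-params.b) * np.exp(params.b * bdU0)
    boltz = grow * np.exp(-bdU0)
    k_chem = params.k_c * (1.0 - p) ** (n - 2.0) * boltz
    k_diff = params.k_d * k0 * np.asarray(D, dtype=float) * boltz
    return k_chem, k_diff, _harmonic(k_chem, k_diff)


def _harmonic(ka, kb):
    ka = np.asarray(ka, dtype=float)
    kb = np.asarray(kb, dtype=float)
    out = np.zeros(np.broadcast(ka, kb).shape)
    with np.errstate(divide="ignore"):
        num = ka * kb
        den = ka + kb
    np.divide(num, den, out=out, where=den > 0)
    return out if out.ndim else float(out)


def diffusion_model(p, D0: float, p0: float, gamma: float):
    """Power-law vanishing diffusivity ``D = D0 [(p0 - p)/p0]^gamma``."""
    p = np.asarray(p, dtype=float)
    if np.any(p > p0):
        warnings.warn("p beyond the diffusion arrest point p0; D set to 0",
                      stacklevel=2)
    x = np.clip((p0 - p) / p0, 0.0, None)
    out = D0 * x ** gamma
    return float(out) if out.ndim == 0 else out


def kamal_rate(p, params: KamalParams):
    """Kamal chemical rate constant ``(k1 + k2 p^M)(1 - p)^(N-2)``."""
    p = np.asarray(p, dtype=float)
    out = (params.k1 + params.k2 * p ** params.M) * (1.0 - p) ** (params.N - 2.0)
    return float(out) if out.ndim == 0 else out


def integrate_kinetics(params: MeanFieldRateParams, t_grid,
                       mode: str = "auto",
                       kamal: KamalParams | None = None,
                       k_overall=None, D_of_p=None, rtol: float = 1e-10):
    """Integrate ``dp/dt = k_overall(p) (1 - p)^2`` from p(0) = 0.

    ``mode`` selects the rate model: ``"fixed"`` (constant barrier dU0),
    ``"auto"`` (autocatalytically decreasing barrier) or ``"kamal"``
    (phenomenological chemical constant, requires *kamal*).  A custom
    ``k_overall(p)`` callable overrides the mode.  ``D_of_p`` overrides the
    internal diffusion model (callable p -> D).  Integration is adaptive and
    stiff-capable; p is clamped to the diffusion arrest point p0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    Dfun = D_of_p if D_of_p is not None else params.D

    if k_overall is None:
        if mode == "fixed":
            def k_overall(p):
                return rate_constants_fixed(
                    p, Dfun(p), params, params.beta * params.dU0)[2]
        elif mode == "auto":
            def k_overall(p):
                return rate_constants_auto(p, Dfun(p), params)[2]
        elif mode == "kamal":
            if kamal is None:
                raise ValueError("mode='kamal' requires KamalParams")

            def k_overall(p):
                kc = kamal_rate(p, kamal)
                return _harmonic(kc, params.k_d * Dfun(p))
        else:
            raise ValueError(f"unknown mode {mode!r}")

    p_cap = min(params.p0, 1.0) - 1e-12

    def rhs(t, y):
        p = min(max(y[0], 0.0), p_cap)
        k = float(np.asarray(k_overall(p)))
        if not np.isfinite(k):
            raise ValueError("non-finite rate constant")
        return [k * (1.0 - p) ** 2]

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [0.0], t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"kinetics integration failed: {sol.message}")
    p = np.clip(np.maximum.accumulate(sol.y[0]), 0.0, p_cap)
    from .observables import KineticCurve

    return KineticCurve(times=t_grid, p=p)


def smoothed_derivative(t, y, window: int = 5, order: int = 2):
    """Local-polynomial (Savitzky-Golay-style) derivative on a ragged grid.

    Fits a polynomial of *order* to the *window* points around each sample
    and returns its slope there.  Window is clipped near the edges.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    if window < order + 1:
        raise ValueError("window must exceed the polynomial order")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        tt, yy = t[lo:hi], y[lo:hi]
        c = np.polyfit(tt - t[i], yy, min(order, len(tt) - 1))
        out[i] = c[-2] if len(c) >= 2 else 0.0
    return out
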