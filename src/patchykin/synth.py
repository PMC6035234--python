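"""Synthetic epoxy-style isotherm generator.

Published cure datasets for DGEBA-amine resins are not redistributable, so
parameter-recovery and calibration tests run on synthetic isotherms that
emulate their structure: several reaction temperatures, a catalytic +
autocatalytic Arrhenius chemical rate with the barrier-effect exponent
n(p) < 2, a diffusive channel ``k_diff = k_d tau^-lambda`` driven by a
Vogel-type structural relaxation time ``tau(p, T)`` that grows by decades
as the system approaches vitrification, and measurement noise on the
conversion.  The generator returns the hidden truth alongside the data so
estimators can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .fitting import K_B, EpoxyFitParams, ExperimentalIsotherm

__all__ = ["SyntheticIsothermSpec", "default_truth",
           "generate_synthetic_isotherms"]


def default_truth() -> EpoxyFitParams:
    """Realistic truth constants for a DGEBA-amine-like system.

    Enthalpies ~1e-19 J per bond and n_inf < 2 sit in the range typical of
    epoxy-amine cures; prefactors are chosen so isothermal cure near 340 K
    takes tens of minutes.
    """
    return EpoxyFitParams(dU_c=9.6e-20, dU_a=9.1e-20, A=5.0e6, B=2.0e7,
                          n_inf=1.38, k_d=6.0e-3, lam=0.45)


@dataclass
class SyntheticIsothermSpec:
    """Truth parameters, temperatures, sampling and noise of one dataset."""

    truth: EpoxyFitParams = field(default_factory=default_truth)
    T_list: tuple = (330.0, 340.0, 350.0, 360.0)
    n_points: int = 60
    p_stop: float = 0.85          # integrate each isotherm up to this p
    noise: float = 0.002          # sigma on p
    noise_mode: str = "additive"  # or "multiplicative"
    # Vogel-type relaxation time tau(p, T) = tau_inf e^(dU_tau/kT) e^(c p/(pv-p))
    tau_inf: float = 1.0e-12
    dU_tau: float = 4.0e-20
    c_vogel: float = 4.0
    p_vogel: float = 1.05

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.noise_mode not in ("additive", "multiplicative"):
            raise ValueError("noise_mode must be additive or multiplicative")

    def tau(self, p, T):
        p = np.asarray(p, dtype=float)
        return (self.tau_inf * np.exp(self.dU_tau / (K_B * T))
                * np.exp(self.c_vogel * p / (self.p_vogel - p)))


def generate_synthetic_isotherms(spec: SyntheticIsothermSpec, rng=None):
    """Integrate the model at each temperature and add measurement noise.

    Returns ``(isotherms, truth)``.  With ``noise = 0`` the tables are an
    exact forward solution of the truth parameters; with a seeded *rng* the
    output is reproducible.  Noisy conversions are monotonized (cumulative
    maximum), matching how cure data are reported.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    isotherms = []
    for T in spec.T_list:
        def rhs(t, y):
            p = min(max(y[0], 0.0), 0.999)
            return [spec.truth.rate(p, T, spec.tau(p, T))]

        def reached(t, y):
            return y[0] - spec.p_stop
        reached.terminal = True
        reached.direction = 1.0

        # generous horizon; the event stops integration at p_stop
        r0 = float(spec.truth.rate(1e-4, T, spec.tau(1e-4, T)))
        t_hi = 50.0 / r0
        sol = solve_ivp(rhs, (0.0, t_hi), [0.0], events=reached,
                        method="LSODA", rtol=1e-10, atol=1e-12,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"isotherm integration failed at T={T}")
        t_end = sol.t_events[0][0] if len(sol.t_events[0]) else sol.t[-1]
        times = np.linspace(0.0, t_end, spec.n_points)
        p = sol.sol(times)[0]
        p = np.clip(p, 0.0, 0.999)
        if spec.noise > 0:
            if spec.noise_mode == "additive":
                p_noisy = p + rng.normal(scale=spec.noise, size=p.shape)
            else:
                p_noisy = p * (1.0 + rng.normal(scale=spec.noise,
                                                size=p.shape))
            p_noisy = np.maximum.accumulate(np.clip(p_noisy, 0.0, 0.999))
        else:
            p_noisy = p
        knots = np.linspace(0.0, min(spec.p_stop + 0.05, 0.99), 25)
        sem = np.full_like(p, max(spec.noise, 1e-6))
        isotherms.append(ExperimentalIsotherm(
            T=float(T), times=times, p=p_noisy,
            tau_p=knots, tau_values=spec.tau(knots, T),
            sem=sem, label=f"synthetic T={T:g}K"))
    return isotherms, spec.truth
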