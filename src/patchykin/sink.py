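"""Growing-sink toy model of the barrier effect.

A partially absorbing sphere (radiation boundary condition) of radius R in a
sea of diffusers at far-field concentration ``c_inf`` captures particles at
the steady-state Smoluchowski rate

    k = 4 pi D R c_inf / (1 + D / (kappa R)),

where the surface reactivity ``kappa = kappa0 exp(-beta dU)`` is suppressed
by an entry barrier.  Because the diffusive supply is not barrier-limited,
the captured flux does not scale as ``exp(-beta dU)``: the ratio
``g = k(p, dU) / [k(p, 0) exp(-beta dU)]`` is always >= 1, growing with the
barrier and saturating as the sink grows (cluster radius
``R(p) = R0 (mass(p))^(1/d_f)`` with a fractal dimension d_f).  This module
reproduces that corrective factor qualitatively; its numbers are internal
to the package, not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["SinkModelParams", "sink_rate", "corrective_factor"]


def _default_radius(p: float) -> float:
    # sink mass grows like the weight-average cluster mass of step growth,
    # 1/(1 - p) pre-gel; radius ~ mass^(1/d_f) with d_f = 2.5
    return (1.0 / max(1.0 - p, 1e-3)) ** (1.0 / 2.5)


@dataclass
class SinkModelParams:
    """Diffuser constant, sink-radius schedule and surface reactivity."""

    D_s: float = 1.0
    kappa0: float = 1.0
    beta_dU: float = 0.0
    c_inf: float = 1.0
    radius: Callable[[float], float] = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.D_s <= 0 or self.kappa0 <= 0 or self.c_inf <= 0:
            raise ValueError("D_s, kappa0 and c_inf must be positive")
        if self.beta_dU < 0:
            raise ValueError("beta_dU must be >= 0")
        if self.radius is None:
            self.radius = _default_radius


def sink_rate(params: SinkModelParams, p: float) -> float:
    """Steady-state adsorption rate of the radiation-boundary sphere.

    Recovers the absorbing Smoluchowski limit ``4 pi D R c_inf`` as
    ``kappa -> inf`` and the reaction-limited ``4 pi R^2 kappa c_inf`` as
    ``D -> inf``.
    """
    R = params.radius(p)
    if R <= 0:
        raise ValueError("sink radius must be positive")
    kappa = params.kappa0 * np.exp(-params.beta_dU)
    return 4.0 * np.pi * params.D_s * R * params.c_inf / (
        1.0 + params.D_s / (kappa * R))


def corrective_factor(params: SinkModelParams, p: float) -> float:
    """g = k(p, dU) / [k(p, 0) exp(-beta dU)] >= 1.

    Equals 1 exactly at zero barrier, increases with the barrier, and
    saturates as the growing sink becomes diffusion-limited.
    """
    barrier = sink_rate(params, p)
    free = sink_rate(
        SinkModelParams(D_s=params.D_s, kappa0=params.kappa0, beta_dU=0.0,
                        c_inf=params.c_inf, radius=params.radius), p)
    return float(barrier / (free * np.exp(-params.beta_dU)))
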