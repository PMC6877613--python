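"""Intracellular chemotaxis signalling model.

Maps the ligand concentration time series experienced by a swimming cell to
its instantaneous tumble rate, through a Monod-Wyman-Changeux receptor
cluster with linear methylation adaptation kinetics and a steep (Hill-type)
motor response acting on the receptor activity.

All functions accept scalar or ndarray methylation/concentration inputs and
broadcast, so the simulator can advance a whole population in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "PathwayParams",
    "PathwayState",
    "ligand_free_energy",
    "receptor_activity",
    "adapted_methylation",
    "tumble_rate",
    "update_state",
    "effective_parameters",
    "total_gain",
]


@dataclass(frozen=True)
class PathwayParams:
    """Constants of the signalling cascade.

    Defaults are standard literature values for the Tar/MeAsp system; the
    adapted activity is ``a_ss = k_R / (k_R + k_B)`` and ``eps0`` is chosen
    (see :func:`default_eps0`) so the adapted methylation level at the
    mid-gradient concentration of 100 uM sits in the middle of ``m_range``.
    """

    N: float = 6.0                 # receptor cluster size
    K_off: float = 20.0            # inactive-state dissociation constant (uM)
    K_on: float = 500.0            # active-state dissociation constant (uM)
    eps1: float = 0.5              # free energy per methyl group (kT)
    eps0: float | None = None      # methylation offset; None -> auto
    k_R: float = 0.0069            # methylation rate (1/s)
    k_B: float = 0.0138            # demethylation rate (1/s)
    m_max: float = 8.0             # methylation range [0, m_max]
    H: float = 10.0                # motor Hill exponent
    lambda0: float = 1.0           # steady-state tumble initiation rate (1/s)
    tau_t: float = 0.12            # tumble duration (s)
    c_adapt: float = 100.0         # concentration used to pin eps0 (uM)

    def __post_init__(self) -> None:
        if not (self.K_on > self.K_off > 0):
            raise ValueError("require K_on > K_off > 0")
        if self.k_R <= 0 or self.k_B <= 0:
            raise ValueError("methylation rates must be positive")
        if self.H < 1:
            raise ValueError("motor Hill exponent must be >= 1")
        if self.eps0 is None:
            object.__setattr__(self, "eps0", default_eps0(self))

    @property
    def a_ss(self) -> float:
        """Adapted receptor activity, set by the methylation kinetics."""
        return self.k_R / (self.k_R + self.k_B)


def default_eps0(params: PathwayParams) -> float:
    """Offset putting the adapted state at ``m = m_max/2`` for ``c_adapt``.

    Solves ``a(m_max/2, c_adapt) = a_ss`` for ``eps0``.
    """
    a_ss = params.k_R / (params.k_R + params.k_B)
    f_ad = ligand_free_energy(params.c_adapt, params, _validate=False)
    return (
        params.eps1 * params.m_max / 2.0
        - f_ad
        + np.log(1.0 / a_ss - 1.0) / params.N
    )


@dataclass
class PathwayState:
    """Per-cell signalling state."""

    m: np.ndarray | float          # methylation level
    a: np.ndarray | float          # receptor activity in [0, 1]
    lam: np.ndarray | float        # current tumble initiation rate (1/s)


def ligand_free_energy(c, params: PathwayParams, _validate: bool = True):
    """Ligand-binding part of the receptor free energy (kT units).

    ``f(c) = ln[(1 + c/K_off) / (1 + c/K_on)]``; monotone increasing in c
    and bounded by ``ln(K_on/K_off)``.
    """
    c = np.asarray(c, dtype=float)
    if _validate:
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite concentration")
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
    out = np.log1p(c / params.K_off) - np.log1p(c / params.K_on)
    return out if out.ndim else float(out)


def receptor_activity(m, c, params: PathwayParams):
    """MWC receptor-cluster activity ``a in [0, 1]``.

    ``a = 1 / (1 + exp(N [eps0 - eps1 m + f(c)]))``: attractant binding
    (f up) lowers activity, methylation raises it.
    """
    m = np.asarray(m, dtype=float)
    E = params.N * (params.eps0 - params.eps1 * m + ligand_free_energy(c, params))
    out = 1.0 / (1.0 + np.exp(E))
    return out if out.ndim else float(out)


def adapted_methylation(c, params: PathwayParams):
    """Methylation level at which activity equals ``a_ss`` for ambient c."""
    f = ligand_free_energy(c, params)
    target = np.log(1.0 / params.a_ss - 1.0) / params.N
    m = (params.eps0 + f - target) / params.eps1
    return np.clip(m, 0.0, params.m_max)


def tumble_rate(a, params: PathwayParams):
    """Motor response: ``lambda = lambda0 (a / a_ss)^H``."""
    return params.lambda0 * (np.asarray(a, dtype=float) / params.a_ss) ** params.H


def update_state(state: PathwayState, c, dt: float, params: PathwayParams) -> PathwayState:
    """One explicit Euler step of the adaptation dynamics.

    ``dm/dt = k_R (1 - a) - k_B a`` (exact adaptation: the fixed point has
    ``a = a_ss`` independent of c), then activity and tumble rate are
    refreshed at the new methylation level.
    """
    if dt > 0.05:
        raise ValueError("pathway integration requires dt <= 0.05 s")
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite concentration")
    a = receptor_activity(state.m, c, params)
    m = state.m + dt * (params.k_R * (1.0 - a) - params.k_B * a)
    m = np.clip(m, 0.0, params.m_max)
    a_new = receptor_activity(m, c, params)
    return PathwayState(m=m, a=a_new, lam=tumble_rate(a_new, params))


def adaptation_time(params: PathwayParams) -> float:
    """Analytic linearized memory time about the adapted state.

    ``tau_m = 1 / [N eps1 a_ss (1 - a_ss) (k_R + k_B)]``.
    """
    a = params.a_ss
    return 1.0 / (params.N * params.eps1 * a * (1.0 - a) * (params.k_R + params.k_B))


def effective_parameters(
    params: PathwayParams,
    D_r: float = 0.057,
    D_T: float = 5.3,
    dt: float = 0.01,
    f_step: float = 1e-3,
) -> Tuple[float, float, float]:
    """Timescales (tau_m, tau_T, tau_R) entering the drift theory.

    tau_m is measured numerically as the e-folding time of the activity
    response to a small step of the ligand free energy, starting from the
    adapted state (the analytic linearization is kept as a test oracle).
    tau_T = (1/lambda0) / (1 - exp(-D_T tau_t)) converts the tumble rate
    into a directional decorrelation time using the mean squared angular
    change during a tumble; tau_R = 1/D_r.
    """
    # simulate the activity relaxation after a sudden f-step, delivered as a
    # concentration step computed by inverting f(c) locally
    c0 = params.c_adapt
    f0 = ligand_free_energy(c0, params)
    # find c1 with f(c1) = f0 + f_step by bisection (f is monotone)
    lo, hi = c0, c0 * 10.0
    while ligand_free_energy(hi, params) < f0 + f_step:
        hi *= 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ligand_free_energy(mid, params) < f0 + f_step:
            lo = mid
        else:
            hi = mid
    c1 = 0.5 * (lo + hi)

    m0 = float(adapted_methylation(c0, params))
    a_ss = params.a_ss
    dev0 = abs(float(receptor_activity(m0, c1, params)) - a_ss)
    target = dev0 / np.e
    state = PathwayState(m=m0, a=receptor_activity(m0, c1, params),
                         lam=params.lambda0)
    t = 0.0
    t_max = 100.0 * adaptation_time(params)
    tau_m = np.nan
    prev_t, prev_dev = 0.0, dev0
    while t < t_max:
        state = update_state(state, c1, dt, params)
        t += dt
        dev = abs(float(state.a) - a_ss)
        if dev <= target:
            frac = (prev_dev - target) / max(prev_dev - dev, 1e-300)
            tau_m = prev_t + frac * (t - prev_t)
            break
        prev_t, prev_dev = t, dev
    tau_T = (1.0 / params.lambda0) / (1.0 - np.exp(-D_T * params.tau_t))
    tau_R = 1.0 / D_r
    return float(tau_m), float(tau_T), float(tau_R)


def total_gain(params: PathwayParams, dim: int = 2) -> float:
    """Total pathway gain G of the drift relation v_ch = G v0^2 tau grad-f.

    Linearizing the cascade about the adapted state, the logarithmic tumble
    rate response to a free-energy perturbation is ``H N (1 - a_ss)``; the
    projection of swimming on the gradient contributes the mean squared
    direction cosine 1/dim (1/2 in two dimensions, 1/3 in three).
    """
    return params.H * params.N * (1.0 - params.a_ss) / dim
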