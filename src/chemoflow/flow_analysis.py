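"""Collective-flow and chemotaxis statistics.

Coarse-grained velocity fields, the velocity-normalized kinetic energy
spectrum E(q) whose peak identifies the dominant eddy size pi/q, spectral
peak / background-corrected amplitude analysis, velocity autocorrelations
and the 0.5-crossing decorrelation time, chemotactic drift statistics, and
the analytic drift theory connecting them.

Spectrum normalization convention: E is binned so that ``sum E(q) dq = 1``
exactly (discrete Parseval), with ``dq = 2 pi / box_side``; only relative
and peak structure is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VelocityField",
    "FlowSpectrum",
    "PeakResult",
    "AutocorrResult",
    "DriftResult",
    "TheoryParams",
    "coarse_grain_velocity",
    "flow_structure_factor",
    "peak_analysis",
    "velocity_autocorrelation",
    "chemotactic_drift",
    "sensing_time",
    "predicted_coefficient",
]

NO_CROSSING = -1.0  # sentinel tau_dec when C_v never reaches 0.5


@dataclass
class VelocityField:
    """Gridded 2D flow sampled on one or more frames."""

    u: np.ndarray                  # (T, ny, nx, 2) um/s
    spacing: float                 # um
    times: np.ndarray              # (T,)
    weights: Optional[np.ndarray] = None  # (T, ny, nx) occupancy weights

    def __post_init__(self) -> None:
        if self.u.ndim == 3:
            self.u = self.u[None]
        if not np.all(np.isfinite(self.u)):
            raise ValueError("velocity field contains non-finite values")

    @property
    def A0(self) -> float:
        """Field-of-view area (um^2)."""
        return self.u.shape[1] * self.u.shape[2] * self.spacing**2

    @property
    def mean_square_speed(self) -> float:
        """<v^2> over occupied nodes (all nodes when no weights given)."""
        v2 = np.sum(self.u**2, axis=-1)
        if self.weights is None:
            return float(v2.mean())
        occ = self.weights > 0
        return float(v2[occ].mean()) if occ.any() else 0.0


@dataclass
class FlowSpectrum:
    q: np.ndarray                  # wavenumbers (um^-1), multiples of dq
    E: np.ndarray                  # structure factor (um)
    dq: float
    n_frames: int


@dataclass
class PeakResult:
    q_max: float
    E_at_max: float
    q_str: float
    deltaE: float
    vortex_size: float             # pi / q_str
    edge_flagged: bool = False


@dataclass
class AutocorrResult:
    lags: np.ndarray
    C_v: np.ndarray
    tau_dec: float                 # NO_CROSSING when C_v stays above 0.5


@dataclass
class DriftResult:
    v_ch: float                    # drift corrected for non-motile fraction
    v0: float                      # mean instantaneous speed
    coefficient: float             # v_ch / v0^2 (s/um)
    alpha: float


@dataclass
class TheoryParams:
    """Inputs of the analytic chemotactic drift relations."""

    G: float                       # total pathway gain
    tau_m: float
    tau_R: float
    tau_T: float
    grad_f: float                  # gradient of the ligand free energy (1/um)
    tau_0: float = 1.0
    D_T: float = 5.3
    tau_t: float = 0.12


# ---------------------------------------------------------------------------

def coarse_grain_velocity(trajectories, grid_spacing: float = 2.0,
                          kernel_sigma: float = 2.5,
                          frames: Optional[slice] = None) -> VelocityField:
    """Gaussian-kernel average of rod velocities on a regular grid.

    Periodic in both directions; nodes with zero kernel weight get zero
    velocity and are excluded from the occupancy weights.
    """
    box = trajectories.config.box_side
    n_nodes = int(round(box / grid_spacing))
    if n_nodes < 2:
        raise ValueError("grid too coarse")
    sel = frames if frames is not None else slice(None)
    pos = trajectories.positions[sel]
    vel = trajectories.velocity[sel]
    T, n, _ = pos.shape
    reach = int(np.ceil(3.0 * kernel_sigma / grid_spacing))
    u = np.zeros((T, n_nodes, n_nodes, 2))
    w = np.zeros((T, n_nodes, n_nodes))
    gx = pos[..., 0] / grid_spacing
    gy = pos[..., 1] / grid_spacing
    i0 = np.floor(gx).astype(int)
    j0 = np.floor(gy).astype(int)
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            ii = (i0 + di) % n_nodes
            jj = (j0 + dj) % n_nodes
            dxu = (i0 + di) - gx
            dyu = (j0 + dj) - gy
            d2 = (dxu**2 + dyu**2) * grid_spacing**2
            ker = np.exp(-d2 / (2.0 * kernel_sigma**2))
            tgrid = np.broadcast_to(np.arange(T)[:, None], (T, n))
            np.add.at(w, (tgrid, ii, jj), ker)
            np.add.at(u, (tgrid, ii, jj, np.zeros_like(ii)), ker * vel[..., 0])
            np.add.at(u, (tgrid, ii, jj, np.ones_like(ii)), ker * vel[..., 1])
    occ = w > 1e-12
    u[occ] /= w[occ][:, None]
    u[~occ] = 0.0
    times = np.asarray(trajectories.times)[sel]
    return VelocityField(u=u, spacing=grid_spacing, times=times, weights=w)


def flow_structure_factor(field: VelocityField) -> FlowSpectrum:
    """Velocity-normalized kinetic energy spectrum E(q).

    E(q) is the annularly binned power of the velocity Fourier transform,
    normalized so that ``sum E dq = 1`` exactly; the q = 0 bin carries the
    mean-flow power.
    """
    u = field.u
    T, ny, nx, _ = u.shape
    if nx != ny:
        raise ValueError("square fields only")
    v2_total = float(np.sum(u**2))
    if v2_total == 0.0:
        raise ValueError("all-zero velocity field: <v^2> = 0")
    dq = 2.0 * np.pi / (nx * field.spacing)
    qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=field.spacing)
    QX, QY = np.meshgrid(qx, qx, indexing="ij")
    qmag = np.hypot(QX, QY)
    bins = np.round(qmag / dq).astype(int)
    n_bins = nx // 2 + 1
    power = np.zeros(n_bins)
    for t in range(T):
        for c in range(2):
            p = np.abs(np.fft.fft2(u[t, :, :, c]))**2
            power += np.bincount(bins.ravel(), weights=p.ravel(),
                                 minlength=bins.max() + 1)[:n_bins]
    # exact normalization over the retained bins
    E = power / (power.sum() * dq)
    q = dq * np.arange(n_bins)
    return FlowSpectrum(q=q, E=E, dq=dq, n_frames=T)


def peak_analysis(spectrum: FlowSpectrum,
                  baseline: Optional[FlowSpectrum] = None,
                  q_str: Optional[float] = None) -> PeakResult:
    """Locate the spectral peak and its background-corrected amplitude.

    The q = 0 and q = dq bins are excluded from the peak search.  ``q_str``
    defaults to the peak location of this spectrum; for a density sweep it
    should be frozen from the densest member and passed in.  The baseline
    defaults to a flat noise floor estimated from the upper third of the
    q range.
    """
    E = spectrum.E
    q = spectrum.q
    lo = 2  # skip q = 0 and q = dq
    i_max = lo + int(np.argmax(E[lo:]))
    edge = i_max in (lo, len(E) - 1) and bool(
        np.all(np.diff(E[lo:]) <= 0) or np.all(np.diff(E[lo:]) >= 0))
    if q_str is None:
        q_str = q[i_max]
    i_str = int(round(q_str / spectrum.dq))
    if baseline is not None:
        if len(baseline.E) != len(E):
            raise ValueError("baseline spectrum has a different q grid")
        e_base = baseline.E[i_str]
    else:
        e_base = float(np.mean(E[2 * len(E) // 3:]))
    return PeakResult(q_max=q[i_max], E_at_max=float(E[i_max]),
                      q_str=float(q[i_str]), deltaE=float(E[i_str] - e_base),
                      vortex_size=float(np.pi / q[i_str]), edge_flagged=edge)


def velocity_autocorrelation(trajectories, use_free_velocity: bool = True,
                             max_lag: Optional[float] = None) -> AutocorrResult:
    """Population-mean velocity autocorrelation and its 0.5-crossing.

    ``use_free_velocity=True`` correlates the propulsion vector v_i n_i
    (the printed definition); otherwise the recorded full instantaneous
    velocities are used.
    """
    t = np.asarray(trajectories.times)
    if len(t) < 100:
        raise ValueError("need at least 100 time samples")
    if use_free_velocity:
        v = trajectories.v_i[None, :, None] * np.stack(
            [np.cos(trajectories.theta), np.sin(trajectories.theta)], axis=-1)
    else:
        v = trajectories.velocity
    T = v.shape[0]
    nfft = 2 ** int(np.ceil(np.log2(2 * T)))
    fv = np.fft.rfft(v.astype(np.float64), n=nfft, axis=0)
    power = np.sum(np.abs(fv)**2, axis=(1, 2))  # over rods and components
    acf = np.fft.irfft(power, n=nfft)[:T]
    acf /= (T - np.arange(T))                # unbiased lag normalization
    C = acf / acf[0]
    dt = t[1] - t[0]
    if max_lag is not None:
        keep = min(T, int(round(max_lag / dt)) + 1)
    else:
        keep = max(2, T // 2)
    lags = np.arange(keep) * dt
    C = C[:keep]
    below = np.flatnonzero(C < 0.5)
    if len(below) == 0:
        import warnings
        warnings.warn("C_v never crossed 0.5 within the available lags")
        tau = NO_CROSSING
    else:
        i = below[0]
        if i == 0:
            tau = 0.0
        else:
            frac = (C[i - 1] - 0.5) / (C[i - 1] - C[i])
            tau = float(lags[i - 1] + frac * dt)
    return AutocorrResult(lags=lags, C_v=C, tau_dec=tau)


def chemotactic_drift(trajectories, alpha: float = 1.0,
                      transient: float = 20.0) -> DriftResult:
    """Up-gradient drift statistics from unwrapped x positions.

    v_d = mean d(unwrapped_x)/dt over rods and time after discarding the
    transient; v_ch = v_d / alpha; the coefficient is v_ch / v0^2 with v0
    the mean instantaneous speed.
    """
    if alpha <= 0 or alpha > 1:
        raise ValueError("alpha must lie in (0, 1]")
    t = np.asarray(trajectories.times)
    keep = t >= transient
    if keep.sum() < 2:
        raise ValueError("transient leaves fewer than 2 samples")
    ts = t[keep]
    xs = trajectories.unwrapped_x[keep]
    v_d = float((xs[-1] - xs[0]).mean() / (ts[-1] - ts[0]))
    v_ch = v_d / alpha
    speed = np.linalg.norm(trajectories.velocity[keep], axis=-1)
    v0 = float(speed.mean())
    return DriftResult(v_ch=v_ch, v0=v0, coefficient=v_ch / v0**2, alpha=alpha)


# ---------------------------------------------------------------------------
# analytic theory
# ---------------------------------------------------------------------------

def sensing_time(tau_m: float, tau_T: float, tau_R: float) -> float:
    """Directional sensing time combining memory and reorientation times.

    tau = [tau_R/(tau_R+tau_T)] * [tau_T/(1 + tau_T/tau_R + tau_T/tau_m)].
    """
    if min(tau_m, tau_T, tau_R) <= 0:
        raise ValueError("all time scales must be positive")
    return (tau_R / (tau_R + tau_T)) \
        * (tau_T / (1.0 + tau_T / tau_R + tau_T / tau_m))


def predicted_coefficient(theory: TheoryParams,
                          tau_dec: Optional[float] = None) -> float:
    """Theoretical chemotactic coefficient v_ch / v0^2 (s/um).

    Without ``tau_dec``: G tau grad_f with tau from :func:`sensing_time`.
    With a measured decorrelation time: the equivalent form
    (tau_dec^2/tau_T) / (1 + tau_dec/tau_m) G grad_f, which reduces to the
    former exactly when tau_dec = tau_R tau_T / (tau_R + tau_T).
    """
    if tau_dec is None:
        tau = sensing_time(theory.tau_m, theory.tau_T, theory.tau_R)
        return theory.G * tau * theory.grad_f
    return (tau_dec**2 / theory.tau_T) / (1.0 + tau_dec / theory.tau_m) \
        * theory.G * theory.grad_f
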