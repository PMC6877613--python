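"""Image-based motility measurements in Fourier space.

Differential dynamic microscopy (DICF computation and swimmer-ISF fitting),
global and local phase-differential velocimetry (the phase of frame-to-frame
Fourier correlators, accumulated over time, is fitted as q . r to give
sub-pixel displacements), the q-range and confinement calibrations of the
speed measurement, and the DDM-amplitude to cell volume fraction
calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as spfft
from scipy.optimize import curve_fit

from .flow_analysis import VelocityField

__all__ = [
    "ImageStack",
    "DICF",
    "ISFFit",
    "VelocimetryConfig",
    "DensityCalibration",
    "compute_dicf",
    "swimmer_isf",
    "fit_dicf",
    "select_q_range",
    "confinement_correction",
    "amplitude_to_volume_fraction",
    "local_velocimetry",
    "phase_diff_drift",
]


@dataclass
class ImageStack:
    """Timed grayscale frames; the common currency of the Fourier layer."""

    frames: np.ndarray             # (T, H, W)
    px_size: float = 1.4           # um
    frame_rate: float = 100.0      # 1/s

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (T >= 2, H, W) stack")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite intensities")

    @property
    def mean_intensity(self) -> float:
        return float(self.frames.mean())

    def save_tiff(self, path) -> None:
        from .io import stack_to_tiff
        stack_to_tiff(self, path)

    @classmethod
    def load_tiff(cls, path, px_size=1.4, frame_rate=100.0) -> "ImageStack":
        from .io import stack_from_tiff
        return stack_from_tiff(path, px_size, frame_rate)


@dataclass
class DICF:
    """Differential image correlation function g(q, tau)."""

    q_px: np.ndarray               # annulus wavenumbers (1/px)
    q_um: np.ndarray               # same in 1/um
    lags: np.ndarray               # (s)
    g: np.ndarray                  # (n_q, n_lags)
    a0: np.ndarray                 # small-lag estimate per q
    a1: np.ndarray                 # plateau-amplitude estimate per q
    mean_intensity: float


@dataclass
class ISFFit:
    """Swimming parameters extracted from a DICF."""

    v0: float                      # um/s, aggregated over the fit q-range
    alpha: float
    D: float                       # um^2/s
    Z: float
    q_range_px: Tuple[float, float]
    v0_q: np.ndarray               # per-q fitted speeds (um/s)
    alpha_q: np.ndarray
    D_q: np.ndarray
    Z_q: np.ndarray
    q_fit_px: np.ndarray
    residual_rms: float

    @property
    def sigma_v(self) -> float:
        return self.v0 / np.sqrt(self.Z + 1.0)


@dataclass(frozen=True)
class VelocimetryConfig:
    """Parameters of the local phase-differential velocimetry."""

    a: int = 32                    # submovie window (px), power of two
    da: int = 4                    # lattice spacing (px)
    l: float = 3.0                 # Gaussian localization range (px)
    fit_window: int = 20           # frames for the velocity fit
    # phase-fit support: the Gaussian localization mixes modes over a range
    # ~sqrt(2)/l in q, so a support much wider than that is needed for an
    # unbiased displacement fit; the anti-wrap condition correspondingly
    # requires displacements below pi/q_fit_max ~ 1.4 px per frame
    q_fit_max: float = 2.2         # (1/px)

    def __post_init__(self) -> None:
        if self.a & (self.a - 1) != 0:
            raise ValueError("window a must be a power of two")
        if self.da > self.a:
            raise ValueError("da must not exceed a")
        if not self.l < self.a / 2:
            raise ValueError("localization range must be < a/2")


@dataclass(frozen=True)
class DensityCalibration:
    """DDM amplitude -> optical density -> cell body volume fraction."""

    m: float                       # logistic constant (per OD unit)
    d0: float = 1.25               # saturation of a1_max/<I>^2
    od_to_phi: float = 1.78e-3     # volume fraction per OD600
    r: float = 0.5                 # cell radius (um)
    L: float = 2.0                 # cell length (um)

    def __post_init__(self) -> None:
        if self.m <= 0 or self.d0 <= 0 or self.od_to_phi <= 0:
            raise ValueError("calibration constants must be positive")


# ---------------------------------------------------------------------------
# DDM
# ---------------------------------------------------------------------------

def default_lags(n_frames: int, n_lags: int = 30) -> np.ndarray:
    """30 log-spaced integer frame lags from 1 to T/10."""
    hi = max(2, n_frames // 10)
    lags = np.unique(np.round(np.logspace(0, np.log10(hi), n_lags)).astype(int))
    return lags[lags >= 1]


def compute_dicf(stack: ImageStack, lags: Optional[Sequence[int]] = None,
                 max_t_samples: int = 60) -> DICF:
    """g(q, tau) = <|I~(q, t+tau) - I~(q, t)|^2> over t and the annulus.

    ``lags`` are integer frame separations (default log-spaced up to T/10);
    for each lag at most ``max_t_samples`` evenly spaced start frames enter
    the time average.
    """
    frames = stack.frames
    T, H, W = frames.shape
    if H != W:
        raise ValueError("square frames only")
    if lags is None:
        lag_arr = default_lags(T)
    else:
        lag_arr = np.asarray(sorted(set(int(l) for l in lags)))
    if lag_arr.max() > T - 1:
        raise ValueError("largest lag exceeds the stack length")

    # scipy's FFT keeps float32 input in complex64, halving the cache that
    # dominates the memory budget for long stacks; shape (T, H, W//2+1)
    fts = spfft.rfft2(frames.astype(np.float32, copy=False), axes=(-2, -1))
    kx = np.fft.fftfreq(H) * 2.0 * np.pi
    ky = np.fft.rfftfreq(W) * 2.0 * np.pi
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    qmag = np.hypot(KX, KY)
    dq = 2.0 * np.pi / H
    bins = np.round(qmag / dq).astype(int)
    # rfft halves the spectrum: double-count interior columns
    mult = np.full(bins.shape, 2.0)
    mult[:, 0] = 1.0
    if W % 2 == 0:
        mult[:, -1] = 1.0
    n_bins = H // 2 + 1
    flat_bins = bins.ravel()
    flat_mult = mult.ravel()
    counts = np.bincount(flat_bins, weights=flat_mult, minlength=n_bins)[:n_bins]

    g = np.empty((n_bins, len(lag_arr)))
    for il, lag in enumerate(lag_arr):
        starts = np.unique(np.linspace(0, T - 1 - lag,
                                       min(max_t_samples, T - lag)).astype(int))
        acc = np.zeros(n_bins)
        for s in starts:
            diff = fts[s + lag] - fts[s]
            p = (diff.real**2 + diff.imag**2).ravel() * flat_mult
            acc += np.bincount(flat_bins, weights=p, minlength=n_bins)[:n_bins]
        g[:, il] = acc / (len(starts) * np.maximum(counts, 1)) / (H * W)
    q_px = dq * np.arange(n_bins)
    a0 = g[:, 0].copy()
    a1 = np.maximum(g[:, -3:].mean(axis=1) - a0, 0.0)
    lag_times = lag_arr / stack.frame_rate
    dicf = DICF(q_px=q_px, q_um=q_px / stack.px_size, lags=lag_times, g=g,
                a0=a0, a1=a1, mean_intensity=stack.mean_intensity)
    return dicf


def swimmer_isf(q, tau, v0: float, Z: float, D: float, alpha: float):
    """Intermediate scattering function of a 3D isotropic swimmer mix.

    f(q,tau) = exp(-D q^2 tau) [ (1-alpha)
               + alpha ((Z+1)/(Z q v0 tau)) sin(Z arctan(lam)) /
                 (1+lam^2)^{Z/2} ],   lam = q v0 tau / (Z+1)

    The tau -> 0 limit is 1 (handled analytically).  ``q`` in 1/um, ``tau``
    in s.  The printed variant with sin(Z^-1 arctan lam) does not satisfy
    f(q, 0) = 1; the standard Schulz-ISF argument Z arctan(lam) is used.
    """
    q = np.asarray(q, dtype=float)
    tau = np.asarray(tau, dtype=float)
    x = q * v0 * tau
    lam = x / (Z + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        envelope = np.exp(-0.5 * Z * np.log1p(lam**2))
        swim = np.where(
            x > 1e-8,
            ((Z + 1.0) / (Z * np.where(x > 1e-8, x, 1.0)))
            * np.sin(Z * np.arctan(lam)) * envelope,
            1.0 - x**2 * (Z + 2.0) / (Z + 1.0) / 6.0,
        )
    out = np.exp(-D * q**2 * tau) * ((1.0 - alpha) + alpha * swim)
    return out if out.ndim else float(out)


def _dicf_model(tau, a0, a1, v0, Z, D, alpha, q):
    return a0 + a1 * (1.0 - swimmer_isf(q, tau, v0, Z, D, alpha))


def fit_dicf(dicf: DICF, q_range_px: Tuple[float, float] = (0.4, 2.0),
             p0: Optional[dict] = None, max_fail_frac: float = 0.3) -> ISFFit:
    """Per-q nonlinear least squares of the DICF against the swimmer model.

    a0 is initialized from the smallest-lag g and a1 from the large-lag
    plateau; physical bounds are v0 in [2, 100] um/s, Z in [0.5, 500],
    D in [0, 5] um^2/s, alpha in [0, 1].  Aggregated speed and motile
    fraction are means over the converged q bins in the fit range.
    """
    guesses = {"v0": 15.0, "Z": 3.0, "D": 0.5, "alpha": 0.7}
    if p0:
        guesses.update(p0)
    sel = np.flatnonzero((dicf.q_px >= q_range_px[0])
                         & (dicf.q_px <= q_range_px[1]))
    if len(sel) == 0:
        raise ValueError("q range contains no annuli")
    lo = [0.0, 0.0, 2.0, 0.5, 0.0, 0.0]
    hi = [np.inf, np.inf, 100.0, 500.0, 5.0, 1.0]
    rows = {k: [] for k in ("v0", "Z", "D", "alpha", "q", "res")}
    n_fail = 0
    for i in sel:
        q_um = dicf.q_um[i]
        y = dicf.g[i]
        a0g = max(dicf.a0[i], 1e-12)
        a1g = max(dicf.a1[i], 1e-12)
        try:
            popt, _ = curve_fit(
                lambda tau, a0, a1, v0, Z, D, alpha: _dicf_model(
                    tau, a0, a1, v0, Z, D, alpha, q_um),
                dicf.lags, y,
                p0=[a0g, a1g, guesses["v0"], guesses["Z"], guesses["D"],
                    guesses["alpha"]],
                bounds=(lo, hi), maxfev=4000)
        except RuntimeError:
            n_fail += 1
            continue
        # a fit pinned at the parameter bounds is a failed annulus (usually
        # a noise-dominated bin where the PSF has destroyed the signal)
        if (popt[1] <= 10 * a0g * 1e-9 or popt[2] <= 2.01 or popt[2] >= 99.0
                or popt[5] <= 1e-3):
            n_fail += 1
            continue
        resid = y - _dicf_model(dicf.lags, *popt, q_um)
        rows["v0"].append(popt[2])
        rows["Z"].append(popt[3])
        rows["D"].append(popt[4])
        rows["alpha"].append(popt[5])
        rows["q"].append(dicf.q_px[i])
        rows["res"].append(np.sqrt(np.mean(resid**2)) / max(popt[1], 1e-12))
    if n_fail > max_fail_frac * len(sel):
        raise RuntimeError(
            f"DICF fit failed on {n_fail}/{len(sel)} q bins "
            f"(q range {q_range_px} px^-1)")
    v0q = np.array(rows["v0"])
    return ISFFit(
        v0=float(v0q.mean()), alpha=float(np.mean(rows["alpha"])),
        D=float(np.median(rows["D"])), Z=float(np.median(rows["Z"])),
        q_range_px=q_range_px, v0_q=v0q, alpha_q=np.array(rows["alpha"]),
        D_q=np.array(rows["D"]), Z_q=np.array(rows["Z"]),
        q_fit_px=np.array(rows["q"]), residual_rms=float(np.mean(rows["res"])))


def select_q_range(L: float) -> Tuple[float, float]:
    """Fit q-range (px^-1) by cell length: shape anisotropy caps q for
    elongated cells."""
    if np.isclose(L, 2.0):
        return (0.4, 2.0)
    if np.isclose(L, 4.0):
        return (0.4, 0.9)
    warnings.warn(f"no calibrated q range for L = {L}; "
                  "using the conservative elongated-cell range")
    return (0.4, 0.9)


_CONFINEMENT_FACTORS = {50: 1.0, 30: 1.075, 8: 1.14}


def confinement_correction(v0_fitted: float, h: float) -> float:
    """Undo the apparent speed-up of the 3D ISF fit under confinement."""
    key = int(round(h))
    if key not in _CONFINEMENT_FACTORS:
        raise ValueError(f"no confinement calibration for h = {h} um")
    return v0_fitted / _CONFINEMENT_FACTORS[key]


def amplitude_to_volume_fraction(a1_max_norm: float,
                                 calib: DensityCalibration,
                                 n_c: Optional[float] = None) -> float:
    """Cell body volume fraction from the normalized DDM amplitude.

    Inverts a1_max/<I>^2 = d0 m OD / (1 + m OD) and applies the linear
    OD -> volume fraction calibration; alternatively, a direct number
    density ``n_c`` (1/um^3) gives pi r^2 L n_c.
    """
    if n_c is not None:
        return np.pi * calib.r**2 * calib.L * n_c
    if a1_max_norm < 0:
        raise ValueError("amplitude must be >= 0")
    if a1_max_norm >= calib.d0:
        raise ValueError("amplitude at or above saturation d0")
    od = a1_max_norm / (calib.m * (calib.d0 - a1_max_norm))
    return calib.od_to_phi * od


# ---------------------------------------------------------------------------
# phase-differential velocimetry
# ---------------------------------------------------------------------------

def _phase_displacements(Z_modes: np.ndarray, qvecs: np.ndarray,
                         weights: np.ndarray) -> np.ndarray:
    """Cumulated displacements from per-frame phase increments.

    Z_modes: (..., T, M) complex mode amplitudes; qvecs (M, 2); weights
    (..., M).  Returns (..., T, 2) displacements in px, with r(0) = 0.
    """
    # with the e^{-i q r} transform convention a displacement +d multiplies
    # modes by e^{-i q d}; conjugating the later frame makes phi = +q . d
    corr = np.conj(Z_modes[..., 1:, :]) * Z_modes[..., :-1, :]
    dphi = np.angle(corr)
    phi = np.cumsum(dphi, axis=-2)
    T = Z_modes.shape[-2]
    phi = np.concatenate([np.zeros_like(phi[..., :1, :]), phi], axis=-2)
    w = weights[..., None, :]
    Sxx = np.sum(weights * qvecs[:, 0]**2, axis=-1)
    Sxy = np.sum(weights * qvecs[:, 0] * qvecs[:, 1], axis=-1)
    Syy = np.sum(weights * qvecs[:, 1]**2, axis=-1)
    bx = np.sum(w * phi * qvecs[:, 0], axis=-1)
    by = np.sum(w * phi * qvecs[:, 1], axis=-1)
    det = Sxx * Syy - Sxy**2
    det = np.where(det == 0, 1.0, det)
    rx = (Syy[..., None] * bx - Sxy[..., None] * by) / det[..., None]
    ry = (Sxx[..., None] * by - Sxy[..., None] * bx) / det[..., None]
    return np.stack([rx, ry], axis=-1)


def _sliding_slopes(r: np.ndarray, window: int, dt: float) -> np.ndarray:
    """OLS slope of r(t) over a centred window, truncated at the ends."""
    T = r.shape[-2]
    out = np.empty_like(r)
    half = window // 2
    for t in range(T):
        lo = max(0, t - half)
        hi = min(T, t + half + 1)
        tt = (np.arange(lo, hi) - (lo + hi - 1) / 2.0) * dt
        denom = np.sum(tt**2)
        seg = r[..., lo:hi, :]
        out[..., t, :] = np.sum(seg * tt[:, None], axis=-2) / denom
    return out


def local_velocimetry(stack: ImageStack,
                      config: VelocimetryConfig = VelocimetryConfig()
                      ) -> VelocityField:
    """Local velocity field time series by windowed phase tracking.

    At each lattice point (spacing ``da``, margin ``a/2``) a Gaussian
    envelope of range ``l`` localizes the windowed DFT; the phase of the
    frame-to-frame correlator is accumulated and fitted as q . r with
    spectral weights |I|^2, and velocities follow from a sliding linear
    fit of r(t).  The anti-wrap condition is a displacement per frame
    below pi / q_fit_max.
    """
    frames = stack.frames
    T, H, W = frames.shape
    a = config.a
    if a > min(H, W):
        raise ValueError("window exceeds the frame")
    # the static background leaks through the Gaussian localization into
    # the fit modes and biases the correlator phases toward zero; removing
    # each frame's scalar mean eliminates the static uniform component
    # without mixing time points
    frames = frames - frames.mean(axis=(1, 2), keepdims=True)
    # q modes of the a x a window below the fit support
    k1 = np.fft.fftfreq(a) * 2.0 * np.pi
    KX, KY = np.meshgrid(k1, k1, indexing="ij")
    qmag = np.hypot(KX, KY)
    mode_mask = (qmag > 0) & (qmag <= config.q_fit_max)
    qvecs = np.stack([KX[mode_mask], KY[mode_mask]], axis=1)

    centre = (a - 1) / 2.0
    ii = np.arange(a) - centre
    env = np.exp(-(ii[:, None]**2 + ii[None, :]**2) / config.l**2)

    win_view_shape = None
    Z_list = []
    for t in range(T):
        wins = sliding_window_view(frames[t], (a, a))[::config.da, ::config.da]
        win_view_shape = wins.shape[:2]
        ft = np.fft.fft2(wins * env, axes=(-2, -1))
        Z_list.append(ft[..., mode_mask])
    Z = np.stack(Z_list, axis=2)  # (ny, nx, T, M)
    weights = np.mean(np.abs(Z)**2, axis=2)
    r = _phase_displacements(Z, qvecs, weights)           # px
    v = _sliding_slopes(r, config.fit_window, 1.0)        # px/frame
    v_um = v * stack.px_size * stack.frame_rate
    times = np.arange(T) / stack.frame_rate
    # axes: rows of the window grid advance along image rows (x index)
    field = np.moveaxis(v_um, 2, 0)                       # (T, ny, nx, 2)
    return VelocityField(u=field, spacing=config.da * stack.px_size,
                         times=times)


def phase_diff_drift(stack: ImageStack, q_fit_max: float = np.pi / 4.0,
                     max_modes_radius: int = 16) -> float:
    """Population drift velocity (um/s, x component) by global phase
    tracking of the full frame (no localization filter)."""
    frames = stack.frames
    T, H, W = frames.shape
    k1x = np.fft.fftfreq(H) * 2.0 * np.pi
    k1y = np.fft.fftfreq(W) * 2.0 * np.pi
    KX, KY = np.meshgrid(k1x, k1y, indexing="ij")
    qmag = np.hypot(KX, KY)
    qcap = min(q_fit_max, 2.0 * np.pi * max_modes_radius / min(H, W))
    mode_mask = (qmag > 0) & (qmag <= qcap)
    qvecs = np.stack([KX[mode_mask], KY[mode_mask]], axis=1)
    ft = np.fft.fft2(frames.astype(np.float64))[:, mode_mask]  # (T, M)
    weights = np.mean(np.abs(ft)**2, axis=0)
    r = _phase_displacements(ft, qvecs, weights)          # (T, 2) px
    dt = 1.0 / stack.frame_rate
    tt = np.arange(T) * dt
    tt = tt - tt.mean()
    slope = (r[:, 0] * tt).sum() / (tt**2).sum()          # px/s along rows
    return float(slope * stack.px_size)
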