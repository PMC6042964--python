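"""Self-diffusion from mean-squared displacements, with finite-size correction.

The self-diffusion coefficient is estimated from the Einstein relation

    D_PBC = lim_{t→∞} (1/6) d/dt ⟨|r(t) − r(0)|²⟩,

with the average taken over all selected particles and all time origins.
Under periodic boundary conditions the measured D_PBC is depressed by the
hydrodynamic self-interaction of the particle with its images; for a
cubic box of edge L the leading correction is

    D_0 = D_PBC + k_B·T·ξ / (6π·η·L),        ξ = 2.837297,

(the cubic-lattice Ewald constant), i.e. the finite-size error scales as
1/L, equivalently N^(−1/3).  ``scaling_fit`` fits measured (L, D_PBC)
pairs against 1/L so the intercept gives the infinite-box extrapolation.

Units: MSD curves carry lag times in ps and values in Ų; diffusion
coefficients cross the API boundary in cm²/s (1 cm²/s = 1e4 Ų/ps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    A2_per_ps_to_cm2_per_s,
    KB_J_PER_K,
    Selection,
    Trajectory,
)

#: Cubic-lattice Ewald self-term constant ξ in the 1/L correction.
XI_CUBIC = 2.837297

#: Default shear viscosity for TIP3P-like water at ~300 K, Pa·s.
DEFAULT_VISCOSITY_PA_S = 3.21e-4

#: Default temperature for the finite-size correction, K.
DEFAULT_TEMPERATURE_K = 298.0


@dataclass
class MSDCurve:
    """Mean-squared displacement vs lag time.

    ``n_samples[k]`` counts (origin, particle) pairs averaged at lag k;
    with all origins it decreases with lag, so long-lag points are
    noisier.  MSD(0) is identically 0.
    """

    lag_ps: np.ndarray
    msd_A2: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        self.lag_ps = np.asarray(self.lag_ps, dtype=float)
        self.msd_A2 = np.asarray(self.msd_A2, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        if not (len(self.lag_ps) == len(self.msd_A2) == len(self.n_samples)):
            raise ValueError("lag, msd and sample-count arrays must align")


@dataclass
class DiffusionEstimate:
    """A fitted diffusion coefficient with its error estimate.

    ``error_cm2_s`` is the absolute difference between fits over the two
    halves of the fit interval.  ``D0_cm2_s`` is populated once the
    finite-size correction has been applied.
    """

    D_pbc_cm2_s: float
    error_cm2_s: float
    fit_interval_ps: tuple[float, float]
    L: float | None = None
    D0_cm2_s: float | None = None
    correction_constant: float | None = None
    detail: dict = field(default_factory=dict)


def compute_msd(
    traj: Trajectory,
    selection: Selection | None = None,
    max_lag: float | None = None,
    origin_stride: int = 1,
    masses: np.ndarray | None = None,
) -> MSDCurve:
    """MSD(τ) averaged over selected particles and all (strided) origins.

    Parameters
    ----------
    traj : Trajectory
        Must hold unwrapped (continuous) coordinates; a trajectory
        flagged ``wrapped=True`` is refused, because image jumps corrupt
        displacements.
    selection : Selection, optional
        Restricts to a subset of atoms (default: all).
    max_lag : float, optional
        Largest lag in ps (default: half the trajectory length, where
        origin averaging still has decent statistics).
    origin_stride : int
        Use every ``origin_stride``-th frame as a time origin.  With
        stride 1 an FFT (Wiener–Khinchin) evaluation is used; larger
        strides fall back to direct averaging.
    masses : ndarray, optional
        Per-selected-particle weights for a mass-weighted average;
        uniform when omitted (the right choice for an all-oxygen water
        selection).
    """
    if traj.wrapped:
        raise ValueError(
            "trajectory coordinates are wrapped into the box; MSD needs "
            "unwrapped (continuous) coordinates — generate them unwrapped "
            "or unwrap before calling compute_msd"
        )
    if origin_stride < 1:
        raise ValueError(f"origin_stride must be ≥ 1, got {origin_stride}")
    idx = selection.resolve(traj) if selection is not None else np.arange(traj.n_atoms)
    if idx.size == 0:
        raise ValueError("selection matches no atoms")
    r = traj.frames[:, idx, :]  # (T, n, 3)
    T = r.shape[0]
    total_span = (T - 1) * traj.dt
    if max_lag is None:
        max_lag = total_span / 2.0
    if max_lag >= T * traj.dt:
        raise ValueError(
            f"max_lag {max_lag} ps exceeds trajectory span {total_span} ps"
        )
    n_lags = int(np.floor(max_lag / traj.dt)) + 1
    n_lags = min(n_lags, T)

    w = None
    if masses is not None:
        w = np.asarray(masses, dtype=float)
        if w.shape != (idx.size,):
            raise ValueError(
                f"masses must have one entry per selected atom ({idx.size})"
            )
        w = w / w.sum()

    if origin_stride == 1:
        per_particle, counts = _msd_fft(r, n_lags)
    else:
        per_particle, counts = _msd_direct(r, n_lags, origin_stride)
    msd = per_particle @ w if w is not None else per_particle.mean(axis=1)
    n_samples = counts * idx.size
    lags = np.arange(n_lags) * traj.dt
    return MSDCurve(lag_ps=lags, msd_A2=msd, n_samples=n_samples)


def _msd_fft(r: np.ndarray, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """All-origin MSD per particle via the FFT autocorrelation identity."""
    T = r.shape[0]
    # S2(τ) = Σ_t r(t)·r(t+τ), via zero-padded FFT along time
    F = np.fft.rfft(r, n=2 * T, axis=0)
    s2 = np.fft.irfft(F * np.conj(F), n=2 * T, axis=0)[:T].sum(axis=2).real
    d_sq = np.sum(r * r, axis=2)  # (T, n)
    q = 2.0 * d_sq.sum(axis=0)
    s1 = np.empty_like(d_sq)
    s1[0] = q
    for m in range(1, T):
        q = q - d_sq[m - 1] - d_sq[T - m]
        s1[m] = q
    counts = (T - np.arange(T)).astype(float)
    msd = (s1 - 2.0 * s2) / counts[:, None]
    msd[0] = 0.0
    return msd[:n_lags], counts[:n_lags].astype(int)


def _msd_direct(
    r: np.ndarray, n_lags: int, origin_stride: int
) -> tuple[np.ndarray, np.ndarray]:
    """Direct strided-origin MSD per particle (reference path)."""
    T, n, _ = r.shape
    msd = np.zeros((n_lags, n))
    counts = np.zeros(n_lags, dtype=int)
    for k in range(n_lags):
        origins = np.arange(0, T - k, origin_stride)
        disp = r[origins + k] - r[origins]
        msd[k] = np.mean(np.sum(disp * disp, axis=2), axis=0)
        counts[k] = origins.size
    return msd, counts


def fit_diffusion(
    msd: MSDCurve,
    t_min: float | None = None,
    t_max: float | None = None,
    L: float | None = None,
) -> DiffusionEstimate:
    """Least-squares slope of MSD over [t_min, t_max]; D = slope/6.

    The default window is [10%, 50%] of the curve's maximum lag — late
    enough to skip short-lag transients, early enough that origin
    statistics remain good.  The quoted error is the difference between
    D fitted on the first and second half of the window, each half
    needing at least 4 points.
    """
    lag_max = msd.lag_ps[-1]
    if t_min is None:
        t_min = 0.1 * lag_max
    if t_max is None:
        t_max = 0.5 * lag_max
    if not (0 <= t_min < t_max <= lag_max):
        raise ValueError(
            f"fit interval [{t_min}, {t_max}] ps not inside (0, {lag_max}] ps"
        )
    sel = (msd.lag_ps >= t_min) & (msd.lag_ps <= t_max)
    t = msd.lag_ps[sel]
    y = msd.msd_A2[sel]
    if t.size < 8:
        raise ValueError(
            f"only {t.size} MSD points in [{t_min}, {t_max}] ps; "
            "need ≥ 8 (4 per half-interval) for a fit with an error estimate"
        )
    slope = _ls_slope(t, y)
    mid = t.size // 2
    d1 = _ls_slope(t[:mid], y[:mid]) / 6.0
    d2 = _ls_slope(t[mid:], y[mid:]) / 6.0
    d_pbc = A2_per_ps_to_cm2_per_s(slope / 6.0)
    return DiffusionEstimate(
        D_pbc_cm2_s=d_pbc,
        error_cm2_s=abs(A2_per_ps_to_cm2_per_s(d1 - d2)),
        fit_interval_ps=(float(t_min), float(t_max)),
        L=L,
        detail={"slope_A2_per_ps": float(slope), "n_points": int(t.size)},
    )


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 2:
        raise ValueError("need at least two points for a slope")
    return float(np.polyfit(t, y, 1)[0])


def finite_size_correction(
    L: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    viscosity: float = DEFAULT_VISCOSITY_PA_S,
) -> float:
    """The additive 1/L correction k_B·T·ξ/(6π·η·L) in cm²/s.

    ``L`` in Å, ``temperature`` in K, ``viscosity`` in Pa·s.
    """
    if not L > 0:
        raise ValueError(f"box edge must be positive, got {L}")
    if not viscosity > 0:
        raise ValueError(f"viscosity must be positive, got {viscosity}")
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    L_m = L * 1e-10
    corr_m2_s = KB_J_PER_K * temperature * XI_CUBIC / (6.0 * np.pi * viscosity * L_m)
    return corr_m2_s * 1e4  # m²/s → cm²/s


def finite_size_correct(
    D_pbc: float,
    L: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    viscosity: float = DEFAULT_VISCOSITY_PA_S,
) -> float:
    """Infinite-box diffusion coefficient D0 = D_PBC + k_B·T·ξ/(6π·η·L).

    All diffusion coefficients in cm²/s; ``L`` in Å.  The correction is
    strictly positive for positive viscosity, so D0 > D_PBC.
    """
    return float(D_pbc) + finite_size_correction(L, temperature, viscosity)


def scaling_fit(
    pairs: "list[tuple[float, float]] | np.ndarray",
) -> tuple[float, float]:
    """Least-squares line of D_PBC against 1/L.

    ``pairs`` holds (L in Å, D_PBC in cm²/s) tuples with at least two
    distinct L.  Returns (slope, intercept); the intercept is the
    infinite-box extrapolation D0 and the slope is negative for the
    hydrodynamic finite-size effect.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (L, D) pairs")
    L, D = arr[:, 0], arr[:, 1]
    if np.unique(L).size < 2:
        raise ValueError("need at least two distinct box edges for a scaling fit")
    slope, intercept = np.polyfit(1.0 / L, D, 1)
    return float(slope), float(intercept)


@dataclass
class ExtrapolationResult:
    """Linear D→first-transition-time extrapolation."""

    t_predicted: float
    slope: float
    intercept: float
    residuals: np.ndarray


def extrapolate_transition_time(
    pairs: "list[tuple[float, float]] | np.ndarray",
    D_query: float,
) -> ExtrapolationResult:
    """Fit t_first_transition as a linear function of D and predict at D_query.

    ``pairs`` holds (D in cm²/s, t in ns) with at least two distinct D.
    Boxes with faster (more bulk-like) water keep the folded state
    longer, so the fitted slope is positive and the prediction at the
    bulk D estimates when the first transition would occur in an
    adequately large box.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (D, t) pairs")
    D, t = arr[:, 0], arr[:, 1]
    if np.unique(D).size < 2:
        raise ValueError("all D values identical: the line is degenerate")
    slope, intercept = np.polyfit(D, t, 1)
    fitted = slope * D + intercept
    return ExtrapolationResult(
        t_predicted=float(slope * D_query + intercept),
        slope=float(slope),
        intercept=float(intercept),
        residuals=t - fitted,
    )
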