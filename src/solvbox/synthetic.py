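"""Synthetic fixtures with exactly known ground truth.

Every analysis stage in this package is exercised against configurations
whose answer is known by construction rather than against (unavailable)
production MD output:

* :func:`gen_brownian_water` — independent Gaussian random walks with a
  prescribed self-diffusion coefficient, the ground truth for the MSD
  estimator;
* :func:`gen_ideal_gas` — a uniform configuration whose g(r) is 1;
* :func:`gen_hbond_lattice` — a periodic simple-cubic oxygen lattice
  where every site has exactly six nearest neighbours at the lattice
  spacing, giving exact hydrogen-bond counts;
* :func:`gen_layered_solute` — delta-function hydration shells around a
  spherical solute, giving exact peak positions and shell populations;
* :func:`gen_transition_trace` — a piecewise-constant distance trace
  with planted change points and i.i.d. Gaussian noise.

Generators are statistical stand-ins, not physical water: there are no
intermolecular forces, no hydrogens, and trace noise is i.i.d. whereas
real structural traces are autocorrelated.  All ground truth (true D,
planted counts, change-point times, shell radii, seed) is recorded in
the returned object's ``metadata`` so downstream tests never re-derive
it from the fixture itself.

Seeding: the seed is always explicit, and the same seed with the same
parameters reproduces the output bit for bit.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import TimeSeries, Trajectory, cm2_per_s_to_A2_per_ps


def gen_brownian_water(
    N: int,
    L: float,
    D: float,
    dt: float,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Brownian pseudo-water: N independent Gaussian random walks.

    Parameters
    ----------
    N : int
        Number of particles (one oxygen site each, no hydrogens).
    L : float
        Cubic box edge, Å (initial positions are uniform in the box).
    D : float
        Self-diffusion coefficient, cm²/s.  Per step and per dimension
        the displacement variance is 2·D·dt (converted to Ų).
    dt : float
        Time step between frames, ps.
    n_frames : int
        Number of stored frames.
    seed : int
        RNG seed; explicit always.

    Returns
    -------
    Trajectory
        Unwrapped coordinates (``wrapped=False``) so the MSD is directly
        computable; call :meth:`~solvbox.model.Trajectory.wrap` for a
        periodic copy.  ``metadata['D_true_cm2_s']`` records the input D.
    """
    if D < 0:
        raise ValueError(f"diffusion coefficient must be non-negative, got {D}")
    if N < 1 or n_frames < 1:
        raise ValueError("need at least one particle and one frame")
    d_a2ps = cm2_per_s_to_A2_per_ps(D)
    step_var = 2.0 * d_a2ps * dt  # Å² per step per dimension
    if not np.isfinite(step_var):
        raise ValueError(f"step variance 2·D·dt overflows: D={D}, dt={dt}")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, L, size=(1, N, 3))
    if n_frames == 1 or step_var == 0.0:
        frames = np.repeat(start, n_frames, axis=0)
    else:
        steps = rng.normal(0.0, np.sqrt(step_var), size=(n_frames - 1, N, 3))
        frames = start + np.concatenate(
            [np.zeros((1, N, 3)), np.cumsum(steps, axis=0)]
        )
    return Trajectory(
        frames=frames,
        box=L,
        dt=dt,
        wrapped=False,
        metadata={
            "kind": "brownian_water",
            "D_true_cm2_s": D,
            "step_var_A2": step_var,
            "seed": seed,
        },
    )


def gen_ideal_gas(N: int, L: float, seed: int) -> Trajectory:
    """One frame of N points uniform in a cubic box: the g(r)=1 oracle."""
    if N < 2:
        raise ValueError(f"need at least two particles, got {N}")
    rng = np.random.default_rng(seed)
    frame = rng.uniform(0.0, L, size=(1, N, 3))
    return Trajectory(
        frames=frame,
        box=L,
        dt=1.0,
        wrapped=True,
        metadata={"kind": "ideal_gas", "N": N, "seed": seed},
    )


def gen_hbond_lattice(n_side: int, spacing: float) -> Trajectory:
    """Periodic simple-cubic oxygen lattice with exact neighbour counts.

    The box edge is n_side·spacing, so under periodic boundaries every
    one of the n_side³ sites has exactly 6 nearest neighbours at
    distance == spacing (and 12 next-nearest at spacing·√2).
    """
    if n_side < 2:
        raise ValueError(f"n_side must be ≥ 2, got {n_side}")
    if not spacing > 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    ax = np.arange(n_side) * spacing
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return Trajectory(
        frames=grid[None, :, :],
        box=n_side * spacing,
        dt=1.0,
        wrapped=True,
        metadata={
            "kind": "hbond_lattice",
            "n_side": n_side,
            "spacing": spacing,
            "neighbours_per_site": 6,
            "pairs_total": 3 * n_side**3,
        },
    )


def gen_layered_solute(
    R: float,
    shell_radii: Sequence[float],
    shell_counts: Sequence[int],
    bulk_N: int,
    L: float,
    seed: int,
) -> tuple[Trajectory, np.ndarray]:
    """Delta-function hydration shells around a spherical solute.

    Atom 0 is the solute reference site at the box centre; exactly
    ``shell_counts[i]`` waters sit uniformly on the sphere of radius
    ``shell_radii[i]``, and ``bulk_N`` waters are uniform in the box but
    outside max(shell_radii)+1 Å.  Shell radii must exceed the solute
    radius R and be sorted ascending.

    Returns the single-frame trajectory and the solute centre.
    """
    radii = np.asarray(shell_radii, dtype=float)
    counts = [int(c) for c in shell_counts]
    if len(radii) != len(counts):
        raise ValueError("shell_radii and shell_counts must have equal length")
    if len(radii) and np.any(np.diff(radii) <= 0):
        raise ValueError("shell radii must be strictly increasing")
    if np.any(radii <= R):
        raise ValueError(
            f"shell radii {radii.tolist()} must all exceed the solute radius {R}"
        )
    rng = np.random.default_rng(seed)
    center = np.full(3, L / 2.0)
    points = [center[None, :]]
    for r, c in zip(radii, counts):
        v = rng.normal(size=(c, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        points.append(center + r * v)
    exclusion = (radii.max() + 1.0) if len(radii) else R
    placed = 0
    bulk: list[np.ndarray] = []
    while placed < bulk_N:
        cand = rng.uniform(0.0, L, size=(max(bulk_N, 64), 3))
        d = np.linalg.norm(cand - center, axis=1)
        keep = cand[d > exclusion]
        take = keep[: bulk_N - placed]
        bulk.append(take)
        placed += len(take)
    if bulk:
        points.append(np.concatenate(bulk))
    frame = np.concatenate(points)
    traj = Trajectory(
        frames=frame[None, :, :],
        box=L,
        dt=1.0,
        wrapped=True,
        metadata={
            "kind": "layered_solute",
            "R": R,
            "shell_radii": radii.tolist(),
            "shell_counts": counts,
            "bulk_N": bulk_N,
            "center": center.tolist(),
            "seed": seed,
        },
    )
    return traj, center


def gen_transition_trace(
    change_points_ns: Sequence[float],
    levels: Sequence[float],
    sigma: float,
    dt_ns: float,
    T_ns: float,
    seed: int,
) -> TimeSeries:
    """Piecewise-constant trace with planted change points and noise.

    Emulates a structural distance trace that jumps between plateaus at
    quaternary transitions.  ``levels`` has one more entry than
    ``change_points_ns``; change points must be strictly increasing and
    lie inside (0, T_ns).  Noise is i.i.d. Gaussian with standard
    deviation ``sigma`` (real traces are autocorrelated; i.i.d. is the
    minimal testable choice).
    """
    cps = np.asarray(change_points_ns, dtype=float)
    lv = np.asarray(levels, dtype=float)
    if len(lv) != len(cps) + 1:
        raise ValueError(
            f"need len(levels) == len(change_points)+1, got {len(lv)} and {len(cps)}"
        )
    if len(cps) and (np.any(np.diff(cps) <= 0) or cps[0] <= 0 or cps[-1] >= T_ns):
        raise ValueError(
            f"change points must be strictly increasing inside (0, {T_ns}), got {cps.tolist()}"
        )
    if sigma < 0 or dt_ns <= 0 or T_ns <= 0:
        raise ValueError("sigma must be ≥ 0 and dt_ns, T_ns positive")
    times = np.arange(0.0, T_ns, dt_ns)
    segment = np.searchsorted(cps, times, side="right")
    mean = lv[segment]
    rng = np.random.default_rng(seed)
    values = mean + (rng.normal(0.0, sigma, size=times.shape) if sigma > 0 else 0.0)
    return TimeSeries(
        times=times,
        values=values,
        label="distance",
        units="Å",
        metadata={
            "kind": "transition_trace",
            "change_points_ns": cps.tolist(),
            "levels": lv.tolist(),
            "sigma": sigma,
            "seed": seed,
        },
    )
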