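"""Hydration structure: g(r), solvent density profiles, region counts.

``radial_distribution`` is the standard pair-correlation estimator: a
histogram of minimum-image reference–target distances normalized by the
ideal-gas shell expectation 4πr²dr·ρ, so a structureless (uniform)
target gives g(r) = 1.

``density_profile`` is the dewetting diagnostic for a large solute: the
water number density as a function of distance from the solute surface
(distance to the solute centre minus an effective solute radius R),
normalized by the bulk density measured far from the solute.  Depletion
of the first bins relative to 1 signals dewetting; an adequately large
box shows the profile recover to 1 well inside the half-box.

Region counters (sphere/cylinder, minimum-image aware) support explicit
water book-keeping, e.g. counting the waters within a given radius of a
channel axis and the frame-to-frame distribution of that count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Selection, Trajectory
from .pbc import minimum_image_displacement


def _resolve(traj: Trajectory, sel) -> np.ndarray:
    if sel is None:
        return np.arange(traj.n_atoms)
    if isinstance(sel, Selection):
        return sel.resolve(traj)
    return np.asarray(sel, dtype=int)


@dataclass
class RDFProfile:
    """g(r) on bin centres with the parameters used to compute it."""

    r: np.ndarray
    g: np.ndarray
    dr: float
    n_frames: int
    n_ref: int
    n_target: int
    rho_target: float

    def first_maxima(self, n: int = 2, min_g: float = 0.0) -> np.ndarray:
        """Bin centres of the first ``n`` local maxima with g > min_g."""
        g = self.g
        peaks = [
            i
            for i in range(1, len(g) - 1)
            if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > min_g
        ]
        return self.r[np.array(peaks[:n], dtype=int)] if peaks else np.array([])


@dataclass
class DensityProfile:
    """ρ(d)/ρ_bulk vs distance d from the solute surface."""

    d: np.ndarray
    ratio: np.ndarray
    dr: float
    R: float
    rho_bulk: float
    normalized: bool = True


def radial_distribution(
    traj: Trajectory,
    ref_selection,
    target_selection,
    r_max: float,
    dr: float,
    frames: "slice | None" = None,
) -> RDFProfile:
    """Radial distribution function between two selections.

    Distances use the minimum-image convention, so ``r_max`` may not
    exceed L/2.  Self-pairs (an atom in both selections) are excluded.
    Normalization per frame: count in [r, r+dr) divided by
    n_ref · 4πr²dr · ρ_target with ρ_target = n_target/L³.
    """
    if not dr > 0:
        raise ValueError(f"dr must be positive, got {dr}")
    L = traj.box
    if r_max > L / 2:
        raise ValueError(
            f"r_max {r_max} Å exceeds half the box edge ({L / 2} Å)"
        )
    ref = _resolve(traj, ref_selection)
    tgt = _resolve(traj, target_selection)
    if ref.size == 0:
        raise ValueError("reference selection matches no atoms")
    if tgt.size == 0:
        raise ValueError("target selection matches no atoms")
    edges = np.arange(0.0, r_max + dr, dr)
    hist = np.zeros(len(edges) - 1)
    frame_iter = traj.frames[frames] if frames is not None else traj.frames
    n_frames = len(frame_iter)
    for frame in frame_iter:
        d = minimum_image_displacement(
            frame[ref][:, None, :], frame[tgt][None, :, :], L
        )
        dist = np.sqrt(np.sum(d * d, axis=-1))
        # exclude atoms present in both selections paired with themselves
        self_mask = ref[:, None] == tgt[None, :]
        dist = dist[~self_mask]
        hist += np.histogram(dist, bins=edges)[0]
    rho = tgt.size / L**3
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers**2 * dr
    norm = n_frames * ref.size * shell_vol * rho
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norm > 0, hist / norm, 0.0)
    return RDFProfile(
        r=centers,
        g=g,
        dr=dr,
        n_frames=n_frames,
        n_ref=int(ref.size),
        n_target=int(tgt.size),
        rho_target=rho,
    )


def effective_solute_radius(
    coords: np.ndarray, center: np.ndarray, quantile: float = 0.99
) -> float:
    """Effective radius: sphere about ``center`` holding ``quantile`` of atoms."""
    d = np.linalg.norm(np.asarray(coords, dtype=float) - center, axis=1)
    return float(np.quantile(d, quantile))


def density_profile(
    traj: Trajectory,
    solute_selection,
    water_selection,
    dr: float = 0.5,
    R: float | None = None,
) -> DensityProfile:
    """Water density vs distance from the solute surface, over ρ_bulk.

    The solute centre is its centre of geometry (per frame); the
    effective radius R defaults to the sphere containing 99% of solute
    atoms and may be given explicitly (e.g. 0 for a point solute).
    ρ_bulk is measured in the outermost 10% of valid distances
    (d ≤ L/2 − R); when no such bulk region exists the profile is
    returned unnormalized with a warning.
    """
    if not dr > 0:
        raise ValueError(f"dr must be positive, got {dr}")
    sol = _resolve(traj, solute_selection)
    wat = _resolve(traj, water_selection)
    if sol.size == 0:
        raise ValueError("solute selection matches no atoms")
    if wat.size == 0:
        raise ValueError("water selection matches no atoms")
    L = traj.box
    first_center = traj.frames[0][sol].mean(axis=0)
    if R is None:
        R = effective_solute_radius(traj.frames[0][sol], first_center)
    d_max = L / 2.0 - R
    if d_max <= dr:
        raise ValueError(
            f"box edge {L} Å too small for a solute of radius {R} Å"
        )
    edges = np.arange(0.0, d_max + dr, dr)
    hist = np.zeros(len(edges) - 1)
    for frame in traj.frames:
        center = frame[sol].mean(axis=0)
        disp = minimum_image_displacement(frame[wat], center, L)
        d = np.sqrt(np.sum(disp * disp, axis=-1)) - R
        hist += np.histogram(d, bins=edges)[0]
    mid = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * (R + mid) ** 2 * dr
    rho = hist / (traj.n_frames * shell_vol)
    n_bulk = max(int(np.floor(0.1 * len(mid))), 0)
    if n_bulk < 1:
        warnings.warn(
            "no bulk region available beyond the solute; returning an "
            "unnormalized density profile",
            stacklevel=2,
        )
        return DensityProfile(d=mid, ratio=rho, dr=dr, R=R, rho_bulk=1.0,
                              normalized=False)
    rho_bulk = float(np.mean(rho[-n_bulk:]))
    if rho_bulk <= 0:
        warnings.warn(
            "bulk density is zero; returning an unnormalized density profile",
            stacklevel=2,
        )
        return DensityProfile(d=mid, ratio=rho, dr=dr, R=R, rho_bulk=0.0,
                              normalized=False)
    return DensityProfile(d=mid, ratio=rho / rho_bulk, dr=dr, R=R,
                          rho_bulk=rho_bulk)


# ---------------------------------------------------------------------------
# Regions


@dataclass(frozen=True)
class SphereRegion:
    """Sphere of given radius about a fixed centre (Å)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    def contains(self, coords: np.ndarray, L: float) -> np.ndarray:
        disp = minimum_image_displacement(coords, np.asarray(self.center), L)
        return np.sum(disp * disp, axis=-1) <= self.radius**2


@dataclass(frozen=True)
class CylinderRegion:
    """Finite cylinder: centre point, axis direction, radius, half-height (Å)."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    half_height: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.half_height > 0):
            raise ValueError(
                f"cylinder radius and half-height must be positive, got "
                f"{self.radius}, {self.half_height}"
            )
        if not np.linalg.norm(self.axis) > 0:
            raise ValueError("cylinder axis must be a non-zero vector")

    def contains(self, coords: np.ndarray, L: float) -> np.ndarray:
        u = np.asarray(self.axis, dtype=float)
        u = u / np.linalg.norm(u)
        disp = minimum_image_displacement(coords, np.asarray(self.center), L)
        axial = disp @ u
        radial_sq = np.sum(disp * disp, axis=-1) - axial**2
        return (np.abs(axial) <= self.half_height) & (
            radial_sq <= self.radius**2
        )


def count_waters_in_region(
    frame: np.ndarray,
    region: "SphereRegion | CylinderRegion",
    L: float,
    water_indices: np.ndarray | None = None,
) -> int:
    """Exact count of water sites inside the region (minimum-image aware)."""
    coords = np.asarray(frame, dtype=float)
    if water_indices is not None:
        coords = coords[np.asarray(water_indices, dtype=int)]
    return int(np.count_nonzero(region.contains(coords, L)))


@dataclass
class CountDistribution:
    """Per-frame region water counts and their normalized histogram."""

    counts: np.ndarray
    values: np.ndarray
    probabilities: np.ndarray
    mean: float
    sd: float
    detail: dict = field(default_factory=dict)


def water_count_distribution(
    traj: Trajectory,
    region: "SphereRegion | CylinderRegion",
    water_selection=None,
) -> CountDistribution:
    """Distribution of the per-frame water count in a region.

    Needs at least two frames; the histogram is over the integer counts
    observed and sums to one.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames for a count distribution")
    idx = _resolve(traj, water_selection)
    counts = np.array(
        [
            count_waters_in_region(f, region, traj.box, idx)
            for f in traj.frames
        ]
    )
    values, freq = np.unique(counts, return_counts=True)
    probs = freq / counts.size
    return CountDistribution(
        counts=counts,
        values=values,
        probabilities=probs,
        mean=float(counts.mean()),
        sd=float(counts.std()),
    )
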