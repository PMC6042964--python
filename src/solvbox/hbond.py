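"""Water–water hydrogen-bond statistics.

A hydrogen bond is identified from the donor–acceptor (oxygen–oxygen)
minimum-image distance alone, against one of three conventional cutoffs:
2.8 Å (strong), 3.0 Å (medium) or 3.3 Å (weak).  No angular term is
applied by default — hydrogen positions are often absent from the
fixtures and from coarse water representations — but an optional
donor-H…acceptor angle filter is available when hydrogens are present.

The headline observable is ⟨N_H-bonds⟩/molecule per frame.  Two counting
conventions exist in the literature: crediting each bond to both
partners (2·pairs/N, the default) or counting each pair once (pairs/N).
The choice scales the absolute level but cancels in the interval-to-
interval drops and in fluctuation trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Selection, TimeSeries, Trajectory
from .pbc import minimum_image_displacement, neighbour_pairs

#: Conventional donor–acceptor cutoffs, Å.
CUTOFFS = {"strong": 2.8, "medium": 3.0, "weak": 3.3}


@dataclass
class HBondStats:
    """Per-frame ⟨N_H-bonds⟩/molecule series plus interval statistics."""

    series: TimeSeries
    cutoff: float
    convention: str = "both"  # "both": 2·pairs/N; "single": pairs/N
    n_molecules: int = 0
    interval_bounds_ns: np.ndarray | None = None
    interval_means: np.ndarray | None = None
    interval_sds: np.ndarray | None = None
    interval_drops: np.ndarray | None = None
    detail: dict = field(default_factory=dict)

    @property
    def fluctuation(self) -> float:
        """Standard deviation of the per-frame average over the series."""
        return float(np.std(self.series.values))


def find_hbonds(
    coords: np.ndarray,
    cutoff: float,
    L: float,
    hydrogens: np.ndarray | None = None,
    donor_of: np.ndarray | None = None,
    angle_min_deg: float = 140.0,
) -> np.ndarray:
    """Unordered oxygen pairs within the donor–acceptor cutoff.

    Cell-list neighbour search; the result set is identical to the
    all-pairs computation.  ``cutoff`` must not exceed L/2.

    When ``hydrogens`` (H coordinates) and ``donor_of`` (oxygen index of
    each H) are given, a pair is kept only if some H on either oxygen
    makes a donor-H…acceptor angle of at least ``angle_min_deg``.
    """
    pairs = neighbour_pairs(coords, cutoff, L)
    if hydrogens is None or len(pairs) == 0:
        return pairs
    keep = np.array(
        [
            _angle_accepts(coords, hydrogens, donor_of, i, j, L, angle_min_deg)
            for i, j in pairs
        ],
        dtype=bool,
    )
    return pairs[keep]


def _angle_accepts(coords, hydrogens, donor_of, i, j, L, angle_min_deg) -> bool:
    cos_min = np.cos(np.deg2rad(180.0 - angle_min_deg))
    for donor, acceptor in ((i, j), (j, i)):
        hs = hydrogens[donor_of == donor]
        for h in hs:
            dh = minimum_image_displacement(h, coords[donor], L)
            ha = minimum_image_displacement(coords[acceptor], h, L)
            nd, na = np.linalg.norm(dh), np.linalg.norm(ha)
            if nd == 0 or na == 0:
                continue
            # angle at H between donor and acceptor
            cos_dha = -np.dot(dh, ha) / (nd * na)
            if cos_dha <= cos_min:
                return True
    return False


def hbond_timeseries(
    traj: Trajectory,
    cutoff: float,
    selection: Selection | None = None,
    stride: int = 1,
    convention: str = "both",
) -> HBondStats:
    """⟨N_H-bonds⟩/molecule for every ``stride``-th frame.

    With the default "both" convention the per-frame value is
    2·(pair count)/N_water; "single" counts each pair once.
    """
    if convention not in ("both", "single"):
        raise ValueError(f"unknown convention {convention!r}")
    idx = selection.resolve(traj) if selection is not None else np.arange(traj.n_atoms)
    if idx.size == 0:
        raise ValueError("water selection matches no atoms")
    factor = 2.0 if convention == "both" else 1.0
    frames = range(0, traj.n_frames, stride)
    values = np.empty(len(frames))
    for k, f in enumerate(frames):
        pairs = find_hbonds(traj.frames[f][idx], cutoff, traj.box)
        values[k] = factor * len(pairs) / idx.size
    times_ns = np.array([f * traj.dt for f in frames]) / 1000.0
    series = TimeSeries(
        times=times_ns,
        values=values,
        label=f"hbonds_per_molecule_cutoff_{cutoff:g}A",
        units="count",
    )
    return HBondStats(
        series=series,
        cutoff=cutoff,
        convention=convention,
        n_molecules=int(idx.size),
    )


def interval_statistics(
    stats: "HBondStats | TimeSeries",
    interval_boundaries_ns: "list[float] | np.ndarray",
) -> HBondStats:
    """Mean, SD and successive mean drops over lifetime intervals.

    ``interval_boundaries_ns`` are the interior boundaries (sorted,
    inside the series span); with k boundaries the series is cut into
    k+1 intervals.  The i-th "drop" is mean(interval i) −
    mean(interval i+1), positive when the level falls across a
    transition.  Every interval must contain at least one sample.
    """
    series = stats.series if isinstance(stats, HBondStats) else stats
    bounds = np.asarray(interval_boundaries_ns, dtype=float)
    if bounds.size and np.any(np.diff(bounds) <= 0):
        raise ValueError("interval boundaries must be strictly increasing")
    t0, t1 = series.times[0], series.times[-1]
    if bounds.size and (bounds[0] <= t0 or bounds[-1] >= t1):
        raise ValueError(
            f"boundaries {bounds.tolist()} must lie strictly inside "
            f"the series span ({t0}, {t1}) ns"
        )
    edges = np.concatenate([[t0], bounds, [np.nextafter(t1, np.inf)]])
    means, sds = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (series.times >= lo) & (series.times < hi)
        if not mask.any():
            raise ValueError(f"interval [{lo}, {hi}) ns contains no samples")
        means.append(float(np.mean(series.values[mask])))
        sds.append(float(np.std(series.values[mask])))
    means_arr = np.array(means)
    result = (
        stats
        if isinstance(stats, HBondStats)
        else HBondStats(series=series, cutoff=float("nan"))
    )
    result.interval_bounds_ns = bounds
    result.interval_means = means_arr
    result.interval_sds = np.array(sds)
    result.interval_drops = means_arr[:-1] - means_arr[1:]
    return result
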