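"""Periodic-boundary utilities for cubic boxes.

All distances follow the minimum-image convention: of the 27 periodic
images of a point in a cubic box of edge L, the nearest one is used, so
no pair distance exceeds L·√3/2.  Minimum-image distances are only a
valid metric for cutoff searches when the cutoff is at most L/2; the
neighbour search enforces that.
"""

from __future__ import annotations

import numpy as np


def minimum_image_displacement(p: np.ndarray, q: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image displacement vector(s) q → p in a cubic box of edge L."""
    if not L > 0:
        raise ValueError(f"box edge must be positive, got {L}")
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    return d - L * np.round(d / L)


def minimum_image_distance(p: np.ndarray, q: np.ndarray, L: float) -> float | np.ndarray:
    """Minimum-image Euclidean distance (Å) between points p and q.

    Broadcasts over leading axes; the last axis holds x/y/z.
    """
    d = minimum_image_displacement(p, q, L)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_distances(coords_a: np.ndarray, coords_b: np.ndarray, L: float) -> np.ndarray:
    """(n_a, n_b) matrix of minimum-image distances between two point sets."""
    a = np.asarray(coords_a, dtype=float)[:, None, :]
    b = np.asarray(coords_b, dtype=float)[None, :, :]
    return minimum_image_distance(a, b, L)


def brute_force_pairs(coords: np.ndarray, cutoff: float, L: float) -> np.ndarray:
    """All unordered pairs (i < j) with minimum-image distance ≤ cutoff.

    O(N²); reference implementation used as the oracle for the cell list.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        return np.zeros((0, 2), dtype=int)
    dist = pairwise_distances(coords, coords, L)
    iu, ju = np.triu_indices(n, k=1)
    mask = dist[iu, ju] <= cutoff
    return np.column_stack([iu[mask], ju[mask]])


def neighbour_pairs(coords: np.ndarray, cutoff: float, L: float) -> np.ndarray:
    """All unordered pairs within ``cutoff`` using a cell-list search.

    Identical result set to :func:`brute_force_pairs`, but O(N) for
    homogeneous systems.  Falls back to the all-pairs route when the box
    holds fewer than 3 cells per edge (the cell decomposition would then
    visit image cells twice).

    Raises
    ------
    ValueError
        If ``cutoff`` exceeds L/2 (minimum-image validity limit).
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if cutoff > L / 2:
        raise ValueError(
            f"cutoff {cutoff} Å exceeds half the box edge ({L / 2} Å); "
            "the minimum-image convention is ambiguous beyond L/2"
        )
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    n_cells = int(np.floor(L / cutoff))
    if n < 2:
        return np.zeros((0, 2), dtype=int)
    if n_cells < 3:
        pairs = brute_force_pairs(coords, cutoff, L)
        return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))] if len(pairs) else pairs

    cell_edge = L / n_cells
    wrapped = np.mod(coords, L)
    idx3 = np.minimum((wrapped / cell_edge).astype(int), n_cells - 1)
    flat = (idx3[:, 0] * n_cells + idx3[:, 1]) * n_cells + idx3[:, 2]

    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    # contents[c] = atom indices in cell c
    boundaries = np.searchsorted(sorted_flat, np.arange(n_cells**3 + 1))
    cells_with_atoms = np.unique(sorted_flat)

    offsets = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    )
    pairs: list[np.ndarray] = []
    for c in cells_with_atoms:
        cz = c % n_cells
        cy = (c // n_cells) % n_cells
        cx = c // (n_cells * n_cells)
        members = order[boundaries[c] : boundaries[c + 1]]
        for dx, dy, dz in offsets:
            nx, ny, nz = (
                (cx + dx) % n_cells,
                (cy + dy) % n_cells,
                (cz + dz) % n_cells,
            )
            nc = (nx * n_cells + ny) * n_cells + nz
            if nc < c:
                continue  # each cell pair visited once
            others = order[boundaries[nc] : boundaries[nc + 1]]
            if others.size == 0:
                continue
            if nc == c:
                if members.size < 2:
                    continue
                d = pairwise_distances(wrapped[members], wrapped[members], L)
                iu, ju = np.triu_indices(members.size, k=1)
                ok = d[iu, ju] <= cutoff
                pairs.append(
                    np.column_stack([members[iu[ok]], members[ju[ok]]])
                )
            else:
                d = pairwise_distances(wrapped[members], wrapped[others], L)
                ii, jj = np.nonzero(d <= cutoff)
                pairs.append(np.column_stack([members[ii], others[jj]]))
    if not pairs:
        return np.zeros((0, 2), dtype=int)
    out = np.concatenate(pairs)
    lo = np.minimum(out[:, 0], out[:, 1])
    hi = np.maximum(out[:, 0], out[:, 1])
    out = np.unique(np.column_stack([lo, hi]), axis=0)
    return out
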