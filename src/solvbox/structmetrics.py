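"""Structural metrics: superposition/RMSD, distance traces, transitions.

Quaternary transitions of a tetramer show up as plateau shifts in
inter-residue distance traces (e.g. the Cα–Cα separation of the two
C-terminal histidines, which moves from ~30.9 Å in the tense state to
~12.6 Å in relaxed-like structures).  ``detect_transitions`` finds such
shifts with penalized binary segmentation: a change point is accepted
while splitting a segment reduces its within-segment squared deviation
by more than a penalty, defaulting to the BIC-like 3·σ̂²·log(n) with the
noise scale σ̂ estimated robustly from first differences.

RMSD uses the optimal least-squares rigid superposition (Kabsch, via
SVD with reflection rejection); structure pairs are matched on the
(chain, residue number) intersection of their Cα atoms, and unmatched
residues are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Structure, TimeSeries, Trajectory


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of B onto A and the resulting RMSD.

    The transform maps B as x → rotation·(x − centroid_B) + centroid_A;
    the rotation is proper (det = +1).
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    dropped: list = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TransitionSet:
    """Detected change points (ns) with per-segment means and parameters."""

    change_points_ns: np.ndarray
    segment_means: np.ndarray
    penalty: float
    min_segment: int

    def __len__(self) -> int:
        return len(self.change_points_ns)


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    pairing: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of B onto A.

    ``pairing``, when given, is an (m, 2) index array pairing rows of A
    with rows of B; otherwise rows are paired positionally.  At least 3
    non-collinear pairs are required.  Reflections are rejected: the
    returned rotation always has determinant +1.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if pairing is not None:
        pairing = np.asarray(pairing, dtype=int)
        A = A[pairing[:, 0]]
        B = B[pairing[:, 1]]
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"paired coordinate sets must be (m, 3); got {A.shape}, {B.shape}")
    m = A.shape[0]
    if m < 3:
        raise ValueError(f"need ≥ 3 paired atoms, got {m}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 → the geometry does not pin down a rotation
    if np.sum(S > S[0] * 1e-10) < 2:
        raise ValueError("degenerate (collinear or coincident) coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = A0 - B0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=ca - R @ cb, rmsd=rmsd, n_atoms=m
    )


def pair_calpha(
    struct_a: Structure, struct_b: Structure
) -> tuple[np.ndarray, np.ndarray, list]:
    """Match Cα atoms of two structures on (chain, residue number).

    Returns the two (m, 3) coordinate arrays in matched order and the
    list of (chain, resid) keys present in only one structure (dropped).
    """
    def calpha_map(s: Structure) -> dict:
        return {
            (a.chain, a.resid): a.position for a in s.atoms if a.name == "CA"
        }

    ma, mb = calpha_map(struct_a), calpha_map(struct_b)
    common = [k for k in ma if k in mb]
    dropped = sorted(set(ma) ^ set(mb))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} shared Cα positions; cannot superpose"
        )
    A = np.array([ma[k] for k in common])
    B = np.array([mb[k] for k in common])
    return A, B, dropped


def structure_rmsd(struct_a: Structure, struct_b: Structure) -> SuperpositionResult:
    """Cα RMSD between two structures after optimal superposition."""
    A, B, dropped = pair_calpha(struct_a, struct_b)
    result = kabsch_rmsd(A, B)
    result.dropped = dropped
    return result


def residue_pair_distance(
    obj: Structure | Trajectory,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
) -> float | TimeSeries:
    """Distance between two named atoms, per frame for a trajectory.

    Atoms are addressed as (chain, residue number, atom name).  No
    minimum-image wrapping is applied: the intended use is intra-protein
    pairs whose molecule is kept whole (center-of-mass restrained).
    """
    def locate(atoms, key):
        chain, resid, name = key
        for i, a in enumerate(atoms):
            if a.chain == chain and a.resid == resid and a.name == name:
                return i
        raise KeyError(f"cannot resolve atom (chain={chain!r}, resid={resid}, name={name!r})")

    if isinstance(obj, Structure):
        i, j = locate(obj.atoms, atom_a), locate(obj.atoms, atom_b)
        coords = obj.coords
        return float(np.linalg.norm(coords[i] - coords[j]))
    if obj.atoms is None:
        raise ValueError("trajectory has no atom metadata to resolve names against")
    i, j = locate(obj.atoms, atom_a), locate(obj.atoms, atom_b)
    disp = obj.frames[:, i, :] - obj.frames[:, j, :]
    values = np.linalg.norm(disp, axis=1)
    return TimeSeries(
        times=obj.times_ps / 1000.0,
        values=values,
        label=f"{atom_a}-{atom_b}",
        units="Å",
    )


@dataclass
class ContactResult:
    """Distance series for atom pairs plus the fraction of bound frames."""

    series: list[TimeSeries]
    bound_fraction: np.ndarray
    cutoff: float


def contact_timeseries(
    traj: Trajectory,
    pairs: "list[tuple[tuple[str, int, str], tuple[str, int, str]]]",
    cutoff: float,
) -> ContactResult:
    """Per-pair distance series and fraction of frames within ``cutoff``.

    A contact (e.g. a salt bridge) is "bound" in a frame when the pair
    distance is at most the cutoff.
    """
    if not cutoff >= 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")
    series = [residue_pair_distance(traj, a, b) for a, b in pairs]
    frac = np.array([float(np.mean(s.values <= cutoff)) for s in series])
    return ContactResult(series=series, bound_fraction=frac, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Change-point detection


def detect_transitions(
    series: TimeSeries,
    penalty: float | None = None,
    min_segment: int = 10,
) -> TransitionSet:
    """Penalized binary segmentation on a piecewise-constant-mean model.

    Recursively splits the series at the point that most reduces the
    total within-segment squared deviation, accepting a split only when
    the reduction exceeds ``penalty``.  The default penalty is
    3·σ̂²·log(n) with σ̂ the robust noise scale from first differences
    (median absolute difference / (0.6745·√2)); segments shorter than
    ``min_segment`` samples are never created.  An empty TransitionSet
    (constant series) is a valid result.
    """
    y = np.asarray(series.values, dtype=float)
    n = y.size
    if n < 2 * min_segment:
        raise ValueError(
            f"series of {n} samples is shorter than 2·min_segment = {2 * min_segment}"
        )
    if penalty is None:
        diffs = np.diff(y)
        mad = np.median(np.abs(diffs - np.median(diffs)))
        sigma = mad / (0.6745 * np.sqrt(2.0)) if mad > 0 else float(np.std(diffs)) / np.sqrt(2.0)
        penalty = 3.0 * sigma**2 * np.log(n)
        if penalty == 0.0:
            penalty = 1e-12  # noiseless series: any true step still exceeds this
    cps = sorted(_binseg(y, 0, n, float(penalty), min_segment))
    edges = [0, *cps, n]
    means = np.array([float(y[a:b].mean()) for a, b in zip(edges[:-1], edges[1:])])
    return TransitionSet(
        change_points_ns=series.times[np.array(cps, dtype=int)]
        if cps
        else np.array([]),
        segment_means=means,
        penalty=float(penalty),
        min_segment=min_segment,
    )


def _binseg(y: np.ndarray, lo: int, hi: int, penalty: float, min_seg: int) -> list[int]:
    """Best-first recursive segmentation of y[lo:hi); returns split indices."""
    split, gain = _best_split(y, lo, hi, min_seg)
    if split is None or gain <= penalty:
        return []
    return (
        _binseg(y, lo, split, penalty, min_seg)
        + [split]
        + _binseg(y, split, hi, penalty, min_seg)
    )


def _best_split(
    y: np.ndarray, lo: int, hi: int, min_seg: int
) -> tuple[int | None, float]:
    """Split of y[lo:hi) maximizing the SSE reduction, honouring min_seg.

    Uses the identity SSE(total) − SSE(left) − SSE(right)
    = n_l·n_r/(n_l+n_r) · (mean_l − mean_r)², evaluated for every
    admissible split from cumulative sums.
    """
    seg = y[lo:hi]
    n = seg.size
    if n < 2 * min_seg:
        return None, 0.0
    csum = np.cumsum(seg)
    total = csum[-1]
    k = np.arange(min_seg, n - min_seg + 1)  # left part sizes
    left_mean = csum[k - 1] / k
    right_mean = (total - csum[k - 1]) / (n - k)
    gains = k * (n - k) / n * (left_mean - right_mean) ** 2
    best = int(np.argmax(gains))
    return lo + int(k[best]), float(gains[best])
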