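"""Core domain types for solvent-box diagnostics.

Unit conventions used throughout the package:

* coordinates and box edges in ångström (Å),
* the trajectory time step ``dt`` in picoseconds (ps),
* time axes of reported series in nanoseconds (ns),
* diffusion coefficients in cm²/s at the API boundary
  (1 cm²/s = 1e4 Å²/ps, see :data:`CM2_PER_S_IN_A2_PER_PS`).

Boxes are cubic; analyses that require periodicity take the edge length
``L`` from the :class:`Trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

#: 1 cm²/s expressed in Å²/ps (1e16 Å² per cm², 1e12 ps per s).
CM2_PER_S_IN_A2_PER_PS = 1.0e4

#: Boltzmann constant, J/K.
KB_J_PER_K = 1.380649e-23

#: Residue names recognised as water by default (configurable per call).
WATER_RESNAMES = frozenset({"HOH", "TIP3", "SOL", "WAT"})


def cm2_per_s_to_A2_per_ps(d: float) -> float:
    """Convert a diffusion coefficient from cm²/s to Å²/ps."""
    return float(d) * CM2_PER_S_IN_A2_PER_PS


def A2_per_ps_to_cm2_per_s(d: float) -> float:
    """Convert a diffusion coefficient from Å²/ps to cm²/s."""
    return float(d) / CM2_PER_S_IN_A2_PER_PS


@dataclass
class Atom:
    """A single atom record: metadata plus Cartesian coordinates in Å."""

    name: str
    element: str
    resname: str
    resid: int
    chain: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """A static atomic model: an ordered atom table with an identifier.

    Invariants: all coordinates are finite, and the
    (chain, resid, atom name) triple is unique across the table.
    """

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("structure contains non-finite coordinates")
        keys = [(a.chain, a.resid, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(
                        f"duplicate atom key (chain, resid, name) = {k!r}"
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    @property
    def chains(self) -> list[str]:
        """Distinct chain identifiers, in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def find_atom(self, chain: str, resid: int, name: str) -> int:
        """Index of the atom with the given (chain, resid, name) key."""
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resid == resid and a.name == name:
                return i
        raise KeyError(
            f"no atom with chain={chain!r} resid={resid} name={name!r}"
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames in a periodic cubic box.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, N, 3)
        Coordinates in Å.  Whether they are wrapped into the box or
        unwrapped (continuous) is recorded in ``wrapped``; displacement
        analyses refuse wrapped input.
    box : float
        Cubic box edge L in Å.
    dt : float
        Time between stored frames, ps.
    atoms : list of Atom, optional
        Per-atom metadata (same order as the coordinate axis); anonymous
        trajectories carry none.
    wrapped : bool
        True if coordinates have been folded into [0, L).
    metadata : dict
        Free-form provenance; synthetic generators record their ground
        truth (true D, planted counts, shell radii, seed) here.
    """

    frames: np.ndarray
    box: float
    dt: float
    atoms: list[Atom] | None = None
    wrapped: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must have shape (n_frames, N, 3), got {self.frames.shape}"
            )
        if not self.box > 0:
            raise ValueError(f"box edge must be positive, got {self.box}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.atoms is not None and len(self.atoms) != self.n_atoms:
            raise ValueError(
                f"{len(self.atoms)} atom records for {self.n_atoms} coordinates"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def wrap(self) -> "Trajectory":
        """Return a copy with coordinates folded into [0, L)³."""
        return replace(
            self,
            frames=np.mod(self.frames, self.box),
            wrapped=True,
            metadata=dict(self.metadata),
        )


@dataclass
class TimeSeries:
    """A labelled scalar time series; times in ns, strictly increasing."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Selection:
    """A predicate over atom metadata that resolves to a stable index list.

    Any combination of fields may be constrained; ``None`` means "match
    anything".  ``resolve`` returns indices in atom-table order, so the
    same Selection applied to the same Structure/Trajectory always yields
    the same ordered list.
    """

    chain: str | None = None
    resid: int | None = None
    resname: str | None = None
    resnames: frozenset[str] | None = None
    name: str | None = None
    element: str | None = None
    predicate: Callable[[Atom], bool] | None = None

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.resid is not None and atom.resid != self.resid:
            return False
        if self.resname is not None and atom.resname != self.resname:
            return False
        if self.resnames is not None and atom.resname not in self.resnames:
            return False
        if self.name is not None and atom.name != self.name:
            return False
        if self.element is not None and atom.element != self.element:
            return False
        if self.predicate is not None and not self.predicate(atom):
            return False
        return True

    def resolve(self, obj: Structure | Trajectory) -> np.ndarray:
        """Ordered indices of matching atoms.

        A Trajectory without atom metadata matches every index (the
        common case for anonymous synthetic water)."""
        atoms = obj.atoms if isinstance(obj, Structure) else obj.atoms
        if atoms is None:
            if isinstance(obj, Trajectory) and self._is_trivial():
                return np.arange(obj.n_atoms)
            raise ValueError(
                "cannot resolve a constrained Selection on a trajectory "
                "without atom metadata"
            )
        return np.array(
            [i for i, a in enumerate(atoms) if self.matches(a)], dtype=int
        )

    def _is_trivial(self) -> bool:
        return all(
            v is None
            for v in (
                self.chain,
                self.resid,
                self.resname,
                self.resnames,
                self.name,
                self.element,
                self.predicate,
            )
        )


def water_selection(resnames: Iterable[str] = WATER_RESNAMES) -> Selection:
    """Selection for water oxygen atoms by residue name (O atoms only)."""
    names = frozenset(resnames)
    return Selection(resnames=names, element="O")
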