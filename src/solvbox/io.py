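"""Readers and writers for structures, trajectories and time series.

Supported formats
-----------------
* PDB (ATOM/HETATM/TER subset, read and write; delegated to gemmi so
  author chain ids and residue numbers are preserved verbatim),
* multi-frame XYZ with a ``box=<L> dt=<dt>`` comment-line convention —
  the canonical plain-text fixture format of this package,
* DCD/XTC (read only, via MDAnalysis when installed),
* two-column CSV (time_ns, value) for :class:`~solvbox.model.TimeSeries`.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Atom, Structure, TimeSeries, Trajectory


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a :class:`Structure`.

    Atoms are returned in file order with author chain ids and residue
    numbers; records the model does not represent (ANISOU, REMARK, ...)
    are ignored.  Only the first MODEL of a multi-model file is read.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) == 0:
        raise ValueError(f"{path} contains no ATOM/HETATM records")
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        resname=residue.name,
                        resid=residue.seqid.num,
                        chain=chain.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise ValueError(f"{path} contains no ATOM/HETATM records")
    return Structure(atoms=atoms, title=st.name or path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as minimal PDB (ATOM/HETATM + TER records)."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.title
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        if a.chain not in chain_map:
            chain_map[a.chain] = gemmi.Chain(a.chain)
        chain = chain_map[a.chain]
        if (
            len(chain) == 0
            or chain[-1].seqid.num != a.resid
            or chain[-1].name != a.resname
        ):
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        chain[-1].add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Multi-frame XYZ

_XYZ_META_RE = re.compile(r"(\w+)=([-+0-9.eE]+)")


def write_xyz(traj: Trajectory, path: str | Path, precision: int = 6) -> None:
    """Write a trajectory as multi-frame XYZ.

    The comment line of every frame carries ``box=<L> dt=<dt> frame=<i>``
    so the file round-trips without sidecar information.  The symbol
    column uses each atom's element when metadata is present, otherwise
    ``X``.
    """
    symbols = (
        [a.element or a.name for a in traj.atoms]
        if traj.atoms is not None
        else ["X"] * traj.n_atoms
    )
    fmt = f"{{}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"box={traj.box:g} dt={traj.dt:g} frame={i}\n")
            for sym, (x, y, z) in zip(symbols, frame):
                fh.write(fmt.format(sym, x, y, z))


def read_xyz(path: str | Path, box: float | None = None, dt: float | None = None) -> Trajectory:
    """Read a multi-frame XYZ file.

    ``box`` (Å) and ``dt`` (ps) are taken from the ``box=... dt=...``
    comment-line convention when present, else from the arguments.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path} is empty: not a valid XYZ trajectory")
    frames: list[np.ndarray] = []
    symbols: list[str] | None = None
    meta_box, meta_dt = None, None
    i = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise ValueError(
                f"{path}: line {i + 1}: frame has {n} atoms, previous frames {n_expected}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        for key, val in _XYZ_META_RE.findall(comment):
            if key == "box":
                meta_box = float(val)
            elif key == "dt":
                meta_dt = float(val)
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.empty((n, 3))
        frame_symbols: list[str] = []
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {i + 3 + j}: expected 'symbol x y z', got {line!r}"
                )
            frame_symbols.append(parts[0])
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {i + 3 + j}: malformed coordinate in {line!r}"
                ) from exc
        if symbols is None:
            symbols = frame_symbols
        frames.append(coords)
        i += 2 + n
    use_box = meta_box if meta_box is not None else box
    use_dt = meta_dt if meta_dt is not None else dt
    if use_box is None:
        raise ValueError(f"{path}: no box edge in file and none supplied")
    if use_dt is None:
        use_dt = 1.0
    atoms = None
    if symbols is not None and any(s != "X" for s in symbols):
        atoms = [
            Atom(name=s, element=s, resname="UNK", resid=k + 1, chain="A",
                 x=0.0, y=0.0, z=0.0)
            for k, s in enumerate(symbols)
        ]
    return Trajectory(frames=np.array(frames), box=use_box, dt=use_dt, atoms=atoms)


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    box: float | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read a trajectory, dispatching on ``format`` or the file suffix.

    XYZ is always supported; DCD and XTC require MDAnalysis plus a
    topology-free fixed atom count, and take ``box``/``dt`` from the file
    when it carries them.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz(path, box=box, dt=dt)
    if fmt in ("dcd", "xtc"):
        try:
            import MDAnalysis as mda
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                f"reading {fmt.upper()} requires MDAnalysis"
            ) from exc
        u = mda.Universe(str(path), format=fmt, to_guess=())
        frames = np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)
        file_box = None
        if u.trajectory.ts.dimensions is not None:
            dims = u.trajectory.ts.dimensions
            if dims[0] > 0:
                if not np.allclose(dims[:3], dims[0]):
                    raise ValueError(
                        f"{path}: non-cubic box {dims[:3]}; only cubic boxes are supported"
                    )
                file_box = float(dims[0])
        use_box = file_box if file_box is not None else box
        file_dt = getattr(u.trajectory, "dt", None)
        use_dt = float(file_dt) if file_dt else dt
        if use_box is None:
            raise ValueError(f"{path}: no box information in file and none supplied")
        if use_dt is None:
            raise ValueError(f"{path}: no time step in file and none supplied")
        return Trajectory(frames=frames, box=use_box, dt=use_dt, wrapped=True)
    raise ValueError(f"unsupported trajectory format: {fmt!r}")


# ---------------------------------------------------------------------------
# Time series

def write_timeseries_csv(series: TimeSeries, path: str | Path) -> None:
    """Write a TimeSeries as a two-column CSV (time_ns, value)."""
    df = pd.DataFrame({"time_ns": series.times, series.label or "value": series.values})
    df.to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> TimeSeries:
    """Read a two-column CSV (time_ns, value) into a TimeSeries."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns (time_ns, value)")
    label = str(df.columns[1])
    return TimeSeries(
        times=df.iloc[:, 0].to_numpy(dtype=float),
        values=df.iloc[:, 1].to_numpy(dtype=float),
        label=label,
    )
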