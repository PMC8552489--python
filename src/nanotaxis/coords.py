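"""Coordinate file I/O: GRO (fixed width, nm) and plain XYZ (nm).

GRO reading/writing is delegated to MDAnalysis; the wrapper converts between
this package's nm convention and MDAnalysis' Angstrom internals, handles the
zero-atom edge case, and turns parser failures into :class:`GROParseError`
with the offending line number.  XYZ files are written in nm (one frame per
block) and are the trajectory interchange format.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .system import BeadType, Box, System

__all__ = ["GROParseError", "write_gro", "read_gro", "write_xyz", "read_xyz",
           "write_traj_xyz"]

# canonical bead-type registry used to re-type beads read from disk
_KNOWN_TYPES = {
    "M": BeadType("M", role="monomer", radius=0.335),
    "G": BeadType("G", role="guest", radius=0.315),
    "C": BeadType("C", role="oligomer-core", radius=0.335),
    "T": BeadType("T", role="oligomer-tail", radius=0.335),
    "H": BeadType("H", role="oligomer-head-charged", charge=-1.0, radius=0.335),
    "RB": BeadType("RB", role="receptor-base", frozen=True, radius=0.335),
    "RL": BeadType("RL", role="receptor-linker", radius=0.335),
    "RH": BeadType("RH", role="receptor-head", radius=0.335),
    "ION": BeadType("ION", role="counterion", radius=0.25),
}


class GROParseError(ValueError):
    """Malformed GRO content; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


def _diagnose_gro(path: Path) -> None:
    """Scan a GRO file and raise GROParseError at the first bad line."""
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GROParseError(len(lines) or 1, "file truncated (needs title, count, box)")
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise GROParseError(2, f"atom count is not an integer: {lines[1]!r}")
    if len(lines) < n + 3:
        raise GROParseError(len(lines), f"expected {n} atom lines plus a box line")
    for k in range(n):
        ln = lines[2 + k]
        if len(ln) < 44:
            raise GROParseError(3 + k, "atom line shorter than fixed-width format")
        try:
            float(ln[20:28]), float(ln[28:36]), float(ln[36:44])
        except ValueError:
            raise GROParseError(3 + k, f"unparseable coordinates: {ln[20:44]!r}")
    box_line = lines[2 + n].split()
    if len(box_line) < 3:
        raise GROParseError(3 + n, f"box line needs at least 3 floats: {lines[2 + n]!r}")
    try:
        [float(v) for v in box_line]
    except ValueError:
        raise GROParseError(3 + n, f"unparseable box line: {lines[2 + n]!r}")


def write_gro(path, system: System, title: str = "nanotaxis system") -> None:
    """Write positions (nm, 3 decimals), bead names and box to a GRO file."""
    import MDAnalysis as mda

    path = Path(path)
    n = system.n_beads
    if n == 0:
        box = system.box or Box(1.0, 1.0, 1.0)
        path.write_text(f"{title}\n    0\n   {box.lx:.5f}   {box.ly:.5f}   {box.lz:.5f}\n")
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", list(system.names))
        u.add_TopologyAttr("resnames", ["SYS"])
        u.add_TopologyAttr("resids", [1])
        u.atoms.positions = system.positions * 10.0
        box = system.box or Box(1.0, 1.0, 1.0)
        u.dimensions = [box.lx * 10, box.ly * 10, box.lz * 10, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))
    # MDAnalysis writes its own title; replace it to embed run metadata
    lines = path.read_text().splitlines()
    lines[0] = title
    path.write_text("\n".join(lines) + "\n")


def read_gro(path) -> System:
    """Read a GRO file back into a :class:`System`.

    Bead types are reconstructed from the name registry this package writes
    (unknown names become generic mobile beads); topology and groups live in
    the run configuration, not in GRO.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    txt = path.read_text().splitlines()
    if len(txt) >= 2 and txt[1].strip() == "0":
        vals = [float(v) for v in txt[2].split()[:3]]
        return System(
            positions=np.zeros((0, 3)), types=[],
            type_index=np.zeros(0, dtype=np.intp),
            box=Box(*vals),
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            pos = u.atoms.positions / 10.0
            names = [str(x) for x in u.atoms.names]
            dims = u.dimensions
    except Exception:
        _diagnose_gro(path)  # raises with a line number if it finds the fault
        raise GROParseError(1, "unreadable GRO content")
    _diagnose_gro(path)  # MDAnalysis can be lenient about the box line
    types: list[BeadType] = []
    index: dict[str, int] = {}
    tix = np.zeros(len(names), dtype=np.intp)
    for k, nm in enumerate(names):
        if nm not in index:
            index[nm] = len(types)
            types.append(_KNOWN_TYPES.get(nm, BeadType(nm, role="monomer")))
        tix[k] = index[nm]
    box = Box(dims[0] / 10.0, dims[1] / 10.0, dims[2] / 10.0) if dims is not None else None
    return System(positions=pos.astype(float), types=types, type_index=tix, box=box)


def write_xyz(path, positions: np.ndarray, names, comment: str = "",
              append: bool = False) -> None:
    """Write one XYZ frame (coordinates in nm)."""
    positions = np.asarray(positions)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for nm, (x, y, z) in zip(names, positions):
            fh.write(f"{nm:<5s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def write_traj_xyz(path, trajectory, group: str | None = None) -> None:
    """Write a whole trajectory as multi-frame XYZ (nm)."""
    sys_ = trajectory.system
    idx = sys_.group(group) if group else np.arange(sys_.n_beads)
    names = sys_.names[idx]
    for f, (t, pos) in enumerate(zip(trajectory.times, trajectory.positions)):
        write_xyz(path, pos[idx], names, comment=f"t = {t:.4f} ps", append=f > 0)


def read_xyz(path) -> list[tuple[list[str], np.ndarray, str]]:
    """Read all frames of an XYZ file: [(names, positions nm, comment), ...]."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as err:
            raise ValueError(f"line {k + 1}: expected atom count, got {lines[k]!r}") from err
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        block = lines[k + 2:k + 2 + n]
        if len(block) < n:
            raise ValueError(f"line {k + 1}: truncated frame (expected {n} atoms)")
        names = []
        pos = np.empty((n, 3))
        for i, ln in enumerate(block):
            parts = ln.split()
            names.append(parts[0])
            pos[i] = [float(v) for v in parts[1:4]]
        frames.append((names, pos, comment))
        k += 2 + n
    return frames
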