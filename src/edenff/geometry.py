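"""Dimer geometries and XYZ file I/O.

Geometries are stored in Ångström. A dimer is a pair of monomers; in a
single XYZ frame the monomer split is given as an atom-count prefix
(the first ``n_a`` atoms belong to monomer A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DimerGeometry",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "write_xyz_frames",
]


@dataclass
class DimerGeometry:
    """Two rigid monomers in a fixed relative arrangement.

    Coordinates are (n, 3) arrays in Ångström. ``label`` carries a short
    free-text key (scan family, probed distance, angular index).
    """

    symbols_a: tuple[str, ...]
    coords_a: np.ndarray
    symbols_b: tuple[str, ...]
    coords_b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.symbols_a = tuple(self.symbols_a)
        self.symbols_b = tuple(self.symbols_b)
        self.coords_a = np.asarray(self.coords_a, dtype=float).reshape(len(self.symbols_a), 3)
        self.coords_b = np.asarray(self.coords_b, dtype=float).reshape(len(self.symbols_b), 3)
        if not (np.isfinite(self.coords_a).all() and np.isfinite(self.coords_b).all()):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols_a) + len(self.symbols_b)

    @property
    def symbols(self) -> tuple[str, ...]:
        return self.symbols_a + self.symbols_b

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([self.coords_a, self.coords_b])

    def min_intermolecular_distance(self) -> float:
        """Smallest A–B interatomic distance, in Ångström."""
        d = self.coords_a[:, None, :] - self.coords_b[None, :, :]
        return float(np.sqrt((d**2).sum(-1)).min())

    def swapped(self) -> "DimerGeometry":
        return DimerGeometry(self.symbols_b, self.coords_b, self.symbols_a, self.coords_a,
                             label=self.label)

    @classmethod
    def from_frame(cls, symbols, coords, n_a: int, label: str = "") -> "DimerGeometry":
        symbols = tuple(symbols)
        coords = np.asarray(coords, dtype=float)
        if not 0 < n_a < len(symbols):
            raise ValueError(f"monomer split {n_a} out of range for {len(symbols)} atoms")
        return cls(symbols[:n_a], coords[:n_a], symbols[n_a:], coords[n_a:], label=label)


def _parse_frame(lines: list[str], start: int, path: str):
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: line {start + 1}: expected an atom count") from exc
    comment = lines[start + 1].rstrip("\n") if start + 1 < len(lines) else ""
    symbols, coords = [], []
    for i in range(n):
        ln = start + 2 + i
        if ln >= len(lines):
            raise ValueError(f"{path}: line {ln + 1}: unexpected end of file")
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {ln + 1}: expected 'symbol x y z'")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln + 1}: malformed coordinate") from exc
        symbols.append(parts[0])
        coords.append(xyz)
    return symbols, np.array(coords), comment, start + 2 + n


def read_xyz_frames(path) -> list[tuple[list[str], np.ndarray, str]]:
    """Read a (possibly multi-frame) XYZ file: list of (symbols, coords Å, comment)."""
    with open(path) as fh:
        lines = fh.readlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        symbols, coords, comment, i = _parse_frame(lines, i, str(path))
        frames.append((symbols, coords, comment))
    if not frames:
        raise ValueError(f"{path}: no XYZ frames found")
    return frames


def read_xyz(path, n_a: int | None = None):
    """Read the first frame of an XYZ file.

    With ``n_a`` returns a :class:`DimerGeometry` (first ``n_a`` atoms are
    monomer A); without it returns ``(symbols, coords, comment)``.
    """
    symbols, coords, comment = read_xyz_frames(path)[0]
    if n_a is None:
        return symbols, coords, comment
    return DimerGeometry.from_frame(symbols, coords, n_a, label=comment)


def write_xyz(path, symbols, coords, comment: str = "") -> None:
    write_xyz_frames(path, [(symbols, coords, comment)])


def write_xyz_frames(path, frames) -> None:
    with open(path, "w") as fh:
        for symbols, coords, comment in frames:
            coords = np.asarray(coords, dtype=float)
            fh.write(f"{len(symbols)}\n{comment}\n")
            for sym, (x, y, z) in zip(symbols, coords):
                fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")


def write_dimer_frames(path, dimers: list[DimerGeometry]) -> None:
    """Write dimers as a multi-frame XYZ; the comment records 'na=<split> <label>'."""
    frames = [(d.symbols, d.coords, f"na={len(d.symbols_a)} {d.label}".rstrip())
              for d in dimers]
    write_xyz_frames(path, frames)


def read_dimer_frames(path) -> list[DimerGeometry]:
    """Read dimers written by :func:`write_dimer_frames`."""
    dimers = []
    for symbols, coords, comment in read_xyz_frames(path):
        parts = comment.split()
        if not parts or not parts[0].startswith("na="):
            raise ValueError(f"{path}: frame comment lacks the 'na=' monomer split")
        n_a = int(parts[0][3:])
        label = comment[len(parts[0]):].strip()
        dimers.append(DimerGeometry.from_frame(symbols, coords, n_a, label=label))
    return dimers
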