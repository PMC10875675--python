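"""Reference interaction-energy sets for calibration.

A :class:`ReferenceSet` pairs dimer geometries with reference
interaction energies (kJ/mol) and a tag naming the scan family each
configuration came from. On disk a set is a multi-frame XYZ file (the
geometries, with monomer-split comments) plus a delimited table
(config id, energy, tag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DimerGeometry, read_dimer_frames, write_dimer_frames

__all__ = ["RefEntry", "ReferenceSet"]

TAGS = ("oxygen_scan", "hydrogen_scan", "o2_scan", "other")


@dataclass
class RefEntry:
    geometry: DimerGeometry
    energy_kj_mol: float
    tag: str = "other"

    def __post_init__(self):
        if not np.isfinite(self.energy_kj_mol):
            raise ValueError("reference energy must be finite")
        if self.tag not in TAGS:
            raise ValueError(f"unknown tag {self.tag!r}; expected one of {TAGS}")


@dataclass
class ReferenceSet:
    entries: list[RefEntry] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def energies(self) -> np.ndarray:
        return np.array([e.energy_kj_mol for e in self.entries])

    @property
    def geometries(self) -> list[DimerGeometry]:
        return [e.geometry for e in self.entries]

    def permuted(self, order) -> "ReferenceSet":
        return ReferenceSet(entries=[self.entries[i] for i in order],
                            provenance=self.provenance)

    def save(self, xyz_path, table_path) -> None:
        write_dimer_frames(xyz_path, self.geometries)
        df = pd.DataFrame({
            "config_id": np.arange(len(self.entries)),
            "energy_kj_mol": self.energies,
            "tag": [e.tag for e in self.entries],
        })
        with open(table_path, "w") as fh:
            for line in self.provenance.splitlines():
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def load(cls, xyz_path, table_path) -> "ReferenceSet":
        dimers = read_dimer_frames(xyz_path)
        provenance_lines = []
        with open(table_path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                provenance_lines.append(line[1:].strip())
            else:
                body.append(line)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)))
        if len(df) != len(dimers):
            raise ValueError("geometry and energy-table lengths differ")
        entries = [RefEntry(geometry=dimers[int(row.config_id)],
                            energy_kj_mol=float(row.energy_kj_mol), tag=str(row.tag))
                   for row in df.itertuples()]
        return cls(entries=entries, provenance="\n".join(provenance_lines))
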