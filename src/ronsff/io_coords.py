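"""Coordinate file input/output (XYZ and GRO).

Internally everything is in nm.  XYZ files are in Angstrom by
convention and are converted on read/write; GRO files are in nm.
Multi-frame variants return lists of (coords, box) for trajectory
post-processing.  Reading goes through MDAnalysis; writing is plain
text emission.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Conformation

__all__ = [
    "read_xyz",
    "read_gro",
    "read_frames",
    "write_xyz",
    "write_gro",
]

_ANGSTROM_PER_NM = 10.0


def _universe(path):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        return mda.Universe(str(path))


def read_xyz(path, species_id: str = "") -> Conformation:
    """Read a single-frame XYZ file (Angstrom) into nm coordinates."""
    u = _universe(path)
    coords = np.asarray(u.atoms.positions, dtype=float) / _ANGSTROM_PER_NM
    return Conformation(species_id=species_id or Path(path).stem, coords=coords)


def read_gro(path, species_id: str = "") -> Conformation:
    """Read a single-frame GRO file (nm)."""
    u = _universe(path)
    # MDAnalysis reports positions in Angstrom regardless of format
    coords = np.asarray(u.atoms.positions, dtype=float) / _ANGSTROM_PER_NM
    return Conformation(species_id=species_id or Path(path).stem, coords=coords)


def read_frames(path) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """Read all frames of an XYZ/GRO trajectory.

    Returns a list of (coords_nm, box_nm) tuples; box is None when the
    file carries no box information (XYZ).
    """
    u = _universe(path)
    frames = []
    for ts in u.trajectory:
        coords = np.asarray(u.atoms.positions, dtype=float) / _ANGSTROM_PER_NM
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float) / _ANGSTROM_PER_NM
        frames.append((coords, box))
    return frames


def write_xyz(path, conf: Conformation, names: list[str] | None = None,
              comment: str = "") -> None:
    names = names or [f"X{i}" for i in range(conf.n_atoms)]
    lines = [str(conf.n_atoms), comment]
    for name, (x, y, z) in zip(names, conf.coords * _ANGSTROM_PER_NM):
        lines.append(f"{name:<4s} {x:14.8f} {y:14.8f} {z:14.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gro(path, conf: Conformation, names: list[str] | None = None,
              resname: str = "MOL", box: float = 5.0) -> None:
    names = names or [f"X{i}" for i in range(conf.n_atoms)]
    lines = [f"{conf.species_id}", f"{conf.n_atoms:5d}"]
    for i, (name, (x, y, z)) in enumerate(zip(names, conf.coords), start=1):
        lines.append(f"{1:5d}{resname:<5s}{name:>5s}{i:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box:10.5f}{box:10.5f}{box:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")
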