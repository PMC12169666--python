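"""Cartesian/internal-coordinate geometry for single molecules.

Dihedral angles follow the IUPAC sign convention: phi = 0 at the cis
(eclipsed) arrangement, values in (-180, 180], sign flipping under
mirror reflection.  Coordinates are in nm, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .params import MoleculeTopology

__all__ = [
    "Conformation",
    "CollinearityError",
    "measure_distance",
    "measure_angle",
    "measure_dihedral",
    "wrap_angle",
    "place_atom",
    "ZMatrix",
    "build_conformation",
]


class CollinearityError(ValueError):
    """Three reference atoms are (nearly) collinear; frame undefined."""


@dataclass
class Conformation:
    """Cartesian coordinates (nm) of one molecule."""

    species_id: str
    coords: np.ndarray  # (N, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def distance(self, i: int, j: int) -> float:
        return measure_distance(self.coords, i, j)

    def angle(self, i: int, j: int, k: int) -> float:
        return measure_angle(self.coords, i, j, k)

    def dihedral(self, i: int, j: int, k: int, l: int) -> float:
        return measure_dihedral(self.coords, i, j, k, l)


def wrap_angle(phi: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    w = (float(phi) + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def measure_distance(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[j] - coords[i]))


def measure_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def measure_dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in degrees, IUPAC convention (cis = 0)."""
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral requires four distinct atoms")
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise CollinearityError("collinear atoms: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / norm_b2
    phi = np.degrees(np.arctan2(y, x))
    return wrap_angle(phi)


def place_atom(
    pos_j: np.ndarray,
    pos_k: np.ndarray,
    pos_l: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place an atom a with |a-j| = bond, angle(a,j,k) and dihedral(a,j,k,l).

    Standard natural-extension (NeRF) construction.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    e1 = pos_k - pos_j
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise ValueError("coincident reference atoms")
    e1 = e1 / n1
    v = pos_l - pos_k
    n = np.cross(e1, v)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise CollinearityError(
            "reference atoms j, k, l are collinear; dihedral placement undefined"
        )
    n = n / nn
    m = np.cross(n, e1)
    d = (
        np.cos(theta) * e1
        + np.sin(theta) * (np.cos(phi) * m - np.sin(phi) * n)
    )
    return pos_j + bond * d


@dataclass(frozen=True)
class ZEntry:
    """Placement record: atom placed off references (j, k, l)."""

    atom: int
    j: int = -1
    k: int = -1
    l: int = -1
    bond: float = 0.0


@dataclass
class ZMatrix:
    """Internal-coordinate parametrization derived from a bond tree.

    Free variables are the placement angles (atom, j, k) and placement
    dihedrals (atom, j, k, l); bond lengths are fixed at the topology's
    b0 values, which is exactly the rigid-bond convention of the force
    field.  The atom ordering of the bundled topologies guarantees each
    atom after the first is bonded to an earlier one.
    """

    entries: list[ZEntry]
    angle_vars: list[tuple[int, int, int]] = field(default_factory=list)
    dihedral_vars: list[tuple[int, int, int, int]] = field(default_factory=list)

    @classmethod
    def from_topology(cls, top: MoleculeTopology) -> "ZMatrix":
        placed: list[int] = []
        entries: list[ZEntry] = []
        parent: dict[int, int] = {}
        for n in range(top.n_atoms):
            if n == 0:
                entries.append(ZEntry(atom=0))
                placed.append(0)
                continue
            nbrs = [x for x in top.bonded_neighbors(n) if x in placed]
            if not nbrs:
                raise ValueError(
                    f"atom {n} has no previously placed bonded neighbour; "
                    "reorder the topology atoms into tree order"
                )
            j = nbrs[0]
            b0 = top.bond_length(n, j)
            if n == 1:
                entries.append(ZEntry(atom=1, j=j, bond=b0))
            else:
                k = parent.get(j, -1)
                if k < 0 or k == n:
                    cand = [x for x in top.bonded_neighbors(j)
                            if x in placed and x != n]
                    if not cand:
                        cand = [x for x in placed if x not in (n, j)]
                    k = cand[0]
                if n == 2 or len(placed) == 2:
                    entries.append(ZEntry(atom=n, j=j, k=k, bond=b0))
                else:
                    l = parent.get(k, -1)
                    if l in (n, j, k) or l < 0:
                        cand = [x for x in placed if x not in (n, j, k)]
                        # prefer an atom bonded to k, then to j
                        bonded_k = [x for x in cand if x in top.bonded_neighbors(k)]
                        bonded_j = [x for x in cand if x in top.bonded_neighbors(j)]
                        l = (bonded_k or bonded_j or cand)[0]
                    entries.append(ZEntry(atom=n, j=j, k=k, l=l, bond=b0))
            parent[n] = j
            placed.append(n)
        zm = cls(entries=entries)
        for e in entries:
            if e.k >= 0:
                zm.angle_vars.append((e.atom, e.j, e.k))
            if e.l >= 0:
                zm.dihedral_vars.append((e.atom, e.j, e.k, e.l))
        return zm

    # -- variable bookkeeping ------------------------------------------

    @property
    def variables(self) -> list[tuple]:
        return list(self.angle_vars) + list(self.dihedral_vars)

    def dihedral_var_index(self, quad: Sequence[int]) -> int | None:
        """Index (within the dihedral block) of a matching placement
        dihedral, accepting the reversed quadruple (same angle value)."""
        q = tuple(quad)
        for idx, v in enumerate(self.dihedral_vars):
            if v == q or v == q[::-1]:
                return idx
        return None

    # -- conversions ----------------------------------------------------

    def to_cartesian(self, angles_deg: Sequence[float],
                     dihedrals_deg: Sequence[float]) -> np.ndarray:
        n = len(self.entries)
        coords = np.zeros((n, 3))
        ai = di = 0
        for e in self.entries:
            if e.j < 0:
                coords[e.atom] = 0.0
            elif e.k < 0:
                coords[e.atom] = coords[e.j] + np.array([0.0, 0.0, e.bond])
            elif e.l < 0:
                theta = angles_deg[ai]
                ai += 1
                # dummy reference off the j-k axis for the first angle
                dummy = coords[e.k] + np.array([1.0, 0.0, 0.0])
                if abs(np.cross(coords[e.k] - coords[e.j],
                                dummy - coords[e.k])).sum() < 1e-9:
                    dummy = coords[e.k] + np.array([0.0, 1.0, 0.0])
                coords[e.atom] = place_atom(coords[e.j], coords[e.k], dummy,
                                            e.bond, theta, 0.0)
            else:
                theta = angles_deg[ai]
                ai += 1
                phi = dihedrals_deg[di]
                di += 1
                coords[e.atom] = place_atom(coords[e.j], coords[e.k],
                                            coords[e.l], e.bond, theta, phi)
        return coords

    def measure(self, coords: np.ndarray) -> tuple[list[float], list[float]]:
        angles = [measure_angle(coords, *v) for v in self.angle_vars]
        dihedrals = [measure_dihedral(coords, *v) for v in self.dihedral_vars]
        return angles, dihedrals


def _default_internals(top: MoleculeTopology, zm: ZMatrix) -> tuple[list[float], list[float]]:
    """Reference values: force-field theta0 for matching angles,
    109.47 degrees otherwise; 180 degrees (planar/anti) for dihedrals."""
    angles = []
    for (a, j, k) in zm.angle_vars:
        val = 109.47
        for t in top.angles:
            if (t.i, t.j, t.k) in ((a, j, k), (k, j, a)):
                val = t.theta0
                break
        angles.append(val)
    dihedrals = [180.0] * len(zm.dihedral_vars)
    return angles, dihedrals


def build_conformation(
    top: MoleculeTopology,
    internal: Mapping | None = None,
) -> Conformation:
    """Build Cartesian coordinates from internal coordinates.

    ``internal`` may contain ``angles``: {(i,j,k): degrees} and
    ``dihedrals``: {(i,j,k,l): degrees}, keyed by placement tuples of
    the topology's Z-matrix (reversed tuples accepted).  Unspecified
    angles default to the force-field reference values, unspecified
    dihedrals to 180 degrees.  Bond lengths are always the b0 values.
    """
    zm = ZMatrix.from_topology(top)
    angles, dihedrals = _default_internals(top, zm)
    internal = internal or {}
    for key, val in internal.get("angles", {}).items():
        q = tuple(key)
        hit = False
        for idx, v in enumerate(zm.angle_vars):
            if v == q or v == q[::-1]:
                angles[idx] = float(val)
                hit = True
                break
        if not hit:
            raise KeyError(f"angle {q} is not a placement variable "
                           f"(available: {zm.angle_vars})")
    for key, val in internal.get("dihedrals", {}).items():
        idx = zm.dihedral_var_index(tuple(key))
        if idx is None:
            raise KeyError(f"dihedral {tuple(key)} is not a placement variable "
                           f"(available: {zm.dihedral_vars})")
        dihedrals[idx] = float(val)
    coords = zm.to_cartesian(angles, dihedrals)
    return Conformation(species_id=top.species_id, coords=coords)
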