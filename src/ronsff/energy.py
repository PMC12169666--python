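"""Potential-energy evaluation for a single molecule in vacuum.

The functional forms are the GROMOS ones: quartic bond stretching,
cosine-harmonic angle bending, harmonic improper dihedrals, a cosine
series for proper dihedrals (or a Ryckaert-Bellemans polynomial in
cos(phi - 180 deg)), and Lennard-Jones + Coulomb nonbonded terms over
the non-excluded intramolecular pairs.  Third-neighbour (1-4) pairs use
the modified C12 repulsion with full charges; pairs across an RB
dihedral are excluded entirely.  Constrained bonds contribute zero
energy (their stretching constants are placeholders).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_FACTOR
from .geometry import (Conformation, measure_angle, measure_dihedral,
                       measure_distance)
from .params import ForceFieldDB, MoleculeTopology, default_database

__all__ = [
    "EnergyBreakdown",
    "bond_energy",
    "angle_energy",
    "improper_energy",
    "gromos_dihedral_energy",
    "rb_dihedral_energy",
    "pair_nonbonded_energy",
    "molecule_energy",
]


@dataclass
class EnergyBreakdown:
    """Term-by-term decomposition, kJ/mol."""

    bond: float = 0.0
    angle: float = 0.0
    improper: float = 0.0
    proper_dihedral: float = 0.0
    lj_14: float = 0.0
    coulomb_14: float = 0.0
    lj_intra: float = 0.0
    coulomb_intra: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.improper + self.proper_dihedral
                + self.lj_14 + self.coulomb_14
                + self.lj_intra + self.coulomb_intra)


def bond_energy(b: float, b0: float, kb: float, constrained: bool = False) -> float:
    """Quartic GROMOS bond-stretching energy, 1/4 kb (b^2 - b0^2)^2."""
    if constrained:
        return 0.0
    if b <= 0 or b0 <= 0:
        raise ValueError("bond lengths must be positive")
    return 0.25 * kb * (b * b - b0 * b0) ** 2


def angle_energy(theta: float, theta0: float, k_theta: float) -> float:
    """Cosine-harmonic bending energy; angles in degrees."""
    if not 0.0 < theta <= 180.0:
        raise ValueError(f"angle {theta} out of range (0, 180]")
    d = math.cos(math.radians(theta)) - math.cos(math.radians(theta0))
    return 0.5 * k_theta * d * d


def improper_energy(xi: float, xi0: float, k_xi: float) -> float:
    """Harmonic out-of-plane energy; xi in degrees, k_xi per rad^2."""
    d = math.radians((xi - xi0 + 180.0) % 360.0 - 180.0)
    return 0.5 * k_xi * d * d


def gromos_dihedral_energy(phi: float, terms) -> float:
    """Cosine-series torsion, sum_i K_i [1 + cos(m_i phi - phi0_i)]."""
    if not terms:
        raise ValueError("empty dihedral term list")
    e = 0.0
    for t in terms:
        if t.m < 1:
            raise ValueError(f"multiplicity {t.m} < 1")
        e += t.k_phi * (1.0 + math.cos(math.radians(t.m * phi - t.phi0)))
    return e


def rb_dihedral_energy(phi: float, c) -> float:
    """Ryckaert-Bellemans torsion, sum_i C_i cos^i(phi - 180 deg)."""
    if len(c) != 6:
        raise ValueError("RB potential requires six coefficients")
    x = math.cos(math.radians(phi - 180.0))
    e, p = 0.0, 1.0
    for ci in c:
        e += ci * p
        p *= x
    return e


def pair_nonbonded_energy(r: float, c6: float, c12: float,
                          qi: float, qj: float) -> float:
    """LJ + Coulomb energy of one pair at separation r (nm)."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    r6 = r ** 6
    return c12 / (r6 * r6) - c6 / r6 + COULOMB_FACTOR * qi * qj / r


def _pair_tables(top: MoleculeTopology, db: ForceFieldDB):
    """Precompute (i, j, c6, c12, qq) for 1-4 and full nonbonded pairs."""
    p14, full = [], []
    for (i, j) in sorted(top.pairs14):
        ti, tj = top.atoms[i].type_name, top.atoms[j].type_name
        c6 = db.combine_c6_14(ti, tj)
        c12 = db.combine_c12(ti, tj, "one_four")
        full_qq = top.atoms[i].charge * top.atoms[j].charge
        p14.append((i, j, c6, c12, full_qq))
    for (i, j) in top.nonbonded_pairs():
        ti, tj = top.atoms[i].type_name, top.atoms[j].type_name
        ai, aj = db.atom_type(ti), db.atom_type(tj)
        if ai.lj_null or aj.lj_null:
            c6 = c12 = 0.0
        else:
            c6 = db.combine_c6(ti, tj)
            c12 = db.combine_c12(ti, tj, "normal")
        full.append((i, j, c6, c12, top.atoms[i].charge * top.atoms[j].charge))
    return p14, full


_PAIR_CACHE: dict[tuple, tuple] = {}


def molecule_energy(
    top: MoleculeTopology,
    conf: Conformation,
    db: ForceFieldDB | None = None,
) -> EnergyBreakdown:
    """Evaluate the full intramolecular potential energy."""
    db = db or default_database()
    coords = np.asarray(conf.coords, dtype=float)
    if len(coords) != top.n_atoms:
        raise ValueError(
            f"conformation has {len(coords)} atoms, topology {top.n_atoms}"
        )
    eb = EnergyBreakdown()
    for b in top.bonds:
        r = measure_distance(coords, b.i, b.j)
        eb.bond += bond_energy(r, b.b0, b.kb, constrained=b.constrained)
    for a in top.angles:
        eb.angle += angle_energy(measure_angle(coords, a.i, a.j, a.k),
                                 a.theta0, a.k_theta)
    for t in top.impropers:
        xi = measure_dihedral(coords, t.i, t.j, t.k, t.l)
        eb.improper += improper_energy(xi, t.xi0, t.k_xi)
    for d in top.dihedrals_gromos:
        phi = measure_dihedral(coords, d.i, d.j, d.k, d.l)
        eb.proper_dihedral += gromos_dihedral_energy(phi, d.terms)
    for d in top.dihedrals_rb:
        phi = measure_dihedral(coords, d.i, d.j, d.k, d.l)
        eb.proper_dihedral += rb_dihedral_energy(phi, d.c)

    key = (id(db), top.species_id, top.variant,
           tuple(a.charge for a in top.atoms),
           tuple((a.type_name) for a in top.atoms),
           top.exclusions, top.pairs14)
    tables = _PAIR_CACHE.get(key)
    if tables is None:
        tables = _pair_tables(top, db)
        _PAIR_CACHE[key] = tables
    p14, full = tables
    for (i, j, c6, c12, qq) in p14:
        r = measure_distance(coords, i, j)
        r6 = r ** 6
        eb.lj_14 += c12 / (r6 * r6) - c6 / r6
        eb.coulomb_14 += COULOMB_FACTOR * qq / r
    for (i, j, c6, c12, qq) in full:
        r = measure_distance(coords, i, j)
        r6 = r ** 6
        eb.lj_intra += c12 / (r6 * r6) - c6 / r6
        eb.coulomb_intra += COULOMB_FACTOR * qq / r
    return eb
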