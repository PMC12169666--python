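"""Energy model: term functional forms and whole-molecule assembly.

The whole-molecule check uses an independent brute-force oracle that
re-derives exclusions from the bond graph and sums all terms with its
own arithmetic.
"""

import math
import zlib

import numpy as np
import pytest

from ronsff.constants import COULOMB_FACTOR
from ronsff.energy import (angle_energy, bond_energy,
                           gromos_dihedral_energy, improper_energy,
                           molecule_energy, pair_nonbonded_energy,
                           rb_dihedral_energy)
from ronsff.geometry import (Conformation, build_conformation, measure_angle,
                             measure_dihedral)
from ronsff.params import DihedralTerm

ALL_SPECIES = ["H2O2", "O2", "HO2", "HO", "O3", "N2O4", "NO2", "NO",
               "HOONO", "HNO3", "HNO2", "NO3-", "NO2-", "O2-", "ONOO-"]


class TestTermForms:
    def test_bond_quartic(self):
        assert bond_energy(0.1, 0.1, 1e7) == 0.0
        # 1/4 * 1e7 * (0.11^2 - 0.10^2)^2
        assert bond_energy(0.11, 0.1, 1e7) == pytest.approx(11.025, rel=1e-9)
        assert bond_energy(0.2, 0.1, 1e7, constrained=True) == 0.0
        with pytest.raises(ValueError):
            bond_energy(-0.1, 0.1, 1e7)

    def test_angle_cosine_harmonic(self):
        assert angle_energy(130.22, 130.22, 3772.45) == 0.0
        expect = 0.5 * 3772.45 * (
            math.cos(math.radians(135)) - math.cos(math.radians(130.22))) ** 2
        assert expect == pytest.approx(7.11, abs=0.01)
        assert angle_energy(135.0, 130.22, 3772.45) == pytest.approx(expect)
        with pytest.raises(ValueError):
            angle_energy(181.0, 100.0, 1.0)

    def test_angle_cosine_symmetry(self):
        # cos(theta) = cos(-theta): theta and 360-theta are equivalent
        assert angle_energy(100.0, 60.0, 50.0) == pytest.approx(
            angle_energy(100.0, 60.0, 50.0))

    def test_improper_harmonic_in_radians(self):
        assert improper_energy(0.0, 0.0, 502.08) == 0.0
        assert improper_energy(5.0, 0.0, 502.08) == pytest.approx(
            0.5 * 502.08 * math.radians(5.0) ** 2, rel=1e-12)
        assert improper_energy(5.0, 0.0, 502.08) == pytest.approx(1.912, abs=1e-3)
        assert improper_energy(-5.0, 0.0, 502.08) == pytest.approx(
            improper_energy(5.0, 0.0, 502.08))

    def test_gromos_series(self):
        term = [DihedralTerm(2, 0.0, -42.3)]
        assert gromos_dihedral_energy(90.0, term) == pytest.approx(0.0, abs=1e-12)
        assert gromos_dihedral_energy(0.0, term) == pytest.approx(-84.6)
        assert gromos_dihedral_energy(33.0, [DihedralTerm(3, 0.0, 0.0)]) == 0.0
        with pytest.raises(ValueError):
            gromos_dihedral_energy(0.0, [DihedralTerm(0, 0.0, 1.0)])
        with pytest.raises(ValueError):
            gromos_dihedral_energy(0.0, [])

    def test_rb_h2o2_endpoints(self, h2o2):
        c = h2o2.dihedrals_rb[0].c
        assert rb_dihedral_energy(0.0, c) == pytest.approx(30.4511, abs=1e-4)
        assert rb_dihedral_energy(180.0, c) == pytest.approx(4.5088, abs=1e-4)

    def test_rb_hno3_quarter_turn(self, db):
        c = db.get_topology("HNO3").dihedrals_rb[0].c
        # cos(90 - 180) = 0: only C0 survives
        assert rb_dihedral_energy(90.0, c) == pytest.approx(32.758724, rel=1e-12)

    def test_pair_coulomb_only(self):
        assert pair_nonbonded_energy(0.5, 0.0, 0.0, 0.5, -0.5) == pytest.approx(
            -69.468, abs=1e-3)

    def test_pair_lj_op_op(self, db):
        c6 = db.combine_c6("OP", "OP")
        c12 = db.combine_c12("OP", "OP")
        assert pair_nonbonded_energy(0.3, c6, c12, 0.0, 0.0) == pytest.approx(
            0.246, abs=1e-3)

    def test_pair_decays_to_zero(self):
        assert pair_nonbonded_energy(100.0, 1e-3, 1e-6, 0.0, 0.0) == pytest.approx(
            0.0, abs=1e-12)
        with pytest.raises(ValueError):
            pair_nonbonded_energy(0.0, 1.0, 1.0, 0.0, 0.0)


def test_breakdown_total_is_component_sum(db, hoono):
    conf = build_conformation(hoono, {"dihedrals": {(0, 1, 2, 3): 30.0,
                                                    (1, 2, 3, 4): 60.0}})
    eb = molecule_energy(hoono, conf, db)
    parts = (eb.bond + eb.angle + eb.improper + eb.proper_dihedral
             + eb.lj_14 + eb.coulomb_14 + eb.lj_intra + eb.coulomb_intra)
    assert eb.total == pytest.approx(parts, rel=1e-12)
    # the 1-5 H...O interaction and the two 1-4 pairs are present
    assert eb.coulomb_14 != 0.0
    assert eb.coulomb_intra != 0.0


def test_h2o2_minimum_and_hno3_reference(db, h2o2):
    conf = build_conformation(h2o2, {"dihedrals": {(3, 1, 0, 2): 112.5}})
    assert molecule_energy(h2o2, conf, db).total == pytest.approx(0.0, abs=1e-3)
    top = db.get_topology("HNO3")
    ref = build_conformation(top)  # planar reference at theta0 values
    # the three in-plane reference angles sum to 360.02 deg, so the flat
    # reference retains a ~1e-4 kJ/mol bending residual
    assert molecule_energy(top, ref, db).total == pytest.approx(0.0, abs=1e-3)


def test_h2o2_torsion_extrema(db, h2o2):
    """The peroxide torsion has a skewed minimum near 112.5 deg with a
    shallow trans barrier (4.509) and a high cis barrier (30.451)."""
    from ronsff.conformers import bare_torsion_potential

    v = bare_torsion_potential(h2o2, (2, 0, 1, 3))
    grid = np.arange(0.0, 180.001, 0.01)
    vals = np.array([v(p) for p in grid])
    phi_min = grid[np.argmin(vals)]
    assert phi_min == pytest.approx(112.5, abs=0.1)
    assert v(0.0) == pytest.approx(30.451, abs=1e-3)
    assert v(180.0) == pytest.approx(4.509, abs=1e-3)


def test_hno3_rb_is_c0_sin_squared(db):
    """With C1=C3=C4=C5=0 and C2=-C0 the torsion reduces analytically
    to C0 sin^2(phi - 180)."""
    c = db.get_topology("HNO3").dihedrals_rb[0].c
    for phi in np.arange(-180.0, 180.1, 7.5):
        expect = c[0] * math.sin(math.radians(phi - 180.0)) ** 2
        assert rb_dihedral_energy(phi, c) == pytest.approx(expect, rel=1e-9,
                                                           abs=1e-9)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def _graph_distance(top, i, j):
    adj = {n: set() for n in range(top.n_atoms)}
    for b in top.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    seen, frontier, d = {i}, {i}, 0
    while frontier:
        if j in frontier:
            return d
        d += 1
        frontier = {v for u in frontier for v in adj[u]} - seen
        seen |= frontier
    return math.inf


def brute_force_energy(top, coords, db):
    """Direct sum over all terms and all atom pairs with exclusions
    re-derived from scratch."""
    e = 0.0
    for b in top.bonds:
        if not b.constrained:
            r = float(np.linalg.norm(coords[b.j] - coords[b.i]))
            e += 0.25 * b.kb * (r * r - b.b0 * b.b0) ** 2
    for a in top.angles:
        th = measure_angle(coords, a.i, a.j, a.k)
        e += 0.5 * a.k_theta * (math.cos(math.radians(th))
                                - math.cos(math.radians(a.theta0))) ** 2
    for t in top.impropers:
        xi = measure_dihedral(coords, t.i, t.j, t.k, t.l)
        e += 0.5 * t.k_xi * math.radians(xi - t.xi0) ** 2
    for d in top.dihedrals_gromos:
        phi = measure_dihedral(coords, d.i, d.j, d.k, d.l)
        for t in d.terms:
            e += t.k_phi * (1 + math.cos(math.radians(t.m * phi - t.phi0)))
    for d in top.dihedrals_rb:
        phi = measure_dihedral(coords, d.i, d.j, d.k, d.l)
        x = math.cos(math.radians(phi - 180.0))
        e += sum(ci * x ** n for n, ci in enumerate(d.c))
    rb_central = {frozenset((d.j, d.k)) for d in top.dihedrals_rb}
    raw = db._species_raw.get(top.species_id, {})
    force_excluded = bool(raw.get("exclude_14"))
    for i in range(top.n_atoms):
        for j in range(i + 1, top.n_atoms):
            dist = _graph_distance(top, i, j)
            if dist <= 2:
                continue
            r = float(np.linalg.norm(coords[j] - coords[i]))
            qq = top.atoms[i].charge * top.atoms[j].charge
            ti, tj = top.atoms[i].type_name, top.atoms[j].type_name
            if dist == 3:
                path_central = [frozenset((a, b))
                                for a in top.bonded_neighbors(i)
                                for b in top.bonded_neighbors(j)
                                if frozenset((a, b)) in
                                {frozenset((bb.i, bb.j)) for bb in top.bonds}]
                if any(c in rb_central for c in path_central) or force_excluded:
                    continue
                c6 = db.combine_c6_14(ti, tj)
                c12 = db.combine_c12(ti, tj, "one_four")
            else:
                if db.atom_type(ti).lj_null or db.atom_type(tj).lj_null:
                    c6 = c12 = 0.0
                else:
                    c6 = db.combine_c6(ti, tj)
                    c12 = db.combine_c12(ti, tj)
            e += c12 / r ** 12 - c6 / r ** 6 + COULOMB_FACTOR * qq / r
    return e


@pytest.mark.parametrize("sid", ALL_SPECIES)
def test_oracle_equivalence(db, sid):
    """molecule_energy agrees with pair-enumeration brute force on
    randomly distorted conformations of every species."""
    top = db.get_topology(sid)
    base = build_conformation(top).coords
    rng = np.random.default_rng(zlib.crc32(sid.encode()) % 2**31)
    for _ in range(100):
        coords = base + rng.normal(scale=0.01, size=base.shape)
        got = molecule_energy(top, Conformation(sid, coords), db).total
        want = brute_force_energy(top, coords, db)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


def test_rigid_body_invariance(db, hoono):
    conf = build_conformation(hoono, {"dihedrals": {(0, 1, 2, 3): 25.0,
                                                    (1, 2, 3, 4): 130.0}})
    e0 = molecule_energy(hoono, conf, db).total
    theta = 0.7
    rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                    [math.sin(theta), math.cos(theta), 0],
                    [0, 0, 1.0]])
    moved = conf.coords @ rot.T + np.array([1.0, -2.0, 3.0])
    e1 = molecule_energy(hoono, Conformation("HOONO", moved), db).total
    assert e1 == pytest.approx(e0, rel=1e-9)


def test_atom_count_mismatch(db, hoono):
    with pytest.raises(ValueError):
        molecule_energy(hoono, Conformation("HOONO", np.zeros((3, 3))), db)
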