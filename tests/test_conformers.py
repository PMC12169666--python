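"""Rigid-bond minimization, torsional scans, dihedral fitting."""

import numpy as np
import pytest

from ronsff.conformers import (HOONO_CONFORMER_SPECS, DihedralRestraint,
                               bare_torsion_potential, conformer_table,
                               fit_dihedral_terms, minimize_rigid_bonds,
                               torsion_scan)
from ronsff.energy import molecule_energy
from ronsff.geometry import build_conformation


def test_h2o2_minimizes_to_skewed_conformer(db, h2o2):
    res = minimize_rigid_bonds(h2o2, {"dihedrals": {(3, 1, 0, 2): 60.0}}, db=db)
    assert res.converged
    assert abs(res.dihedrals[(2, 0, 1, 3)]) == pytest.approx(112.5, abs=0.1)
    # bonds stay exactly at their constraint lengths
    for b in h2o2.bonds:
        assert res.conformation.distance(b.i, b.j) == pytest.approx(b.b0,
                                                                    abs=1e-12)


def test_hno3_relaxes_to_planarity(db):
    top = db.get_topology("HNO3")
    res = minimize_rigid_bonds(
        top, {"dihedrals": {(3, 0, 1, 2): 165.0, (4, 3, 0, 1): 160.0}}, db=db)
    assert res.converged
    assert abs(res.conformation.dihedral(1, 0, 3, 4)) == pytest.approx(
        180.0, abs=0.1)
    assert res.conformation.dihedral(0, 1, 2, 3) == pytest.approx(0.0, abs=0.1)
    assert res.energy == pytest.approx(0.0, abs=1e-4)


def test_minimization_trace_never_increases(db, hoono):
    res = minimize_rigid_bonds(
        hoono, {"dihedrals": {(0, 1, 2, 3): 150.0, (1, 2, 3, 4): 120.0}}, db=db)
    assert res.converged
    diffs = np.diff(res.trace)
    assert np.all(diffs <= 1e-9)
    assert res.grad_norm < 1e-6


def test_planar_hoono_starts_are_stationary(db, hoono):
    """All-planar dihedral combinations have exactly zero torsional
    gradient by symmetry, so minimization leaves them planar."""
    for onoo, nooh in [(0.0, 180.0), (180.0, 0.0), (180.0, 180.0)]:
        res = minimize_rigid_bonds(
            hoono, {"dihedrals": {(0, 1, 2, 3): onoo, (1, 2, 3, 4): nooh}},
            db=db)
        assert abs(res.dihedrals[(0, 1, 2, 3)]) == pytest.approx(abs(onoo),
                                                                 abs=1e-6)
        assert abs(res.dihedrals[(1, 2, 3, 4)]) == pytest.approx(abs(nooh),
                                                                 abs=1e-6)


TABLE = {
    # conformer: (dE kJ/mol, |ONOO| deg, |NOOH| deg)
    "cis-cis": (0.0, 0.0, 0.0),
    "cis-gauche": (3.4, 2.5, 50.0),
    "cis-perp": (1.4, 2.1, 90.0),
    "cis-trans": (12.3, 0.0, 180.0),
    "perp-perp": (55.1, 95.0, 100.5),
    "trans-cis": (25.0, 179.7, 0.0),
    "trans-perp": (13.4, 179.5, 105.0),
    "trans-trans": (21.0, 179.7, 180.0),
}


def test_hoono_conformer_table(db, hoono):
    """The eight HOONO conformers reproduce the published relative
    energies within 0.5 kJ/mol and dihedrals within 3 degrees."""
    rows = conformer_table(hoono, HOONO_CONFORMER_SPECS, db)
    assert [r.label for r in rows] == list(TABLE)
    for r in rows:
        de, onoo, nooh = TABLE[r.label]
        assert r.converged, r.label
        assert not r.basin_escape, r.label
        assert r.delta_e == pytest.approx(de, abs=0.5), r.label
        assert abs(r.dihedrals[(0, 1, 2, 3)]) == pytest.approx(onoo, abs=3.0)
        assert abs(r.dihedrals[(1, 2, 3, 4)]) == pytest.approx(nooh, abs=3.0)


def test_basin_escape_is_flagged(db, hoono):
    """A free gauche start drains into the perp well and is flagged."""
    rows = conformer_table(hoono, (
        {"label": "cis-cis",
         "start": {"dihedrals": {(0, 1, 2, 3): 0.0, (1, 2, 3, 4): 0.0}}},
        {"label": "gauche-free",
         "start": {"dihedrals": {(0, 1, 2, 3): -7.5, (1, 2, 3, 4): 53.9}}},
    ), db)
    assert rows[1].basin_escape


def test_restraint_pulls_dihedral(db, hoono):
    r = minimize_rigid_bonds(
        hoono, {"dihedrals": {(0, 1, 2, 3): 0.0, (1, 2, 3, 4): 60.0}},
        restraints=[DihedralRestraint((1, 2, 3, 4), 70.0, k=5e4)], db=db)
    assert r.dihedrals[(1, 2, 3, 4)] == pytest.approx(70.0, abs=1.0)


class TestTorsionScan:
    def test_onoo_torsion_only_gap(self, db):
        top = db.get_topology("ONOO-")
        prof = torsion_scan(top, (0, 1, 2, 3), [0.0, 90.0, 180.0],
                            mode="torsion_only", db=db)
        assert prof.energy[2] - prof.energy[0] == pytest.approx(15.0, abs=1e-9)

    def test_hno2_torsion_only(self, db):
        top = db.get_topology("HNO2")
        v = bare_torsion_potential(top, (0, 1, 2, 3))
        assert v(90.0) == pytest.approx(38.651923, rel=1e-12)
        grid = np.arange(-180.0, 180.1, 0.5)
        vals = np.array([v(p) for p in grid])
        # minima exactly at the planar arrangements
        assert vals.min() == pytest.approx(v(180.0))
        assert v(0.0) < v(90.0)

    def test_scan_matches_energy_component(self, db, hoono):
        prof = torsion_scan(hoono, (1, 2, 3, 4),
                            np.arange(-150.0, 151.0, 30.0), db=db)
        for phi, e in zip(prof.phi, prof.energy):
            conf = build_conformation(
                hoono, {"dihedrals": {(0, 1, 2, 3): 0.0, (1, 2, 3, 4): phi}})
            eb = molecule_energy(hoono, conf, db)
            onoo_part = bare_torsion_potential(hoono, (0, 1, 2, 3))(
                conf.dihedral(0, 1, 2, 3))
            assert eb.proper_dihedral - onoo_part == pytest.approx(e, abs=1e-9)

    def test_full_relaxed_scan_onoo(self, db):
        """Relaxed full-model scan keeps the anion's cis form ~13-15
        kJ/mol below trans."""
        top = db.get_topology("ONOO-")
        prof = torsion_scan(top, (0, 1, 2, 3), [0.0, 60.0, 120.0, 180.0],
                            mode="full_molecule_relaxed", db=db)
        assert not prof.flagged
        gap = prof.energy[-1] - prof.energy[0]
        assert 13.0 <= gap <= 15.0

    def test_bad_grid_rejected(self, db, hoono):
        with pytest.raises(ValueError):
            torsion_scan(hoono, (1, 2, 3, 4), [0.0, 0.0, 10.0], db=db)


class TestFitDihedral:
    GRID = np.arange(-180.0, 180.0, 10.0)

    def test_zero_residual_gives_zero_coefficients(self):
        y = np.zeros_like(self.GRID)
        fit = fit_dihedral_terms(self.GRID, y, y,
                                 {"kind": "gromos", "terms": [(1, 0.0), (2, 0.0)]})
        for t in fit["terms"]:
            assert t["k_phi"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_of_cosine_term(self):
        target = 5.0 * (1.0 + np.cos(np.radians(2 * self.GRID)))
        fit = fit_dihedral_terms(self.GRID, target, np.zeros_like(self.GRID),
                                 {"kind": "gromos", "terms": [(2, 0.0)]})
        assert fit["terms"][0]["k_phi"] == pytest.approx(5.0, rel=1e-9)
        assert fit["rms"] == pytest.approx(0.0, abs=1e-9)

    def test_rb_recovery(self, db):
        c_true = db.get_topology("HNO2").dihedrals_rb[0].c
        from ronsff.energy import rb_dihedral_energy

        target = np.array([rb_dihedral_energy(p, c_true) for p in self.GRID])
        fit = fit_dihedral_terms(self.GRID, target, np.zeros_like(self.GRID),
                                 {"kind": "rb", "order": 5})
        assert np.allclose(fit["c"], c_true, atol=1e-8)

    def test_rank_deficient_basis_raises(self):
        grid = np.array([0.0, 180.0])  # cannot resolve m=1 vs m=3
        with pytest.raises(np.linalg.LinAlgError):
            fit_dihedral_terms(grid, [0.0, 1.0], [0.0, 0.0],
                               {"kind": "gromos",
                                "terms": [(1, 0.0), (3, 0.0)]})

    def test_hoono_nooh_fit_reproduces_minima(self, db, hoono):
        """Fitting the model's own N-O-O-H profile (as a stand-in
        reference) recovers a potential with the perp minimum."""
        v = bare_torsion_potential(hoono, (1, 2, 3, 4))
        target = np.array([v(p) for p in self.GRID])
        fit = fit_dihedral_terms(
            self.GRID, target, np.zeros_like(self.GRID),
            {"kind": "gromos", "terms": [(1, 0.0), (2, 0.0), (3, 0.0), (4, 0.0)]})
        ks = [t["k_phi"] for t in fit["terms"]]
        assert np.allclose(ks, [0.691523, 3.90789, -1.2377, -0.606849],
                           atol=1e-6)
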