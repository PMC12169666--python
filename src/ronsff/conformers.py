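"""Rigid-bond conformer analysis.

Geometry optimization is carried out in internal coordinates: bond
lengths stay exactly at their reference values (the constraint
convention of the force field) while bending angles and dihedrals are
free variables.  For the small (<= 6 atom) molecules in the database
this is an exact, deterministic treatment.  The optimizer is a
quasi-Newton (BFGS) minimizer with central-difference gradients and a
fixed starting point, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .energy import gromos_dihedral_energy, molecule_energy, rb_dihedral_energy
from .geometry import Conformation, ZMatrix, build_conformation, wrap_angle
from .params import ForceFieldDB, MoleculeTopology, default_database

__all__ = [
    "ConformerResult",
    "TorsionProfile",
    "DihedralRestraint",
    "minimize_rigid_bonds",
    "conformer_table",
    "torsion_scan",
    "fit_dihedral_terms",
    "HOONO_CONFORMER_SPECS",
]

#: gradient-norm convergence criterion, kJ mol^-1 deg^-1
GRAD_TOL = 1e-6


@dataclass(frozen=True)
class DihedralRestraint:
    """Harmonic restraint 0.5 k (phi - target)^2 on a dihedral."""

    quad: tuple[int, int, int, int]
    target: float          # degrees
    k: float = 1000.0      # kJ mol^-1 rad^-2

    def energy(self, phi_deg: float) -> float:
        d = math.radians(wrap_angle(phi_deg - self.target))
        return 0.5 * self.k * d * d


@dataclass
class ConformerResult:
    label: str
    conformation: Conformation
    energy: float
    angles: dict[tuple[int, int, int], float]
    dihedrals: dict[tuple[int, int, int, int], float]
    converged: bool
    grad_norm: float       # kJ mol^-1 deg^-1
    n_iter: int = 0
    trace: list[float] = field(default_factory=list)
    delta_e: float | None = None
    basin_escape: bool = False


@dataclass
class TorsionProfile:
    quad: tuple[int, int, int, int]
    phi: np.ndarray        # degrees, strictly increasing
    energy: np.ndarray     # kJ/mol
    mode: str              # "torsion_only" | "full_molecule_relaxed"
    flagged: list[int] = field(default_factory=list)  # non-converged points

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("phi grid must be strictly increasing")
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("profile energies must be finite")


def _measured_internals(top: MoleculeTopology, conf: Conformation):
    angles = {(a.i, a.j, a.k): conf.angle(a.i, a.j, a.k) for a in top.angles}
    dihedrals = {}
    for d in list(top.dihedrals_gromos) + list(top.dihedrals_rb):
        dihedrals[(d.i, d.j, d.k, d.l)] = conf.dihedral(d.i, d.j, d.k, d.l)
    return angles, dihedrals


def minimize_rigid_bonds(
    top: MoleculeTopology,
    start: Conformation | Mapping,
    restraints: Sequence[DihedralRestraint] = (),
    pins: Mapping[tuple, float] | None = None,
    db: ForceFieldDB | None = None,
    label: str = "",
    maxiter: int = 10_000,
) -> ConformerResult:
    """Minimize the molecular energy over angles and dihedrals.

    Bonds are held exactly at their b0 values.  ``start`` is either a
    Conformation or an internal-coordinate mapping accepted by
    :func:`ronsff.geometry.build_conformation`.  ``pins`` fixes selected
    placement dihedrals at given values (removed from the optimization);
    ``restraints`` adds harmonic dihedral penalties on arbitrary
    quadruples.  Non-convergence is reported via the ``converged`` flag,
    never silently.
    """
    db = db or default_database()
    zm = ZMatrix.from_topology(top)
    if isinstance(start, Conformation):
        a0, d0 = zm.measure(start.coords)
    else:
        conf0 = build_conformation(top, start)
        a0, d0 = zm.measure(conf0.coords)
    na = len(a0)
    x0 = np.radians(np.array(list(a0) + list(d0), dtype=float))

    pinned: dict[int, float] = {}
    for quad, val in (pins or {}).items():
        idx = zm.dihedral_var_index(quad)
        if idx is None:
            raise KeyError(f"cannot pin {quad}: not a placement dihedral")
        pinned[na + idx] = math.radians(float(val))
    free = [i for i in range(len(x0)) if i not in pinned]
    for i, v in pinned.items():
        x0[i] = v

    trace: list[float] = []

    def unpack(xf: np.ndarray) -> np.ndarray:
        x = x0.copy()
        x[free] = xf
        return x

    def coords_of(xf: np.ndarray) -> np.ndarray:
        x = unpack(xf)
        return zm.to_cartesian(np.degrees(x[:na]), np.degrees(x[na:]))

    def objective(xf: np.ndarray) -> float:
        coords = coords_of(xf)
        conf = Conformation(top.species_id, coords)
        e = molecule_energy(top, conf, db).total
        for r in restraints:
            e += r.energy(conf.dihedral(*r.quad))
        return e

    def grad(xf: np.ndarray) -> np.ndarray:
        h = 1e-6
        g = np.zeros_like(xf)
        for i in range(len(xf)):
            xp = xf.copy()
            xp[i] += h
            xm = xf.copy()
            xm[i] -= h
            g[i] = (objective(xp) - objective(xm)) / (2 * h)
        return g

    if free:
        res = optimize.minimize(
            objective,
            x0[free],
            jac=grad,
            method="BFGS",
            callback=lambda xk: trace.append(objective(xk)),
            options={"gtol": 1e-8, "maxiter": maxiter},
        )
        xf = res.x
        n_iter = int(res.nit)
    else:
        xf = x0[free]
        n_iter = 0
    gfin = grad(xf) if free else np.zeros(0)
    # report per-degree gradient norm
    gnorm = float(np.max(np.abs(gfin)) * math.pi / 180.0) if free else 0.0
    converged = gnorm < GRAD_TOL

    coords = coords_of(xf)
    conf = Conformation(top.species_id, coords)
    energy = molecule_energy(top, conf, db).total
    angles, dihedrals = _measured_internals(top, conf)
    return ConformerResult(
        label=label,
        conformation=conf,
        energy=energy,
        angles=angles,
        dihedrals=dihedrals,
        converged=converged,
        grad_norm=gnorm,
        n_iter=n_iter,
        trace=trace,
    )


def conformer_table(
    top: MoleculeTopology,
    specs: Sequence[Mapping],
    db: ForceFieldDB | None = None,
    basin_tol: float = 30.0,
) -> list[ConformerResult]:
    """Minimize a list of conformer starts; energies relative to the first.

    Each spec provides ``label``, ``start`` (internal-coordinate mapping
    or Conformation) and optionally ``pins``/``restraints``.  A result
    whose free dihedrals drift more than ``basin_tol`` degrees from the
    start is flagged as a basin escape.
    """
    db = db or default_database()
    results: list[ConformerResult] = []
    for spec in specs:
        start = spec["start"]
        res = minimize_rigid_bonds(
            top,
            start,
            restraints=spec.get("restraints", ()),
            pins=spec.get("pins"),
            db=db,
            label=spec.get("label", ""),
        )
        if isinstance(start, Mapping):
            for quad, val in start.get("dihedrals", {}).items():
                q = tuple(quad)
                got = res.dihedrals.get(q)
                if got is None:
                    got = res.conformation.dihedral(*q)
                if abs(wrap_angle(got - val)) > basin_tol:
                    res.basin_escape = True
        results.append(res)
    e0 = results[0].energy if results else 0.0
    for r in results:
        r.delta_e = r.energy - e0
    return results


#: Characterization protocol of the eight HOONO conformers; atoms are
#: ordered OT(0)-N(1)-OC(2)-OH(3)-H(4), so (0,1,2,3) is the O-N-O-O
#: dihedral and (1,2,3,4) the N-O-O-H dihedral.  Starting internals are
#: the ab initio reference geometries.  The planar conformers (cis-cis,
#: cis-trans, trans-cis, trans-trans) are symmetry-stationary in both
#: dihedrals and minimize freely, as does trans-perp, which is a true
#: minimum of the classical model.  cis-gauche and cis-perp are not
#: separate free minima of the classical surface (the gauche ledge
#: drains into the perp well), so they are characterized with N-O-O-H
#: held at the nominal conformer value; perp-perp likewise is a
#: torsional-ridge structure characterized with O-N-O-O held at 95 deg.
HOONO_CONFORMER_SPECS: tuple[dict, ...] = (
    {"label": "cis-cis",
     "start": {"angles": {(0, 1, 2): 114.3, (1, 2, 3): 113.6, (2, 3, 4): 100.6},
               "dihedrals": {(0, 1, 2, 3): 0.0, (1, 2, 3, 4): 0.0}}},
    {"label": "cis-gauche",
     "start": {"angles": {(0, 1, 2): 114.0, (1, 2, 3): 111.9, (2, 3, 4): 102.0},
               "dihedrals": {(0, 1, 2, 3): -7.5, (1, 2, 3, 4): 53.9}},
     "pins": {(1, 2, 3, 4): 50.0}},
    {"label": "cis-perp",
     "start": {"angles": {(0, 1, 2): 113.9, (1, 2, 3): 109.7, (2, 3, 4): 101.0},
               "dihedrals": {(0, 1, 2, 3): -5.1, (1, 2, 3, 4): 92.0}},
     "pins": {(1, 2, 3, 4): 90.0}},
    {"label": "cis-trans",
     "start": {"angles": {(0, 1, 2): 114.8, (1, 2, 3): 108.5, (2, 3, 4): 95.6},
               "dihedrals": {(0, 1, 2, 3): 0.0, (1, 2, 3, 4): 180.0}}},
    {"label": "perp-perp",
     "start": {"angles": {(0, 1, 2): 109.5, (1, 2, 3): 96.4, (2, 3, 4): 99.7},
               "dihedrals": {(0, 1, 2, 3): 81.9, (1, 2, 3, 4): 100.6}},
     "pins": {(0, 1, 2, 3): 95.0}},
    {"label": "trans-cis",
     "start": {"angles": {(0, 1, 2): 110.3, (1, 2, 3): 106.1, (2, 3, 4): 100.8},
               "dihedrals": {(0, 1, 2, 3): 180.0, (1, 2, 3, 4): 0.0}}},
    {"label": "trans-perp",
     "start": {"angles": {(0, 1, 2): 108.4, (1, 2, 3): 104.7, (2, 3, 4): 100.1},
               "dihedrals": {(0, 1, 2, 3): 176.6, (1, 2, 3, 4): 101.0}}},
    {"label": "trans-trans",
     "start": {"angles": {(0, 1, 2): 108.5, (1, 2, 3): 102.3, (2, 3, 4): 96.8},
               "dihedrals": {(0, 1, 2, 3): 180.0, (1, 2, 3, 4): 180.0}}},
)


def bare_torsion_potential(top: MoleculeTopology,
                           quad: Sequence[int]) -> Callable[[float], float]:
    """The molecule's torsional potential on one quadruple, as a function
    of the dihedral angle in degrees (all matching terms summed)."""
    q = tuple(quad)
    terms = []
    for d in top.dihedrals_gromos:
        if (d.i, d.j, d.k, d.l) in (q, q[::-1]):
            terms.append(("g", d.terms))
    for d in top.dihedrals_rb:
        if (d.i, d.j, d.k, d.l) in (q, q[::-1]):
            terms.append(("rb", d.c))
    if not terms:
        raise KeyError(f"no proper dihedral on quadruple {q}")

    def v(phi: float) -> float:
        e = 0.0
        for kind, par in terms:
            e += (gromos_dihedral_energy(phi, par) if kind == "g"
                  else rb_dihedral_energy(phi, par))
        return e

    return v


def torsion_scan(
    top: MoleculeTopology,
    quad: Sequence[int],
    grid: Sequence[float],
    mode: str = "torsion_only",
    db: ForceFieldDB | None = None,
    start: Mapping | Conformation | None = None,
) -> TorsionProfile:
    """Scan a dihedral over a grid of angles (degrees).

    ``torsion_only`` evaluates the bare torsional potential;
    ``full_molecule_relaxed`` pins the dihedral at each grid value and
    minimizes all remaining internal degrees of freedom, walking the
    grid with continuation from the previous point.
    """
    db = db or default_database()
    grid = np.asarray(list(grid), dtype=float)
    q = tuple(quad)
    flagged: list[int] = []
    if mode == "torsion_only":
        v = bare_torsion_potential(top, q)
        energies = np.array([v(p) for p in grid])
    elif mode == "full_molecule_relaxed":
        zm = ZMatrix.from_topology(top)
        if zm.dihedral_var_index(q) is None:
            raise KeyError(f"dihedral {q} is not a placement variable")
        energies = np.empty_like(grid)
        current: Conformation | Mapping | None = start
        for n, phi in enumerate(grid):
            if current is None:
                current = {"dihedrals": {q: float(phi)}}
            res = minimize_rigid_bonds(top, current, pins={q: float(phi)}, db=db)
            if not res.converged:
                flagged.append(n)
            energies[n] = res.energy
            current = res.conformation
    else:
        raise ValueError(f"unknown scan mode {mode!r}")
    return TorsionProfile(quad=q, phi=grid, energy=energies,
                          mode=mode, flagged=flagged)


def fit_dihedral_terms(
    grid: Sequence[float],
    target: Sequence[float],
    classical_without_torsion: Sequence[float],
    basis: Mapping,
) -> dict:
    """Least-squares fit of a torsional potential to a residual profile.

    The residual target(phi) - classical_without_torsion(phi) is fitted
    with either a GROMOS cosine series (``basis={"kind": "gromos",
    "terms": [(m, phi0), ...]}``) or an RB polynomial (``basis=
    {"kind": "rb", "order": 5}``).  A constant offset is always part of
    the design and absorbed; for the RB form the offset is reported as
    C0.  Raises on a rank-deficient design for the supplied grid.
    """
    phi = np.asarray(list(grid), dtype=float)
    resid = np.asarray(list(target), dtype=float) - np.asarray(
        list(classical_without_torsion), dtype=float)
    if phi.shape != resid.shape:
        raise ValueError("profiles must share the grid")
    kind = basis["kind"]
    if kind == "gromos":
        terms = [(int(m), float(phi0)) for (m, phi0) in basis["terms"]]
        cols = [np.cos(np.radians(m * phi - phi0)) for (m, phi0) in terms]
    elif kind == "rb":
        order = int(basis.get("order", 5))
        x = np.cos(np.radians(phi - 180.0))
        cols = [x ** i for i in range(1, order + 1)]
    else:
        raise ValueError(f"unknown basis kind {kind!r}")
    design = np.column_stack([np.ones_like(phi)] + cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient dihedral basis for the given grid"
        )
    coef, *_ = np.linalg.lstsq(design, resid, rcond=None)
    fitted = design @ coef
    rms = float(np.sqrt(np.mean((fitted - resid) ** 2)))
    if kind == "gromos":
        # K (1 + cos(...)) contributes K to the constant; report K only.
        ks = coef[1:]
        return {"kind": "gromos",
                "terms": [{"m": m, "phi0": p0, "k_phi": float(k)}
                          for (m, p0), k in zip(terms, ks)],
                "offset": float(coef[0] - np.sum(ks)),
                "rms": rms}
    c = [float(coef[0])] + [float(v) for v in coef[1:]]
    c = (c + [0.0] * 6)[:6]
    return {"kind": "rb", "c": tuple(c), "rms": rms}
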