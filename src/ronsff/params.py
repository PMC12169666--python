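"""Force-field parameter database for reactive oxygen and nitrogen species.

The database bundles the nonbonded atom-type table (with multi-slot C12
repulsion parameters), the per-pair C12 slot-selection matrix, the
modified 1-4 parameters, and the molecular topologies of the 15
parametrized species.  Cross interactions use geometric combination,

    C6(i,j)  = sqrt(C6(i,i)) * sqrt(C6(j,j))
    C12(i,j) = sqrt(C12(i,i)[a]) * sqrt(C12(j,j)[b])

where the slot indices (a, b) are looked up per ordered type pair in
the selection matrix.  Pairs absent from the matrix raise
:class:`UnparametrizedPairError` rather than falling back silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "AtomTypeRecord",
    "AtomRecord",
    "BondTerm",
    "AngleTerm",
    "ImproperTerm",
    "DihedralTerm",
    "ProperDihedralGromos",
    "ProperDihedralRB",
    "MoleculeTopology",
    "ForceFieldDB",
    "UnknownTypeError",
    "UnknownSpeciesError",
    "UnparametrizedPairError",
    "ValidationReport",
    "load_database",
]

VARIANTS = ("53A6", "54A7")


class UnknownTypeError(LookupError):
    """Requested atom type is not in the database."""


class UnknownSpeciesError(LookupError):
    """Requested species is not in the database."""


class UnparametrizedPairError(LookupError):
    """The requested type pair has no C12 selection entry or LJ values."""


@dataclass(frozen=True)
class AtomTypeRecord:
    """One nonbonded atom type with its (multi-slot) LJ parameters."""

    name: str
    mass: float
    sqrt_c6: float
    sqrt_c12: tuple[float, ...]
    sqrt_c6_14: float | None = None
    sqrt_c12_14: float | None = None
    description: str = ""

    @property
    def lj_null(self) -> bool:
        """True for pure-Coulomb sites (polar H, dummies)."""
        return self.sqrt_c6 == 0.0 and all(s == 0.0 for s in self.sqrt_c12)

    @property
    def has_14(self) -> bool:
        return self.sqrt_c6_14 is not None and self.sqrt_c12_14 is not None


@dataclass(frozen=True)
class AtomRecord:
    name: str
    role: str
    type_name: str
    charge: float


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    b0: float
    kb: float = 0.0       # placeholder; bonds are used as constraints
    constrained: bool = True


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    theta0: float         # degrees
    k_theta: float        # kJ/mol (cosine-harmonic form)


@dataclass(frozen=True)
class ImproperTerm:
    i: int
    j: int
    k: int
    l: int
    xi0: float            # degrees
    k_xi: float           # kJ mol^-1 rad^-2


@dataclass(frozen=True)
class DihedralTerm:
    m: int                # multiplicity >= 1
    phi0: float           # degrees, 0 or 180
    k_phi: float          # kJ/mol


@dataclass(frozen=True)
class ProperDihedralGromos:
    i: int
    j: int
    k: int
    l: int
    terms: tuple[DihedralTerm, ...]


@dataclass(frozen=True)
class ProperDihedralRB:
    i: int
    j: int
    k: int
    l: int
    c: tuple[float, float, float, float, float, float]


@dataclass(frozen=True)
class MoleculeTopology:
    """Complete bonded/nonbonded description of one species."""

    species_id: str
    name: str
    formal_charge: int
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondTerm, ...]
    angles: tuple[AngleTerm, ...] = ()
    impropers: tuple[ImproperTerm, ...] = ()
    dihedrals_gromos: tuple[ProperDihedralGromos, ...] = ()
    dihedrals_rb: tuple[ProperDihedralRB, ...] = ()
    exclusions: frozenset[tuple[int, int]] = frozenset()
    pairs14: frozenset[tuple[int, int]] = frozenset()
    variant: str = "53A6"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return sum(a.charge for a in self.atoms)

    def bonded_neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return sorted(out)

    def bond_length(self, i: int, j: int) -> float:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b.b0
        raise KeyError(f"no bond between atoms {i} and {j}")

    def nonbonded_pairs(self) -> list[tuple[int, int]]:
        """All intramolecular pairs that interact at full strength."""
        out = []
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                p = (i, j)
                if p not in self.exclusions and p not in self.pairs14:
                    out.append(p)
        return out


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"{len(self.violations)} violation(s), "
                 f"{len(self.warnings)} warning(s)"]
        lines += [f"VIOLATION: {m}" for m in self.violations]
        lines += [f"warning:   {m}" for m in self.warnings]
        return "\n".join(lines)


def _graph_distances(n: int, bonds: Iterable[BondTerm]) -> dict[tuple[int, int], int]:
    """All-pairs shortest path lengths over the bond graph (BFS)."""
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for b in bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    dist: dict[tuple[int, int], int] = {}
    for src in range(n):
        seen = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = d
                        nxt.append(v)
            frontier = nxt
        for dst, dd in seen.items():
            if src < dst:
                dist[(src, dst)] = dd
    return dist


def build_exclusions(
    n_atoms: int,
    bonds: Sequence[BondTerm],
    dihedrals_gromos: Sequence[ProperDihedralGromos],
    dihedrals_rb: Sequence[ProperDihedralRB],
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """Derive the exclusion and 1-4 pair lists from the bonded graph.

    First and second neighbours are excluded.  A third-neighbour pair is
    a 1-4 pair (modified C12, full charges) when the central bond of the
    connecting path carries a GROMOS-type proper dihedral, and fully
    excluded when it carries an RB dihedral.  Third-neighbour pairs over
    a bond with no proper dihedral default to the 1-4 treatment.
    """
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for b in bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    rb_bonds = {frozenset((d.j, d.k)) for d in dihedrals_rb}

    dist = _graph_distances(n_atoms, bonds)
    excl: set[tuple[int, int]] = set()
    p14: set[tuple[int, int]] = set()
    for (i, j), d in dist.items():
        if d in (1, 2):
            excl.add((i, j))
        elif d == 3:
            centrals = {
                frozenset((a, b))
                for a in adj[i]
                for b in adj[j]
                if b in adj[a] and a != j and b != i
            }
            if centrals & rb_bonds:
                excl.add((i, j))
            else:
                # GROMOS dihedral on the central bond, or no proper
                # dihedral at all: 1-4 treatment either way.
                p14.add((i, j))
    return frozenset(excl), frozenset(p14)


def _as_pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


class ForceFieldDB:
    """Loaded force-field database with combination-rule logic."""

    def __init__(
        self,
        atom_types: Mapping[str, AtomTypeRecord],
        matrix_rows: Mapping[str, dict],
        matrix_columns: Sequence[str],
        species_raw: Mapping[str, dict],
        variant_54a7: Mapping | None = None,
        version: str = "1.0",
    ):
        self.atom_types = dict(atom_types)
        self.matrix_rows = dict(matrix_rows)
        self.matrix_columns = list(matrix_columns)
        self._species_raw = dict(species_raw)
        self.variant_54a7 = dict(variant_54a7 or {})
        self.version = version

    # -- type lookups -------------------------------------------------

    def atom_type(self, name: str) -> AtomTypeRecord:
        try:
            return self.atom_types[name]
        except KeyError:
            raise UnknownTypeError(f"atom type {name!r} is not in the database")

    def _slot(self, rec: AtomTypeRecord, index: int, pair: str) -> float:
        if index < 1 or index > len(rec.sqrt_c12):
            raise UnparametrizedPairError(
                f"pair {pair}: C12 slot {index} of type {rec.name!r} is not defined"
            )
        return rec.sqrt_c12[index - 1]

    def c12_selection(self, type_i: str, type_j: str) -> tuple[int, int]:
        """Slot indices (for type_i, for type_j) from the selection matrix."""
        if type_i in self.matrix_rows and type_j in self.matrix_columns:
            row = self.matrix_rows[type_i]
            col = self.matrix_columns.index(type_j)
            return row["row_slot"][col], row["col_slot"][col]
        if type_j in self.matrix_rows and type_i in self.matrix_columns:
            row = self.matrix_rows[type_j]
            col = self.matrix_columns.index(type_i)
            return row["col_slot"][col], row["row_slot"][col]
        raise UnparametrizedPairError(
            f"no C12 selection entry for pair ({type_i}, {type_j})"
        )

    # -- combination rules --------------------------------------------

    def combine_c6(self, type_i: str, type_j: str) -> float:
        """Geometric-rule dispersion coefficient, kJ mol^-1 nm^6."""
        return self.atom_type(type_i).sqrt_c6 * self.atom_type(type_j).sqrt_c6

    def combine_c12(self, type_i: str, type_j: str, context: str = "normal") -> float:
        """Repulsion coefficient for a type pair, kJ mol^-1 nm^12.

        ``context="normal"`` uses the slot-selection matrix;
        ``context="one_four"`` uses the modified third-neighbour values.
        """
        ti, tj = self.atom_type(type_i), self.atom_type(type_j)
        if context == "normal":
            si, sj = self.c12_selection(type_i, type_j)
            return self._slot(ti, si, f"{type_i}-{type_j}") * self._slot(
                tj, sj, f"{type_i}-{type_j}"
            )
        if context == "one_four":
            if ti.lj_null or tj.lj_null:
                return 0.0
            if not (ti.has_14 and tj.has_14):
                missing = ti.name if not ti.has_14 else tj.name
                raise UnparametrizedPairError(
                    f"type {missing!r} has no 1-4 LJ parameters"
                )
            return ti.sqrt_c12_14 * tj.sqrt_c12_14
        raise ValueError(f"unknown context {context!r}")

    def combine_c6_14(self, type_i: str, type_j: str) -> float:
        ti, tj = self.atom_type(type_i), self.atom_type(type_j)
        if ti.lj_null or tj.lj_null:
            return 0.0
        if not (ti.has_14 and tj.has_14):
            missing = ti.name if not ti.has_14 else tj.name
            raise UnparametrizedPairError(f"type {missing!r} has no 1-4 LJ parameters")
        return ti.sqrt_c6_14 * tj.sqrt_c6_14

    # -- species ------------------------------------------------------

    def list_species(self) -> list[str]:
        return list(self._species_raw.keys())

    def get_topology(self, species_id: str, variant: str = "53A6") -> MoleculeTopology:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        try:
            raw = self._species_raw[species_id]
        except KeyError:
            raise UnknownSpeciesError(
                f"species {species_id!r} is not in the database"
            )
        atoms = tuple(
            AtomRecord(a["name"], a.get("role", a["name"]), a["type"], float(a["charge"]))
            for a in raw["atoms"]
        )
        bonds = tuple(
            BondTerm(b["ij"][0], b["ij"][1], float(b["b0"]),
                     float(b.get("kb", 0.0)), bool(b.get("constrained", True)))
            for b in raw.get("bonds", [])
        )
        angles = tuple(
            AngleTerm(*a["ijk"], float(a["theta0"]), float(a["k_theta"]))
            for a in raw.get("angles", [])
        )
        impropers = tuple(
            ImproperTerm(*t["ijkl"], float(t["xi0"]), float(t["k_xi"]))
            for t in raw.get("impropers", [])
        )
        dihedrals_g = tuple(
            ProperDihedralGromos(
                *d["ijkl"],
                tuple(DihedralTerm(int(t["m"]), float(t["phi0"]), float(t["k_phi"]))
                      for t in d["terms"]),
            )
            for d in raw.get("dihedrals_gromos", [])
        )
        dihedrals_rb = tuple(
            ProperDihedralRB(*d["ijkl"], tuple(float(x) for x in d["c"]))
            for d in raw.get("dihedrals_rb", [])
        )
        for a in atoms:
            self.atom_type(a.type_name)  # raise early on unknown types
        excl, p14 = build_exclusions(len(atoms), bonds, dihedrals_g, dihedrals_rb)
        if raw.get("exclude_14"):
            excl, p14 = excl | p14, frozenset()
        return MoleculeTopology(
            species_id=species_id,
            name=raw.get("name", species_id),
            formal_charge=int(raw.get("formal_charge", 0)),
            atoms=atoms,
            bonds=bonds,
            angles=angles,
            impropers=impropers,
            dihedrals_gromos=dihedrals_g,
            dihedrals_rb=dihedrals_rb,
            exclusions=excl,
            pairs14=p14,
            variant=variant,
        )

    def qm_charges(self, species_id: str) -> dict | None:
        """Provenance metadata: initial electronic-structure charges."""
        raw = self._species_raw.get(species_id)
        if raw is None:
            raise UnknownSpeciesError(f"species {species_id!r} is not in the database")
        return raw.get("qm_charges")

    # -- validation ---------------------------------------------------

    RONS_TYPES = ("OP", "OO", "OQ", "NQ")

    def validate(self) -> ValidationReport:
        rep = ValidationReport()
        self._validate_types(rep)
        self._validate_matrix(rep)
        self._validate_species(rep)
        return rep

    def _validate_types(self, rep: ValidationReport) -> None:
        oxygen_mass, nitrogen_mass = 15.999, 14.007
        for name, rec in self.atom_types.items():
            if rec.mass < 0 or (rec.mass == 0 and name != "DUM"):
                rep.add(f"type {name}: nonpositive mass {rec.mass}")
            if rec.sqrt_c6 < 0:
                rep.add(f"type {name}: negative sqrt(C6)")
            if not rec.lj_null and any(s <= 0 for s in rec.sqrt_c12):
                rep.add(f"type {name}: nonpositive sqrt(C12) slot")
        for name in ("OP", "OO", "OQ"):
            rec = self.atom_types.get(name)
            if rec and rec.mass != oxygen_mass:
                rep.add(f"type {name}: mass {rec.mass} != {oxygen_mass}")
        rec = self.atom_types.get("NQ")
        if rec and rec.mass != nitrogen_mass:
            rep.add(f"type NQ: mass {rec.mass} != {nitrogen_mass}")

    def _validate_matrix(self, rep: ValidationReport) -> None:
        ncol = len(self.matrix_columns)
        for t in self.RONS_TYPES:
            if t not in self.matrix_columns:
                rep.add(f"selection matrix: missing column for {t}")
            if t not in self.matrix_rows:
                rep.add(f"selection matrix: missing row for {t}")
        for row_name, row in self.matrix_rows.items():
            for half in ("row_slot", "col_slot"):
                if len(row[half]) != ncol:
                    rep.add(f"matrix row {row_name}: {half} has wrong length")
                    continue
                for idx in row[half]:
                    if idx not in (1, 2, 3):
                        rep.add(f"matrix row {row_name}: slot index {idx} out of range")
            # indices must point at defined slots where LJ values are bundled
            for col, cname in enumerate(self.matrix_columns):
                crec = self.atom_types.get(cname)
                if crec and row["col_slot"][col] > len(crec.sqrt_c12):
                    rep.add(
                        f"matrix ({row_name},{cname}): column slot "
                        f"{row['col_slot'][col]} undefined for {cname}"
                    )
                rrec = self.atom_types.get(row_name)
                if rrec is None:
                    continue
                if row["row_slot"][col] > len(rrec.sqrt_c12):
                    rep.add(
                        f"matrix ({row_name},{cname}): row slot "
                        f"{row['row_slot'][col]} undefined for {row_name}"
                    )
        missing = [r for r in self.matrix_rows if r not in self.atom_types]
        if missing:
            rep.warn(
                "matrix rows without bundled LJ values (extend from the "
                f"engine's standard tables): {', '.join(sorted(missing))}"
            )
        # symmetry where both orders are resolvable
        for a in self.RONS_TYPES:
            for b in self.RONS_TYPES:
                try:
                    ab = self.combine_c12(a, b)
                    ba = self.combine_c12(b, a)
                except UnparametrizedPairError:
                    rep.add(f"matrix: pair ({a},{b}) unresolvable")
                    continue
                if abs(ab - ba) > 1e-18:
                    rep.add(f"matrix: asymmetric C12 for ({a},{b}): {ab} vs {ba}")
        sel = self.c12_selection("OP", "OQ")
        if sel != (2, 3):
            rep.add(f"matrix: OP-OQ selection {sel} != (2, 3)")

    def _validate_species(self, rep: ValidationReport) -> None:
        for sid in self.list_species():
            try:
                top = self.get_topology(sid)
            except (UnknownTypeError, KeyError) as exc:
                rep.add(f"{sid}: topology build failed: {exc}")
                continue
            if abs(top.net_charge - top.formal_charge) > 1e-6:
                rep.add(
                    f"{sid}: net charge {top.net_charge:+.6f} != "
                    f"formal charge {top.formal_charge:+d}"
                )
            if top.exclusions & top.pairs14:
                rep.add(f"{sid}: exclusion and 1-4 lists overlap")
            for b in top.bonds:
                if b.b0 <= 0:
                    rep.add(f"{sid}: bond ({b.i},{b.j}) has b0 <= 0")
            for a in top.angles:
                if not 0 < a.theta0 <= 180:
                    rep.add(f"{sid}: angle ({a.i},{a.j},{a.k}) theta0 out of range")
            for t in top.impropers:
                if t.k_xi < 0:
                    rep.add(f"{sid}: improper k_xi < 0")
            for d in top.dihedrals_gromos:
                for t in d.terms:
                    if t.m < 1:
                        rep.add(f"{sid}: dihedral multiplicity {t.m} < 1")
            rb_centrals = {frozenset((d.j, d.k)) for d in top.dihedrals_rb}
            g_centrals = {frozenset((d.j, d.k)) for d in top.dihedrals_gromos}
            if rb_centrals & g_centrals:
                rep.add(f"{sid}: GROMOS and RB dihedrals share a central bond")
            # 1-4 pairs must be combinable
            for (i, j) in top.pairs14:
                try:
                    self.combine_c12(top.atoms[i].type_name,
                                     top.atoms[j].type_name, "one_four")
                except UnparametrizedPairError as exc:
                    rep.add(f"{sid}: 1-4 pair ({i},{j}): {exc}")

    # -- mutation helper (for tests / what-if validation) -------------

    def with_charge(self, species_id: str, atom_index: int, charge: float) -> "ForceFieldDB":
        """Copy of the database with one atomic charge replaced."""
        import copy

        raw = copy.deepcopy(self._species_raw)
        raw[species_id]["atoms"][atom_index]["charge"] = charge
        return ForceFieldDB(self.atom_types, self.matrix_rows,
                            self.matrix_columns, raw, self.variant_54a7,
                            self.version)

    def without_matrix_row(self, row_name: str) -> "ForceFieldDB":
        rows = {k: v for k, v in self.matrix_rows.items() if k != row_name}
        return ForceFieldDB(self.atom_types, rows, self.matrix_columns,
                            self._species_raw, self.variant_54a7, self.version)


def _load_yaml(name: str):
    ref = resources.files("ronsff.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_database() -> ForceFieldDB:
    """Load the bundled parameter database."""
    types_raw = _load_yaml("atom_types.yaml")
    matrix_raw = _load_yaml("c12_matrix.yaml")
    mol_raw = _load_yaml("molecules.yaml")
    var_raw = _load_yaml("variant_54a7.yaml")

    atom_types: dict[str, AtomTypeRecord] = {}
    for section in ("rons_types", "standard"):
        for name, rec in types_raw[section].items():
            atom_types[name] = AtomTypeRecord(
                name=name,
                mass=float(rec["mass"]),
                sqrt_c6=float(rec["sqrt_c6"]),
                sqrt_c12=tuple(float(x) for x in rec["sqrt_c12"]),
                sqrt_c6_14=(float(rec["sqrt_c6_14"])
                            if "sqrt_c6_14" in rec else None),
                sqrt_c12_14=(float(rec["sqrt_c12_14"])
                             if "sqrt_c12_14" in rec else None),
                description=rec.get("description", ""),
            )
    species = {s["id"]: s for s in mol_raw["species"]}
    return ForceFieldDB(
        atom_types=atom_types,
        matrix_rows=matrix_raw["rows"],
        matrix_columns=matrix_raw["columns"],
        species_raw=species,
        variant_54a7=var_raw,
    )


_DEFAULT_DB: ForceFieldDB | None = None


def default_database() -> ForceFieldDB:
    """Shared lazily-loaded instance of the bundled database."""
    global _DEFAULT_DB
    if _DEFAULT_DB is None:
        _DEFAULT_DB = load_database()
    return _DEFAULT_DB
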