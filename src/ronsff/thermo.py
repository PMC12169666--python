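"""Thermodynamic post-processing of free-energy and liquid-phase data.

Solvation free energies from thermodynamic integration are obtained by
quadrature of tabulated ensemble-averaged Hamiltonian derivatives,

    dG_solv = -[ int_0^1 <dH/dlambda>_C dlambda
               + int_0^1 <dH/dlambda>_LJ dlambda ],

with the Coulomb and Lennard-Jones decoupling legs integrated on their
own lambda grids.  The heat of vaporization follows from the gas/liquid
interaction-energy gap, dHvap = U_gas - U_liq + RT.  For a solute with
two torsional conformers (cis/trans), the observable hydration free
energy combines the per-conformer values with the gas-phase
isomerization free energy dGi through a two-state thermodynamic cycle:

    dGw = dGw_trans - RT ln[ (1 + exp((-dGi + dGw_trans - dGw_cis)/RT))
                             / (1 + exp(-dGi/RT)) ].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate

from .constants import R_GAS, T_DEFAULT

__all__ = [
    "TIDataset",
    "SolvationResult",
    "ConformerCycleInput",
    "ti_integrate",
    "heat_of_vaporization",
    "torsional_isomerization_dG",
    "conformer_weighted_dGw",
    "read_ti_leg",
]


def _check_leg(lam: np.ndarray, name: str) -> None:
    if lam.ndim != 1 or len(lam) < 2:
        raise ValueError(f"{name} leg needs at least two lambda points")
    if np.any(np.diff(lam) <= 0):
        raise ValueError(f"{name} leg lambdas must be strictly increasing")
    if lam[0] < 0 or lam[-1] > 1:
        raise ValueError(f"{name} leg lambdas must lie in [0, 1]")
    if not (math.isclose(lam[0], 0.0, abs_tol=1e-12)
            and math.isclose(lam[-1], 1.0, abs_tol=1e-12)):
        raise ValueError(f"{name} leg must include both endpoints 0 and 1")


@dataclass
class TIDataset:
    """Tabulated <dH/dlambda> curves for the two decoupling legs."""

    coulomb_lambda: np.ndarray
    coulomb_dhdl: np.ndarray
    lj_lambda: np.ndarray
    lj_dhdl: np.ndarray
    solute: str = ""
    solvent: str = "water"
    temperature: float = T_DEFAULT

    def __post_init__(self):
        self.coulomb_lambda = np.asarray(self.coulomb_lambda, dtype=float)
        self.coulomb_dhdl = np.asarray(self.coulomb_dhdl, dtype=float)
        self.lj_lambda = np.asarray(self.lj_lambda, dtype=float)
        self.lj_dhdl = np.asarray(self.lj_dhdl, dtype=float)
        _check_leg(self.coulomb_lambda, "Coulomb")
        _check_leg(self.lj_lambda, "LJ")
        if len(self.coulomb_lambda) != len(self.coulomb_dhdl):
            raise ValueError("Coulomb leg: lambda/value length mismatch")
        if len(self.lj_lambda) != len(self.lj_dhdl):
            raise ValueError("LJ leg: lambda/value length mismatch")


@dataclass(frozen=True)
class SolvationResult:
    dG_total: float
    dG_coulomb: float
    dG_lj: float


@dataclass(frozen=True)
class ConformerCycleInput:
    dGw_trans: float
    dGw_cis: float
    dGi: float
    T: float = T_DEFAULT


def ti_integrate(dataset: TIDataset, method: str = "trapezoid") -> SolvationResult:
    """Quadrature of the two decoupling legs on their native grids."""
    if method == "trapezoid":
        quad = np.trapezoid
    elif method == "simpson":
        quad = lambda y, x: integrate.simpson(y, x=x)  # noqa: E731
    else:
        raise ValueError(f"unknown quadrature method {method!r}")
    dg_c = -float(quad(dataset.coulomb_dhdl, dataset.coulomb_lambda))
    dg_lj = -float(quad(dataset.lj_dhdl, dataset.lj_lambda))
    return SolvationResult(dG_total=dg_c + dg_lj, dG_coulomb=dg_c, dG_lj=dg_lj)


def heat_of_vaporization(u_gas: float, u_liq: float, T: float = T_DEFAULT) -> float:
    """dHvap = U_gas - U_liq + RT (kJ/mol)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return u_gas - u_liq + R_GAS * T


def _as_potential(potential) -> Callable[[float], float]:
    if callable(potential):
        return potential
    if hasattr(potential, "c"):
        from .energy import rb_dihedral_energy

        return lambda phi: rb_dihedral_energy(phi, potential.c)
    if hasattr(potential, "terms"):
        from .energy import gromos_dihedral_energy

        return lambda phi: gromos_dihedral_energy(phi, potential.terms)
    raise TypeError(
        "potential must be callable, an RB dihedral, or a GROMOS dihedral"
    )


def torsional_isomerization_dG(
    potential,
    mode: str = "minima",
    T: float = T_DEFAULT,
    grid_step: float = 0.01,
) -> float:
    """Trans-to-cis isomerization free energy of a two-basin torsion.

    The cis basin is |phi| < 90 deg, the trans basin the rest.  Mode
    ``minima`` returns V(cis minimum) - V(trans minimum); mode
    ``boltzmann`` returns -RT ln(Z_cis / Z_trans) with Z the Boltzmann
    integral of the bare torsional potential over each basin.
    """
    v = _as_potential(potential)
    phi = np.arange(-180.0 + grid_step, 180.0 + grid_step / 2, grid_step)
    vals = np.array([v(p) for p in phi])
    cis = np.abs(phi) < 90.0
    trans = ~cis
    # two-basin check: each basin minimum must not sit on the 90-degree
    # dividing line (a basin whose best point is the boundary is no basin)
    i_cis = np.argmin(np.where(cis, vals, np.inf))
    i_trans = np.argmin(np.where(trans, vals, np.inf))
    if min(abs(abs(phi[i_cis]) - 90.0), abs(abs(phi[i_trans]) - 90.0)) < 2 * grid_step:
        raise ValueError("potential does not have separate cis/trans basins")
    if mode == "minima":
        return float(vals[i_cis] - vals[i_trans])
    if mode == "boltzmann":
        if T <= 0:
            raise ValueError("temperature must be positive")
        rt = R_GAS * T
        vmin = vals.min()
        w = np.exp(-(vals - vmin) / rt)
        z_cis = np.trapezoid(w[cis], phi[cis])
        # the trans basin wraps around +-180: integrate its two contiguous
        # halves separately to avoid a spurious segment across the cis basin
        lo, hi = phi <= -90.0, phi >= 90.0
        z_trans = np.trapezoid(w[lo], phi[lo]) + np.trapezoid(w[hi], phi[hi])
        return float(-rt * math.log(z_cis / z_trans))
    raise ValueError(f"unknown mode {mode!r}")


def conformer_weighted_dGw(cycle: ConformerCycleInput) -> float:
    """Two-conformer thermodynamic-cycle hydration free energy."""
    if cycle.T <= 0:
        raise ValueError("temperature must be positive")
    rt = R_GAS * cycle.T
    num = 1.0 + math.exp((-cycle.dGi + cycle.dGw_trans - cycle.dGw_cis) / rt)
    den = 1.0 + math.exp(-cycle.dGi / rt)
    return cycle.dGw_trans - rt * math.log(num / den)


def read_ti_leg(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a plain two-column (lambda, <dH/dlambda>) text file."""
    data = np.loadtxt(path, comments=("#", "@"))
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return data[:, 0], data[:, 1]
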