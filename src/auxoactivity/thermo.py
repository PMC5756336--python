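"""Gibbs-energy feasibility of alkane fermentation coupled to methanogenesis.

Evaluates ΔG = ΔG° + RT ln Q for user-replaceable reactions under in-situ
conditions (temperature, pH, concentrations, partial pressures), finds
equilibrium acetate concentrations (ΔG = 0), and maps the pH x acetate
"window of opportunity" in which fermenting hexadecane to acetate and
consuming that acetate by acetoclastic methanogenesis are simultaneously
exergonic.  The bundled defaults are the Dolfing-style reaction set:

* R1  C16H34 + 16 H2O -> 8 CH3COO- + 8 H+ + 17 H2
* R2  4 H2 + 2 HCO3- + H+ -> CH3COO- + 4 H2O  (reductive acetogenesis)
* R1' = R1 + 17/4 R2 — acetate as sole fermentation product (H2-free)
* R3  CH3COO- + H2O -> CH4 + HCO3-  (acetoclastic methanogenesis)

Activity conventions: molar concentrations for aqueous solutes (activity
coefficient 1), partial pressures in atm for gases, activity 1 for water
and the pure hexadecane phase, and a(H+) = 10^-pH.  Formation energies
are tabulated at 298.15 K; at other temperatures ΔG°(T) is obtained from
the Gibbs-Helmholtz relation using the tabulated ΔHf° (van 't Hoff
correction, enthalpies assumed temperature-independent).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import (
    AQUEOUS,
    GAS,
    PURE_LIQUID,
    R_KJ,
    T_STANDARD,
    WATER,
    Conditions,
    Reaction,
    ValidationError,
)

BOTH_FEASIBLE = "both_feasible"
FERMENTATION_ONLY = "fermentation_only"
METHANOGENESIS_ONLY = "methanogenesis_only"
NEITHER = "neither"

_BALANCED_ELEMENTS = ("C", "H", "O")


@dataclass(frozen=True)
class SpeciesData:
    species_id: str
    delta_Gf_standard: float  # kJ/mol at 298.15 K
    delta_Hf_standard: float  # kJ/mol at 298.15 K
    elemental_composition: dict[str, int]
    charge: int


@dataclass(frozen=True)
class FormationEnergyTable:
    species: dict[str, SpeciesData]

    def __getitem__(self, species_id: str) -> SpeciesData:
        try:
            return self.species[species_id]
        except KeyError:
            raise ValidationError(
                f"no formation-energy datum for species {species_id!r}"
            ) from None


@dataclass
class FeasibilityWindow:
    """ΔG surfaces and the joint-exergonic region over a pH x acetate grid."""

    pH_grid: np.ndarray
    acetate_grid: np.ndarray  # mol/L
    fermentation_dg: np.ndarray  # kJ/mol, shape (n_pH, n_acetate)
    methanogenesis_dg: np.ndarray
    window: np.ndarray  # bool
    # per-pH equilibrium acetate (ΔG = 0) for each reaction; NaN if no
    # root inside the acetate grid bounds
    fermentation_boundary: np.ndarray
    methanogenesis_boundary: np.ndarray


def load_formation_energies(path: Optional[str] = None) -> FormationEnergyTable:
    """Load the bundled (or a user-supplied) species table."""
    if path is None:
        raw = json.loads(
            resources.files("auxoactivity.data").joinpath("species.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)
    species = {
        sid: SpeciesData(
            species_id=sid,
            delta_Gf_standard=float(entry["delta_Gf_standard"]),
            delta_Hf_standard=float(entry["delta_Hf_standard"]),
            elemental_composition={
                el: int(n) for el, n in entry["elemental_composition"].items()
            },
            charge=int(entry["charge"]),
        )
        for sid, entry in raw.items()
    }
    return FormationEnergyTable(species=species)


def load_reactions(path: Optional[str] = None) -> dict[str, Reaction]:
    """Load the bundled (or a user-supplied) reaction set, keyed by name."""
    if path is None:
        raw = json.loads(
            resources.files("auxoactivity.data").joinpath("reactions.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)
    reactions = {}
    for entry in raw:
        reactions[entry["name"]] = Reaction(
            name=entry["name"],
            stoichiometry={
                sp: Fraction(coef) for sp, coef in entry["stoichiometry"].items()
            },
            species_phase=dict(entry["species_phase"]),
            reference=entry.get("reference", ""),
        )
    return reactions


def check_balance(reaction: Reaction, table: FormationEnergyTable) -> None:
    """Verify elemental (C, H, O) and charge balance; raise naming the element."""
    for element in _BALANCED_ELEMENTS:
        net = sum(
            nu * table[sp].elemental_composition.get(element, 0)
            for sp, nu in reaction.stoichiometry.items()
        )
        if net != 0:
            raise ValidationError(
                f"reaction {reaction.name} is unbalanced in {element} (net {net})"
            )
    net_charge = sum(
        nu * table[sp].charge for sp, nu in reaction.stoichiometry.items()
    )
    if net_charge != 0:
        raise ValidationError(
            f"reaction {reaction.name} is unbalanced in charge (net {net_charge})"
        )


def standard_delta_g(
    reaction: Reaction, table: FormationEnergyTable, temperature: float = T_STANDARD
) -> float:
    """ΔG°(T) = Σ ν ΔGf°, Gibbs-Helmholtz-corrected away from 298.15 K."""
    dg0 = float(
        sum(nu * table[sp].delta_Gf_standard for sp, nu in reaction.stoichiometry.items())
    )
    if temperature == T_STANDARD:
        return dg0
    dh0 = float(
        sum(nu * table[sp].delta_Hf_standard for sp, nu in reaction.stoichiometry.items())
    )
    ratio = temperature / T_STANDARD
    return ratio * dg0 + (1.0 - ratio) * dh0


def ln_reaction_quotient(reaction: Reaction, conditions: Conditions) -> float:
    """ln Q with the activity conventions described in the module docstring."""
    ln_q = 0.0
    for sp, nu in reaction.stoichiometry.items():
        phase = reaction.species_phase[sp]
        if phase in (WATER, PURE_LIQUID):
            continue
        if sp == "H+":
            activity = 10.0 ** (-conditions.pH)
        elif phase == AQUEOUS:
            if sp not in conditions.concentrations:
                raise ValidationError(
                    f"reaction {reaction.name}: no concentration for aqueous "
                    f"species {sp!r}"
                )
            activity = conditions.concentrations[sp]
        elif phase == GAS:
            if sp not in conditions.partial_pressures:
                raise ValidationError(
                    f"reaction {reaction.name}: no partial pressure for gas {sp!r}"
                )
            activity = conditions.partial_pressures[sp]
        else:  # pragma: no cover - phases validated at construction
            raise ValidationError(f"unknown phase {phase!r}")
        ln_q += float(nu) * math.log(activity)
    return ln_q


def delta_g(
    reaction: Reaction, conditions: Conditions, table: FormationEnergyTable
) -> float:
    """In-situ ΔG (kJ per mole of reaction) = ΔG°(T) + RT ln Q."""
    check_balance(reaction, table)
    dg0 = standard_delta_g(reaction, table, conditions.temperature)
    return dg0 + R_KJ * conditions.temperature * ln_reaction_quotient(
        reaction, conditions
    )


def _delta_g_at_acetate(
    reaction: Reaction,
    conditions: Conditions,
    table: FormationEnergyTable,
    acetate: float,
    species: str,
) -> float:
    return delta_g(
        reaction, conditions.replace(concentrations={species: acetate}), table
    )


def equilibrium_acetate(
    reaction: Reaction,
    conditions: Conditions,
    table: FormationEnergyTable,
    bounds: tuple[float, float] = (1e-12, 10.0),
    species: str = "acetate",
) -> float:
    """Concentration of ``species`` at which ΔG crosses 0.

    ΔG is monotone in ln c whenever the species appears on one side
    only, so the root is unique when it exists.  The search runs in
    ln-concentration space and refines to |ΔG| < 1e-6 kJ/mol; if ΔG has
    the same sign at both bounds the error reports the endpoint values.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValidationError("bounds must satisfy 0 < lower < upper")
    f_lo = _delta_g_at_acetate(reaction, conditions, table, lo, species)
    f_hi = _delta_g_at_acetate(reaction, conditions, table, hi, species)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if (f_lo > 0) == (f_hi > 0):
        raise ValidationError(
            f"no ΔG sign change for {species} in [{lo:g}, {hi:g}] M: "
            f"ΔG({lo:g}) = {f_lo:.6g} kJ/mol, ΔG({hi:g}) = {f_hi:.6g} kJ/mol"
        )

    def f(ln_c: float) -> float:
        return _delta_g_at_acetate(reaction, conditions, table, math.exp(ln_c), species)

    root = brentq(f, math.log(lo), math.log(hi), xtol=1e-15, rtol=8.9e-16)
    conc = math.exp(root)
    residual = _delta_g_at_acetate(reaction, conditions, table, conc, species)
    if abs(residual) >= 1e-6:  # pragma: no cover - brentq at machine precision
        raise ValidationError(
            f"root refinement failed: |ΔG| = {abs(residual):.3g} kJ/mol"
        )
    return conc


def feasibility_window(
    fermentation: Reaction,
    methanogenesis: Reaction,
    table: FormationEnergyTable,
    pH_grid: Sequence[float],
    acetate_grid: Sequence[float],
    conditions_base: Conditions,
    acetate_species: str = "acetate",
) -> FeasibilityWindow:
    """Evaluate both reactions over a pH x acetate grid.

    ``conditions_base`` supplies temperature and the activities of every
    species other than acetate and H+.  The window is the element-wise
    region where both ΔG values are strictly negative; per pH, the ΔG = 0
    boundary concentrations are exported when they fall inside the grid
    bounds (NaN otherwise).
    """
    pH_grid = np.asarray(pH_grid, dtype=float)
    acetate_grid = np.asarray(acetate_grid, dtype=float)
    for grid, label in ((pH_grid, "pH_grid"), (acetate_grid, "acetate_grid")):
        if grid.ndim != 1 or len(grid) < 2 or not np.all(np.diff(grid) > 0):
            raise ValidationError(f"{label} must be strictly increasing")
    n_ph, n_ac = len(pH_grid), len(acetate_grid)
    ferm_dg = np.empty((n_ph, n_ac))
    meth_dg = np.empty((n_ph, n_ac))
    ferm_boundary = np.full(n_ph, np.nan)
    meth_boundary = np.full(n_ph, np.nan)
    bounds = (float(acetate_grid[0]), float(acetate_grid[-1]))
    for i, ph in enumerate(pH_grid):
        cond = conditions_base.replace(pH=float(ph))
        for j, ac in enumerate(acetate_grid):
            point = cond.replace(concentrations={acetate_species: float(ac)})
            ferm_dg[i, j] = delta_g(fermentation, point, table)
            meth_dg[i, j] = delta_g(methanogenesis, point, table)
        for rxn, store in ((fermentation, ferm_boundary), (methanogenesis, meth_boundary)):
            try:
                store[i] = equilibrium_acetate(
                    rxn, cond, table, bounds=bounds, species=acetate_species
                )
            except ValidationError:
                pass  # equilibrium outside the grid; boundary stays NaN
    window = (ferm_dg < 0) & (meth_dg < 0)
    return FeasibilityWindow(
        pH_grid=pH_grid,
        acetate_grid=acetate_grid,
        fermentation_dg=ferm_dg,
        methanogenesis_dg=meth_dg,
        window=window,
        fermentation_boundary=ferm_boundary,
        methanogenesis_boundary=meth_boundary,
    )


def assess_well(
    pH: float,
    acetate: float,
    conditions_base: Conditions,
    fermentation: Reaction,
    methanogenesis: Reaction,
    table: FormationEnergyTable,
    acetate_species: str = "acetate",
) -> str:
    """Classify one well's measured (pH, acetate) by the signs of both ΔG.

    Feasibility is strict (ΔG < 0): a well sitting exactly on a ΔG = 0
    boundary is not feasible for that reaction.
    """
    if acetate <= 0:
        raise ValidationError("acetate concentration must be > 0")
    point = conditions_base.replace(
        pH=pH, concentrations={acetate_species: acetate}
    )
    ferm = delta_g(fermentation, point, table) < 0
    meth = delta_g(methanogenesis, point, table) < 0
    if ferm and meth:
        return BOTH_FEASIBLE
    if ferm:
        return FERMENTATION_ONLY
    if meth:
        return METHANOGENESIS_ONLY
    return NEITHER


def default_conditions(
    temperature: float = T_STANDARD,
    pH: float = 7.0,
    bicarbonate: float = 0.01,
    methane_atm: float = 1.0,
    hydrogen_atm: float = 1e-4,
) -> Conditions:
    """Reference reservoir-water conditions for the bundled reaction set.

    Defaults: 10 mM bicarbonate, 1 atm methane, 10^-4 atm H2, 298.15 K.
    These are explicit configuration, not measurements; replace them with
    site data where available.
    """
    return Conditions(
        temperature=temperature,
        pH=pH,
        concentrations={"HCO3-": bicarbonate, "acetate": 1e-4},
        partial_pressures={"CH4": methane_atm, "H2": hydrogen_atm},
    )
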