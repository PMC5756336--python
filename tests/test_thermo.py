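"""Gibbs-energy evaluation, equilibrium roots, and the feasibility window."""
import math
from fractions import Fraction

import numpy as np
import pytest

from auxoactivity import thermo
from auxoactivity.models import Conditions, R_KJ, Reaction, ValidationError


@pytest.fixture(scope="module")
def table():
    return thermo.load_formation_energies()


@pytest.fixture(scope="module")
def reactions():
    return thermo.load_reactions()


def rich_conditions(pH=7.0, temperature=298.15, acetate=1e-3):
    """Conditions supplying an activity for every bundled species."""
    return Conditions(
        temperature=temperature,
        pH=pH,
        concentrations={"acetate": acetate, "HCO3-": 0.01},
        partial_pressures={"CH4": 1.0, "H2": 1e-4},
    )


class TestBalance:
    def test_every_bundled_reaction_balances(self, table, reactions):
        for reaction in reactions.values():
            thermo.check_balance(reaction, table)  # raises on imbalance

    def test_unbalanced_reaction_names_the_element(self, table):
        bad = Reaction(
            name="bad",
            stoichiometry={"CH4": Fraction(1), "H2O": Fraction(-1)},
            species_phase={"CH4": "gas", "H2O": "water"},
        )
        with pytest.raises(ValidationError, match="C"):
            thermo.check_balance(bad, table)


class TestDeltaG:
    def test_unit_activities_reduce_to_standard_delta_g(self, table, reactions):
        """pH 0, 1 M, 1 atm: Q = 1 so dG equals the formation-energy sum."""
        conditions = Conditions(
            temperature=298.15, pH=0.0,
            concentrations={"acetate": 1.0, "HCO3-": 1.0},
            partial_pressures={"CH4": 1.0, "H2": 1.0},
        )
        for reaction in reactions.values():
            dg = thermo.delta_g(reaction, conditions, table)
            dg0 = sum(
                float(nu) * table[sp].delta_Gf_standard
                for sp, nu in reaction.stoichiometry.items()
            )
            assert dg == pytest.approx(dg0, abs=1e-12)

    def test_acetoclastic_methanogenesis_hand_summation(self, table, reactions):
        """Spreadsheet-style oracle at 298.15 K, pH 7, 1 M / 1 atm: sum the
        bundled formation energies by hand and add RT ln Q term by term."""
        reaction = reactions["acetoclastic_methanogenesis"]
        conditions = Conditions(
            temperature=298.15, pH=7.0,
            concentrations={"acetate": 1.0, "HCO3-": 1.0},
            partial_pressures={"CH4": 1.0},
        )
        # independent arithmetic, outside the code path under test
        dg0 = (
            table["CH4"].delta_Gf_standard
            + table["HCO3-"].delta_Gf_standard
            - table["acetate"].delta_Gf_standard
            - table["H2O"].delta_Gf_standard
        )
        ln_q = (
            math.log(1.0)      # CH4, 1 atm
            + math.log(1.0)    # HCO3-, 1 M
            - math.log(1.0)    # acetate, 1 M
        )                      # water: activity 1; no proton in the reaction
        expected = dg0 + R_KJ * 298.15 * ln_q
        assert thermo.delta_g(reaction, conditions, table) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(-31.01, abs=0.005)

    def test_tenfold_acetate_shifts_dg_by_nu_rt_ln10(self, table, reactions):
        rt_ln10 = R_KJ * 298.15 * math.log(10.0)
        for name, nu_acetate in (
            ("hexadecane_fermentation", 8.0),
            ("hexadecane_to_acetate_net", 12.25),
            ("acetoclastic_methanogenesis", -1.0),
        ):
            reaction = reactions[name]
            base = thermo.delta_g(reaction, rich_conditions(acetate=1e-4), table)
            up = thermo.delta_g(reaction, rich_conditions(acetate=1e-3), table)
            assert up - base == pytest.approx(nu_acetate * rt_ln10, rel=1e-12)

    def test_dg_derivative_in_ln_acetate_is_nu_rt(self, table, reactions):
        """Finite-difference check of d(dG)/d ln[acetate] = nu RT."""
        reaction = reactions["hexadecane_to_acetate_net"]
        c0, h = 1e-3, 1e-6
        up = thermo.delta_g(reaction, rich_conditions(acetate=c0 * math.exp(h)), table)
        down = thermo.delta_g(reaction, rich_conditions(acetate=c0 * math.exp(-h)), table)
        derivative = (up - down) / (2 * h)
        assert derivative == pytest.approx(12.25 * R_KJ * 298.15, rel=1e-6)

    def test_hess_additivity_over_random_rational_combinations(self, table, reactions):
        """dG of a rational combination of reactions equals the same
        combination of their dG values, to 1e-9 kJ/mol, for 100 random
        coefficient pairs."""
        rng = np.random.default_rng(2024)
        base = [reactions["hexadecane_fermentation"], reactions["wl_acetogenesis"]]
        conditions = rich_conditions()
        dg_base = [thermo.delta_g(r, conditions, table) for r in base]
        for k in range(100):
            coefs = [
                Fraction(int(rng.integers(-8, 9)), int(rng.integers(1, 7)))
                for _ in base
            ]
            if all(c == 0 for c in coefs):
                coefs[0] = Fraction(1)
            net = Reaction.linear_combination(list(zip(coefs, base)), f"net{k}")
            expected = sum(float(c) * dg for c, dg in zip(coefs, dg_base))
            assert thermo.delta_g(net, conditions, table) == pytest.approx(
                expected, abs=1e-9
            )

    def test_vant_hoff_correction_recovers_gibbs_helmholtz(self, table, reactions):
        reaction = reactions["acetoclastic_methanogenesis"]
        t = 328.15
        dg0_t = thermo.standard_delta_g(reaction, table, t)
        dh0 = sum(
            float(nu) * table[sp].delta_Hf_standard
            for sp, nu in reaction.stoichiometry.items()
        )
        dg0_298 = thermo.standard_delta_g(reaction, table)
        assert dg0_t == pytest.approx(
            dh0 + (dg0_298 - dh0) * t / 298.15, abs=1e-12
        )


class TestEquilibriumAcetate:
    def closed_form(self, reaction, conditions, table):
        """Algebraic oracle: solve dG0 + RT(ln Q_rest + nu ln c) = 0."""
        rt = R_KJ * conditions.temperature
        dg0 = thermo.standard_delta_g(reaction, table, conditions.temperature)
        nu = float(reaction.stoichiometry["acetate"])
        stripped = Conditions(
            temperature=conditions.temperature, pH=conditions.pH,
            concentrations={**conditions.concentrations, "acetate": 1.0},
            partial_pressures=conditions.partial_pressures,
        )
        ln_q_rest = thermo.ln_reaction_quotient(reaction, stripped)
        return math.exp(-(dg0 / rt + ln_q_rest) / nu)

    def test_root_is_a_fixed_point_of_delta_g(self, table, reactions):
        reaction = reactions["hexadecane_to_acetate_net"]
        conditions = rich_conditions()
        root = thermo.equilibrium_acetate(reaction, conditions, table)
        residual = thermo.delta_g(
            reaction, conditions.replace(concentrations={"acetate": root}), table
        )
        assert abs(residual) < 1e-6

    def test_matches_closed_form_on_random_ph_and_temperature(self, table, reactions):
        rng = np.random.default_rng(11)
        for name in ("hexadecane_to_acetate_net", "acetoclastic_methanogenesis"):
            reaction = reactions[name]
            for _ in range(25):
                conditions = rich_conditions(
                    pH=float(rng.uniform(4.0, 9.0)),
                    temperature=float(rng.uniform(280.0, 360.0)),
                )
                expected = self.closed_form(reaction, conditions, table)
                if not 1e-12 < expected < 10.0:
                    continue
                root = thermo.equilibrium_acetate(
                    reaction, conditions, table, bounds=(1e-12, 10.0)
                )
                assert root == pytest.approx(expected, rel=1e-9)

    def test_fermentation_equilibrium_drops_with_ph(self, table, reactions):
        """The fermentation releases protons, so acid conditions push its
        equilibrium acetate down."""
        reaction = reactions["hexadecane_to_acetate_net"]
        roots = [
            thermo.equilibrium_acetate(reaction, rich_conditions(pH=ph), table)
            for ph in (5.0, 6.0, 7.0, 8.0)
        ]
        assert all(a < b for a, b in zip(roots, roots[1:]))

    def test_no_sign_change_reports_endpoint_values(self, table, reactions):
        reaction = reactions["acetoclastic_methanogenesis"]
        with pytest.raises(ValidationError, match="kJ/mol"):
            thermo.equilibrium_acetate(
                reaction, rich_conditions(), table, bounds=(1e-3, 1.0)
            )


class TestFeasibilityWindow:
    def make_window(self, table, reactions, n_ph=12, n_ac=20):
        return thermo.feasibility_window(
            reactions["hexadecane_to_acetate_net"],
            reactions["acetoclastic_methanogenesis"],
            table,
            np.linspace(4.0, 9.0, n_ph),
            np.logspace(-9, 0, n_ac),
            thermo.default_conditions(),
        )

    def test_window_is_elementwise_joint_exergonicity(self, table, reactions):
        w = self.make_window(table, reactions)
        assert np.array_equal(
            w.window, (w.fermentation_dg < 0) & (w.methanogenesis_dg < 0)
        )

    def test_window_matches_boundary_interval_per_ph(self, table, reactions):
        """At fixed pH, the window over the acetate grid is exactly the
        open interval between the methanogenesis and fermentation
        equilibrium concentrations."""
        w = self.make_window(table, reactions)
        for i in range(len(w.pH_grid)):
            lower = w.methanogenesis_boundary[i]
            upper = w.fermentation_boundary[i]
            for j, ac in enumerate(w.acetate_grid):
                in_interval = (
                    (np.isnan(lower) or ac > lower)
                    and (not np.isnan(upper) and ac < upper)
                )
                if np.isnan(upper):
                    # fermentation equilibrium outside the grid: fall back
                    # to the sign of dG itself
                    in_interval = (
                        w.fermentation_dg[i, j] < 0
                        and (np.isnan(lower) or ac > lower)
                    )
                assert bool(w.window[i, j]) == bool(in_interval)

    def test_window_empty_when_boundaries_cross(self, table, reactions):
        """If the fermentation ceiling sits below the methanogenesis floor
        there is no acetate concentration serving both."""
        w = self.make_window(table, reactions)
        for i in range(len(w.pH_grid)):
            lo, hi = w.methanogenesis_boundary[i], w.fermentation_boundary[i]
            if not np.isnan(lo) and not np.isnan(hi) and hi < lo:
                assert not w.window[i].any()

    def test_grid_refinement_preserves_classification(self, table, reactions):
        coarse = self.make_window(table, reactions, n_ph=5, n_ac=7)
        fine = thermo.feasibility_window(
            reactions["hexadecane_to_acetate_net"],
            reactions["acetoclastic_methanogenesis"],
            table,
            np.linspace(4.0, 9.0, 5),
            np.logspace(-9, 0, 13),  # supersets the 7-point grid
            thermo.default_conditions(),
        )
        assert np.array_equal(coarse.window, fine.window[:, ::2])

    def test_fermentation_monotone_in_acetate(self, table, reactions):
        """Raising acetate at fixed pH never turns an endergonic
        fermentation point exergonic (acetate is a product)."""
        w = self.make_window(table, reactions)
        endergonic = w.fermentation_dg >= 0
        assert np.all(endergonic[:, :-1] <= endergonic[:, 1:])


class TestAssessWell:
    def test_interior_well_both_feasible(self, table, reactions):
        verdict = thermo.assess_well(
            7.0, 1e-4, thermo.default_conditions(),
            reactions["hexadecane_to_acetate_net"],
            reactions["acetoclastic_methanogenesis"], table,
        )
        assert verdict == thermo.BOTH_FEASIBLE

    def test_boundary_well_is_not_feasible_for_fermentation(self, table, reactions):
        """A well sitting on the fermentation dG = 0 boundary fails the
        strict exergonicity requirement."""
        ferm = reactions["hexadecane_to_acetate_net"]
        meth = reactions["acetoclastic_methanogenesis"]
        base = thermo.default_conditions()
        boundary = thermo.equilibrium_acetate(
            ferm, base.replace(pH=7.0), table
        ) * (1.0 + 1e-9)
        verdict = thermo.assess_well(7.0, boundary, base, ferm, meth, table)
        assert verdict == thermo.METHANOGENESIS_ONLY

    def test_agrees_with_window_at_grid_points(self, table, reactions):
        ferm = reactions["hexadecane_to_acetate_net"]
        meth = reactions["acetoclastic_methanogenesis"]
        base = thermo.default_conditions()
        w = thermo.feasibility_window(
            ferm, meth, table, np.linspace(4.5, 8.5, 6),
            np.logspace(-8, -1, 8), base,
        )
        for i, ph in enumerate(w.pH_grid):
            for j, ac in enumerate(w.acetate_grid):
                verdict = thermo.assess_well(float(ph), float(ac), base,
                                             ferm, meth, table)
                assert (verdict == thermo.BOTH_FEASIBLE) == bool(w.window[i, j])

    def test_non_positive_acetate_is_fatal(self, table, reactions):
        with pytest.raises(ValidationError, match="acetate"):
            thermo.assess_well(
                7.0, 0.0, thermo.default_conditions(),
                reactions["hexadecane_to_acetate_net"],
                reactions["acetoclastic_methanogenesis"], table,
            )
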