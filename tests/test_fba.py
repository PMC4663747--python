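"""FBA correctness against independent oracles, medium handling, and the
essentiality screen."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from microrep.fba import (
    FbaError,
    Medium,
    ScreenConfig,
    check_anaerobic_growth,
    essential_nutrients,
    remove_metabolite,
    rich_medium,
    solve_fba,
)
from microrep.model_io import MetabolicModel, Metabolite, Reaction, ValidationError

from conftest import make_chain_model


# ---------------------------------------------------------------------------
# independent oracle: enumerate the vertices of {v : S v = 0, l <= v <= u}

def vertex_enumeration_max(S: np.ndarray, bounds: list[tuple[float, float]], obj: int) -> float:
    """Max of v[obj] over the polytope, by brute-force vertex enumeration."""
    n = S.shape[1]
    r = np.linalg.matrix_rank(S, tol=1e-10)
    k = n - r
    best = -np.inf
    for fixed in itertools.combinations(range(n), k):
        rest = [i for i in range(n) if i not in fixed]
        A = S[:, rest]
        if rest and np.linalg.matrix_rank(A, tol=1e-10) < len(rest):
            continue  # not a basis
        for pattern in itertools.product((0, 1), repeat=k):
            x = np.zeros(n)
            for i, p in zip(fixed, pattern):
                x[i] = bounds[i][p]
            if rest:
                sol, *_ = np.linalg.lstsq(A, -S[:, fixed] @ x[list(fixed)], rcond=None)
                x[rest] = sol
            if np.max(np.abs(S @ x)) > 1e-7:
                continue
            if all(bounds[i][0] - 1e-9 <= x[i] <= bounds[i][1] + 1e-9 for i in range(n)):
                best = max(best, x[obj])
    return best


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """Random valid model with <= 8 reactions and 0 always feasible."""
    n_cyt = int(rng.integers(1, 4))
    mets = [Metabolite(id="X_e", compartment="extracellular")] + [
        Metabolite(id=f"M{i}_c", compartment="cytosol") for i in range(n_cyt)
    ]
    cyt_ids = [m.id for m in mets[1:]]

    def rnd_bounds():
        lo = float(np.round(-rng.uniform(0, 10), 3))
        hi = float(np.round(rng.uniform(0, 10), 3))
        return lo, hi

    rxns = [
        Reaction(id="EX_X", stoichiometry={"X_e": -1.0}, lower_bound=-10.0,
                 upper_bound=10.0, is_exchange=True),
        Reaction(id="T_X", stoichiometry={"X_e": -1.0, cyt_ids[0]: 1.0},
                 lower_bound=min(0.0, rnd_bounds()[0]), upper_bound=rnd_bounds()[1]),
    ]
    n_internal = int(rng.integers(0, 5))
    for j in range(n_internal):
        k = int(rng.integers(1, min(3, n_cyt) + 1))
        chosen = rng.choice(cyt_ids, size=k, replace=False)
        stoich = {}
        for i, mid in enumerate(chosen):
            coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            if i == 0:
                coef = -abs(coef)
            stoich[mid] = coef
        lo, hi = rnd_bounds()
        rxns.append(Reaction(id=f"R{j}", stoichiometry=stoich, lower_bound=lo, upper_bound=hi))
    k = int(rng.integers(1, n_cyt + 1))
    bio_mets = rng.choice(cyt_ids, size=k, replace=False)
    rxns.append(
        Reaction(
            id="BIOMASS",
            stoichiometry={mid: -float(rng.integers(1, 3)) for mid in bio_mets},
            lower_bound=0.0,
            upper_bound=float(np.round(rng.uniform(1, 10), 3)),
            is_biomass=True,
        )
    )
    return MetabolicModel(
        organism_id="rand", metabolites=mets, reactions=rxns, biomass_reaction_id="BIOMASS"
    )


def build_S(model: MetabolicModel) -> np.ndarray:
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for mid, c in r.stoichiometry.items():
            S[met_pos[mid], j] = c
    return S


class TestSolveFba:
    def test_chain_growth_pinned_by_uptake_bound(self, chain_model):
        res = solve_fba(chain_model, rich_medium(chain_model))
        assert res.optimal
        assert res.growth_rate == pytest.approx(10.0, abs=1e-8)
        assert res.growth_rate == pytest.approx(res.fluxes["BIOMASS"])

    def test_stoichiometric_halving(self):
        model = make_chain_model(biomass_per_b=2.0)
        res = solve_fba(model, rich_medium(model))
        assert res.growth_rate == pytest.approx(5.0, abs=1e-8)

    def test_steady_state_and_bounds_hold_at_optimum(self, chain_model):
        medium = rich_medium(chain_model)
        res = solve_fba(chain_model, medium)
        S = build_S(chain_model)
        v = np.array([res.fluxes[r.id] for r in chain_model.reactions])
        assert np.max(np.abs(S @ v)) < 1e-8
        for r, flux in zip(chain_model.reactions, v):
            lo = -10.0 if r.is_exchange else r.lower_bound
            assert lo - 1e-8 <= flux <= r.upper_bound + 1e-8

    def test_matches_vertex_enumeration_oracle(self):
        rng = np.random.default_rng(1234)
        checked = 0
        for _ in range(80):
            model = random_small_model(rng)
            medium = rich_medium(model)
            res = solve_fba(model, medium)
            assert res.optimal  # v = 0 is always feasible here
            S = build_S(model)
            bounds = []
            for r in model.reactions:
                lo = -10.0 if r.is_exchange else r.lower_bound
                bounds.append((lo, r.upper_bound))
            obj = next(i for i, r in enumerate(model.reactions) if r.is_biomass)
            oracle = vertex_enumeration_max(S, bounds, obj)
            assert res.growth_rate == pytest.approx(oracle, abs=1e-6)
            checked += 1
        assert checked == 80

    def test_matches_cobra_glpk_on_generated_models(self, small_community):
        cobra = pytest.importorskip("cobra")
        for model in list(small_community.models)[:3]:
            cm = cobra.Model(model.organism_id)
            cm.add_metabolites(
                [cobra.Metabolite(m.id, compartment="e" if m.compartment == "extracellular" else "c")
                 for m in model.metabolites]
            )
            for r in model.reactions:
                cr = cobra.Reaction(r.id)
                cm.add_reactions([cr])
                cr.add_metabolites({cm.metabolites.get_by_id(k): v for k, v in r.stoichiometry.items()})
                cr.bounds = (-10.0 if r.is_exchange else r.lower_bound, r.upper_bound)
            cm.objective = model.biomass_reaction_id
            cm.solver = "glpk"
            ours = solve_fba(model, rich_medium(model)).growth_rate
            assert ours == pytest.approx(cm.optimize().objective_value, abs=1e-6)

    def test_uptake_monotonicity_and_linearity(self, chain_model):
        growth = []
        for limit in (2.5, 5.0, 10.0):
            medium = rich_medium(chain_model, ScreenConfig(uptake_limit=limit))
            growth.append(solve_fba(chain_model, medium).growth_rate)
        assert growth == sorted(growth)
        assert growth[1] == pytest.approx(2 * growth[0], abs=1e-8)
        assert growth[2] == pytest.approx(2 * growth[1], abs=1e-8)

    def test_closing_an_exchange_never_increases_growth(self, small_community):
        for model in list(small_community.models)[:4]:
            medium = rich_medium(model)
            base = solve_fba(model, medium).growth_rate
            for mid in model.exchanged_metabolite_ids():
                g = solve_fba(model, remove_metabolite(medium, model, mid)).growth_rate
                if np.isnan(g):
                    g = 0.0
                assert g <= base + 1e-8


class TestMedium:
    def test_rich_medium_opens_every_exchange(self, small_community):
        model = small_community.models.models[0]
        medium = rich_medium(model, ScreenConfig(uptake_limit=10.0))
        exch = {r.id for r in model.exchange_reactions()}
        assert set(medium.max_uptake) == exch
        assert all(v == 10.0 for v in medium.max_uptake.values())
        m75 = rich_medium(model, ScreenConfig(uptake_limit=7.5))
        assert all(v == 7.5 for v in m75.max_uptake.values())

    def test_remove_metabolite_is_idempotent_and_pure(self, chain_model):
        medium = rich_medium(chain_model)
        once = remove_metabolite(medium, chain_model, "A_e")
        twice = remove_metabolite(once, chain_model, "A_e")
        assert once.closed == twice.closed == frozenset({"EX_A"})
        assert "EX_A" in medium.max_uptake  # original untouched

    def test_removing_intracellular_metabolite_raises(self, chain_model):
        with pytest.raises(KeyError, match="A_c"):
            remove_metabolite(rich_medium(chain_model), chain_model, "A_c")

    def test_medium_referencing_unknown_reaction_rejected(self, chain_model):
        with pytest.raises(ValidationError, match="EX_missing"):
            solve_fba(chain_model, Medium(max_uptake={"EX_missing": 10.0}))

    def test_open_and_closed_conflict_rejected(self):
        with pytest.raises(ValueError, match="open and closed"):
            Medium(max_uptake={"EX_A": 10.0}, closed=frozenset({"EX_A"}))


class TestEssentialityScreen:
    def test_single_route_nutrient_is_essential(self, chain_model):
        ess, gmap = essential_nutrients(chain_model)
        assert ess == {"A_e"}
        assert gmap["A_e"] == 0.0

    def test_redundant_substrates_are_not_essential(self):
        model = make_chain_model(extra_substrate=True)
        ess, gmap = essential_nutrients(model)
        assert ess == set()
        assert set(gmap) == {"A_e", "C_e"}

    def test_cutoff_boundary_is_strict(self):
        # alternative route capped just below / above the 0.05 1/h cutoff
        for cap, expect_essential in ((0.049, True), (0.051, False)):
            model = make_chain_model(extra_substrate=True, alt_cap=cap)
            ess, gmap = essential_nutrients(model)
            assert gmap["A_e"] == pytest.approx(cap, abs=1e-8)
            assert (("A_e" in ess) is expect_essential)

    def test_no_growth_baseline_raises(self):
        model = make_chain_model()
        starved = MetabolicModel(
            organism_id="starved",
            metabolites=model.metabolites,
            reactions=[
                r if r.id != "AB"
                else Reaction(id="AB", stoichiometry=r.stoichiometry, lower_bound=0.0, upper_bound=0.0)
                for r in model.reactions
            ],
            biomass_reaction_id="BIOMASS",
        )
        with pytest.raises(FbaError, match="rich medium"):
            essential_nutrients(starved)


class TestAnaerobicCheck:
    def test_oxygen_free_chain_is_anaerobic_capable(self, chain_model):
        ok, g = check_anaerobic_growth(chain_model, "o2_e")
        assert ok and g == pytest.approx(10.0)

    def test_obligate_aerobe_detected(self):
        # biomass route consumes imported oxygen stoichiometrically
        mets = [
            Metabolite(id="o2_e", compartment="extracellular"),
            Metabolite(id="o2_c", compartment="cytosol"),
            Metabolite(id="A_e", compartment="extracellular"),
            Metabolite(id="A_c", compartment="cytosol"),
        ]
        rxns = [
            Reaction(id="EX_o2", stoichiometry={"o2_e": -1.0}, is_exchange=True),
            Reaction(id="T_o2", stoichiometry={"o2_e": -1.0, "o2_c": 1.0}, lower_bound=0.0),
            Reaction(id="EX_A", stoichiometry={"A_e": -1.0}, is_exchange=True),
            Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0}, lower_bound=0.0),
            Reaction(id="BIOMASS", stoichiometry={"A_c": -1.0, "o2_c": -1.0},
                     lower_bound=0.0, is_biomass=True),
        ]
        aerobe = MetabolicModel(
            organism_id="aerobe", metabolites=mets, reactions=rxns,
            biomass_reaction_id="BIOMASS",
        )
        ok, g = check_anaerobic_growth(aerobe, "o2_e")
        assert not ok and g == 0.0

    def test_whole_synthetic_community_is_anaerobic_capable(self, small_community):
        for model in small_community.models:
            ok, _ = check_anaerobic_growth(model, "o2_e")
            assert ok
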