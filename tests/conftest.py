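"""Shared fixtures: toy chain models and small synthetic communities."""

from __future__ import annotations

import numpy as np
import pytest

from microrep.model_io import MetabolicModel, Metabolite, Reaction
from microrep.synthetic import SimulationConfig, generate_community


def make_chain_model(
    biomass_per_b: float = 1.0,
    organism_id: str = "toy",
    extra_substrate: bool = False,
    alt_cap: float | None = None,
) -> MetabolicModel:
    """Linear chain: EX_A -> transport -> A_c -> B_c -> biomass.

    With ``extra_substrate`` a second nutrient C feeds B_c as well; its
    pathway flux can be capped at ``alt_cap`` to pin removal growth rates.
    """
    mets = [
        Metabolite(id="A_e", compartment="extracellular"),
        Metabolite(id="A_c", compartment="cytosol"),
        Metabolite(id="B_c", compartment="cytosol"),
    ]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A_e": -1.0}, is_exchange=True),
        Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0}, lower_bound=0.0),
        Reaction(id="AB", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0),
        Reaction(
            id="BIOMASS",
            stoichiometry={"B_c": -biomass_per_b},
            lower_bound=0.0,
            is_biomass=True,
        ),
    ]
    if extra_substrate:
        mets += [
            Metabolite(id="C_e", compartment="extracellular"),
            Metabolite(id="C_c", compartment="cytosol"),
        ]
        rxns += [
            Reaction(id="EX_C", stoichiometry={"C_e": -1.0}, is_exchange=True),
            Reaction(id="T_C", stoichiometry={"C_e": -1.0, "C_c": 1.0}, lower_bound=0.0),
            Reaction(
                id="CB",
                stoichiometry={"C_c": -1.0, "B_c": 1.0},
                lower_bound=0.0,
                upper_bound=alt_cap if alt_cap is not None else 1000.0,
            ),
        ]
    return MetabolicModel(
        organism_id=organism_id,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )


@pytest.fixture
def chain_model() -> MetabolicModel:
    return make_chain_model()


@pytest.fixture(scope="session")
def small_community():
    """A 20-organism community, small enough for per-test FBA work."""
    cfg = SimulationConfig(
        n_organisms=20,
        n_features=60,
        n_nutrients=5,
        n_classes=3,
        n_genera=6,
        seed=11,
    )
    return generate_community(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150)
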