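import pytest

from remiflux.model import MetabolicModel, Metabolite, Reaction, parse_gpr
from remiflux.synthetic import SyntheticSpec, generate_toy_model


def make_chain_model(yield_coef: float = 1.0, uptake: float = 10.0) -> MetabolicModel:
    """EX_A (uptake-limited) -> transport -> A->B -> biomass(B)."""
    model = MetabolicModel(
        "chain",
        [
            Metabolite("a_e", "e", formula="C2H4O2", charge=0),
            Metabolite("a_c", "c", formula="C2H4O2", charge=0),
            Metabolite("b_c", "c", formula="C2H4O2", charge=0),
        ],
        [
            Reaction("EX_a", {"a_e": -1.0}, lower_bound=-uptake, upper_bound=0.0,
                     kind="exchange"),
            Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, lower_bound=0.0,
                     kind="transport", gpr=parse_gpr("gT")),
            Reaction("AB", {"a_c": -1.0, "b_c": yield_coef}, lower_bound=0.0,
                     gpr=parse_gpr("gAB")),
            Reaction("BIOMASS", {"b_c": -1.0}, lower_bound=0.0, kind="biomass"),
        ],
        {"c": "cytosol", "e": "extracellular"},
        "BIOMASS",
    )
    model.validate()
    return model


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def chain_half_yield():
    return make_chain_model(yield_coef=0.5)


@pytest.fixture
def default_instance():
    """One default synthetic instance (model, thermo, truth)."""
    return generate_toy_model(SyntheticSpec())


@pytest.fixture
def blocked_instance():
    """Synthetic instance with three planted dead-end reactions."""
    return generate_toy_model(
        SyntheticSpec(n_metabolites=23, n_reactions=33, n_blocked=3)
    )
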