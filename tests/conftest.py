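import numpy as np
import pytest

from c1flux import build_core_model
from c1flux.fba import FluxConstraintSet, solve_fba
from c1flux.isotopes import SCENARIOS
from c1flux.network import MetabolicModel, Reaction


@pytest.fixture(scope="session")
def formatotroph_model():
    return build_core_model("rG-F")


@pytest.fixture(scope="session")
def methylotroph_model():
    return build_core_model("rG-M")


@pytest.fixture(scope="session")
def mixotroph_model():
    return build_core_model("rG1")


@pytest.fixture(scope="session")
def formatotroph_flux(formatotroph_model):
    fd = solve_fba(formatotroph_model, FluxConstraintSet({"for": 18.5}))
    assert fd.status == "optimal"
    return fd


@pytest.fixture
def scenarios():
    return SCENARIOS


def with_free_cofactors(model: MetabolicModel) -> MetabolicModel:
    """Copy of a model with free ATP/NADH/NADPH generation (energy costs 0)."""
    import copy

    rxns = copy.deepcopy(model.reactions)
    rxns += [
        Reaction("FREE_ATP", {"adp": -1, "atp": 1}, bounds=(0.0, float("inf"))),
        Reaction("FREE_NADH", {"nad": -1, "nadh": 1}, bounds=(0.0, float("inf"))),
        Reaction("FREE_NADPH", {"nadp": -1, "nadph": 1}, bounds=(0.0, float("inf"))),
    ]
    for r in rxns:
        if r.id == "NGAM":
            r.bounds = (0.0, 0.0)
    return MetabolicModel(metabolites=list(model.metabolites), reactions=rxns,
                          biomass_reaction_id=model.biomass_reaction_id,
                          cofactor_params=dict(model.cofactor_params),
                          name=model.name + "+free-energy")


def pyruvate_sink_model(strain: str = "rG-F") -> MetabolicModel:
    """Strain model whose objective drains pyruvate only (no energy cost)."""
    model = build_core_model(
        strain,
        cofactor_params={"gam_atp": 0.0, "ngam_atp": 0.0},
        biomass_drains={"pyr": 1.0, "accoa": 0.0, "oaa": 0.0, "akg": 0.0,
                        "ser": 0.0, "gly": 0.0, "mlthf": 0.0, "nadph": 0.0},
    )
    return with_free_cofactors(model)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
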