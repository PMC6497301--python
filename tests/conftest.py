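"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from gembench.expression import ExpressionProfile
from gembench.model import MetabolicModel
from gembench.synthetic import FixtureSpec, make_expression_panel, make_toy_model


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=1, n_blocked=2)


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return make_toy_model(toy_spec)


@pytest.fixture(scope="session")
def toy_panel(toy_model, toy_spec):
    return make_expression_panel(toy_model, toy_spec)


@pytest.fixture(scope="session")
def chain_model():
    """3-reaction chain: EX_A (uptake <= 10) -> CONV (A->B) -> biomass (B->)."""
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["EX_A", "CONV", "BIOMASS"],
        S=np.array([[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lb=np.array([-10.0, 0.0, 0.0]),
        ub=np.array([1000.0, 1000.0, 1000.0]),
        gene_ids=["g1"],
        gpr=["", "g1", ""],
        objective_id="BIOMASS",
        model_id="chain",
    )


@pytest.fixture(scope="session")
def cycle_model():
    """Chain with a parallel futile cycle: pFBA must zero the cycle."""
    # metabolites A, B; EX_A uptake; CONV A->B; biomass consumes B;
    # futile pair F1: A->B, F2: B->A (both irreversible) forms a cycle with CONV?
    # Use F1: B->A and CONV A->B: loop CONV+F1 carries arbitrary flux.
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["EX_A", "CONV", "F_BACK", "BIOMASS"],
        S=np.array(
            [
                [-1.0, -1.0, 1.0, 0.0],
                [0.0, 1.0, -1.0, -1.0],
            ]
        ),
        lb=np.array([-10.0, 0.0, 0.0, 0.0]),
        ub=np.array([1000.0, 1000.0, 1000.0, 1000.0]),
        gene_ids=[],
        gpr=["", "", "", ""],
        objective_id="BIOMASS",
        model_id="cycle",
    )


def chain_fixture_metabolites_ok(m: MetabolicModel) -> bool:
    return m.n_metabolites == 2
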