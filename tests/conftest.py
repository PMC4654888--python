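from fractions import Fraction

import pytest

from thrbypass import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_curated_model,
)


@pytest.fixture(scope="session")
def curated_on() -> MetabolicModel:
    """Curated model with the threonine bypass active (tdh/kbl open)."""
    return build_curated_model(bypass_active=True)


@pytest.fixture(scope="session")
def curated_off() -> MetabolicModel:
    """Curated model with the bypass repressed (wild-type tdh/kbl bounds)."""
    return build_curated_model(bypass_active=False)


@pytest.fixture()
def linear_chain() -> MetabolicModel:
    """A -> B with uptake capped at 5: unique optimum, secretion 5."""
    f = Fraction
    return MetabolicModel(
        metabolites=[
            Metabolite("A", is_boundary=True),
            Metabolite("B", is_boundary=True),
        ],
        reactions=[
            Reaction("EX_A", {"A": f(-1)}, -5.0, 0.0),
            Reaction("conv", {"A": f(-1), "B": f(1)}, 0.0, 100.0),
            Reaction("EX_B", {"B": f(-1)}, 0.0, 100.0),
        ],
        cofactor_policy="split",
        name="linear chain",
    )
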