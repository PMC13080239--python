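import numpy as np
import pandas as pd
import pytest

from myoflux.instantiate import EnzymeMapping, ProteinAbundanceMatrix
from myoflux.network import build_reference_model, load_default_model
from myoflux.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def model():
    """The shipped calibrated reduced cardiac model."""
    return load_default_model()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic three-group cohort (deterministic seed)."""
    return generate_cohort(CohortConfig.tiny(seed=11))


@pytest.fixture(scope="session")
def mapping(model):
    return EnzymeMapping.from_model(model)


def linear_chain_doc(vup=0.4, km=2.0, s0=5.0, k_out=3.0):
    """Boundary S --(MM uptake)--> X --(mass action)--> boundary P.

    Closed-form steady flux: v = vup * s0 / (s0 + km), with X = v / k_out.
    """
    return {
        "name": "chain",
        "metabolites": [
            {"id": "s", "compartment": "plasma", "conc0": s0},
            {"id": "x", "compartment": "cytosol", "conc0": 0.1},
            {"id": "p", "compartment": "plasma", "conc0": 0.0},
        ],
        "pools": [],
        "reactions": [
            {
                "id": "up",
                "pathway": "transport",
                "stoichiometry": {"s": -1, "x": 1},
                "law": {"form": "irreversible-MM", "vmax": vup, "km": {"s": km}},
            },
            {
                "id": "out",
                "pathway": "transport",
                "stoichiometry": {"x": -1, "p": 1},
                "law": {"form": "mass-action", "vmax": k_out},
            },
        ],
    }


def minimal_pool_doc():
    """Smallest valid document exercising a conserved pool: a 3-reaction
    chain where a carrier (atp/adp) cycles."""
    return {
        "name": "mini",
        "metabolites": [
            {"id": "s", "compartment": "plasma", "conc0": 2.0},
            {"id": "x", "compartment": "cytosol", "conc0": 0.1},
            {"id": "atp", "compartment": "cytosol", "conc0": 1.0},
            {"id": "adp", "compartment": "cytosol", "conc0": 1.0},
        ],
        "pools": [{"name": "adenine", "members": ["atp", "adp"], "total": 2.0}],
        "reactions": [
            {
                "id": "make",
                "pathway": "transport",
                "stoichiometry": {"s": -1, "x": 1, "adp": -1, "atp": 1},
                "law": {"form": "irreversible-MM", "vmax": 0.5, "km": {"s": 1.0, "adp": 0.2}},
            },
            {
                "id": "spend",
                "pathway": "atp-demand",
                "stoichiometry": {"atp": -1, "adp": 1},
                "law": {"form": "load-hyperbolic", "vmax": 0.2, "km": {"atp": 0.5}},
            },
            {
                "id": "drain",
                "pathway": "transport",
                "stoichiometry": {"x": -1},
                "law": {"form": "mass-action", "vmax": 1.0},
            },
        ],
    }


def toy_matrix(data: dict[str, dict[str, float]], groups: dict[str, str]):
    """Convenience: ProteinAbundanceMatrix from {sample: {protein: value}}."""
    df = pd.DataFrame(data, dtype=float)
    return ProteinAbundanceMatrix(intensity=df, group=groups)
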