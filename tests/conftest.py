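import numpy as np
import pytest

from gpkinetics.catalog import MODELS, ModelSpec, ParamVector
from gpkinetics.synthetic import feasible_params, table2_presets


@pytest.fixture(scope="session")
def presets():
    return table2_presets()


@pytest.fixture(scope="session")
def compound_truths(presets):
    """Feasible ground truths for every model at its Compound-category preset."""
    return {
        spec.name: feasible_params(spec, presets[(spec.name, "Compound")])
        for spec in MODELS
    }


def draw_valid_params(spec: ModelSpec, rng: np.random.Generator) -> ParamVector:
    """Random parameter vector satisfying the model's constraints, in ranges
    typical of gas-production curves."""
    labels = {c.label for c in spec.constraints}
    kw = {}
    for name in spec.param_names:
        if name == "m":
            kw["m"] = rng.uniform(30.0, 100.0)
        elif name == "r":
            kw["r"] = rng.uniform(0.05, 0.5)
        elif name == "mu":
            kw["mu"] = rng.uniform(-5.0, 10.0)
        elif name == "a":
            if spec.name == "Generalized logistic":
                kw["a"] = rng.uniform(0.05, 0.3)  # plays the rate role
            elif "a>1" in labels:
                kw["a"] = rng.uniform(1.05, 3.0)
            else:
                kw["a"] = rng.uniform(0.3, 3.0)
        elif name == "p":
            lo = 1.05 if "p>1" in labels else 0.3
            kw["p"] = rng.uniform(lo, lo + 2.5)
    return ParamVector(**kw)
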