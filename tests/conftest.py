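import numpy as np
import pytest
from hypothesis import settings

from sprsim import MaterialRegistry, make_fixtures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from sprsim.fresnel import Layer, LayerStack


@pytest.fixture(scope="session")
def registry():
    reg = MaterialRegistry.default()
    reg.calibrate_core_shell()
    return reg


@pytest.fixture(scope="session")
def constituents(registry):
    """Calibrated (eps_core, eps_shell) of the magnetite/gold constituents."""
    return registry.constituents()


@pytest.fixture(scope="session")
def fixture_scenarios():
    return make_fixtures()


@pytest.fixture(scope="session")
def hb_film_stack(registry):
    """Four-layer benchmark: prism / Ag 40 nm / Hb film 20 nm / air."""
    return LayerStack(
        wavelength_nm=632.8,
        layers=(
            Layer.from_material("bk7", registry.get("bk7")),
            Layer.from_material("silver", registry.get("silver"), thickness_nm=40.0),
            Layer.from_material(
                "hb_cytoplasm_hi", registry.get("hb_cytoplasm_hi"), thickness_nm=20.0
            ),
            Layer.from_material("air", registry.get("air")),
        ),
    )


def random_passive_stack(rng: np.random.Generator, n_layers: int) -> LayerStack:
    """A random physically passive stack with a lossless dielectric prism."""
    layers = [Layer(name="prism", eps=complex(rng.uniform(1.5, 4.0)))]
    for j in range(n_layers - 2):
        eps = complex(rng.uniform(-18.0, 6.0), rng.uniform(0.0, 4.0))
        layers.append(Layer(name=f"film{j}", eps=eps, thickness_nm=rng.uniform(1.0, 200.0)))
    layers.append(Layer(name="exit", eps=complex(rng.uniform(1.0, 3.0))))
    return LayerStack(wavelength_nm=632.8, layers=tuple(layers))
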