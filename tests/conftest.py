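import numpy as np
import pytest
from dataclasses import replace

from periplaque.synthetic import (
    GliaProfile,
    PlaqueSpec,
    SceneSpec,
    SynapseProfile,
    generate_stack,
)


@pytest.fixture(scope="session")
def small_synapse_spec():
    """20×20 µm plaque-free synapse-mode scene (200 µm³ per 10 µm crop depth)."""
    return SceneSpec(
        field_size_um=(20.0, 20.0),
        acquisition_mode="synapse",
        pixel_size_um=0.25,
        plaque_specs=(),
        synapse_profile=SynapseProfile(baseline_pair_density_per_um3=0.3),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_synapse_stack(small_synapse_spec):
    return generate_stack(small_synapse_spec)


@pytest.fixture(scope="session")
def small_glia_spec():
    """Compact glia-mode scene with one centred non-diffuse plaque."""
    return SceneSpec(
        field_size_um=(140.0, 140.0),
        acquisition_mode="glia",
        pixel_size_um=0.4,
        plaque_specs=(
            PlaqueSpec(center_um=(70.0, 70.0), radius_um=15.0, plaque_class="non_diffuse"),
        ),
        glia_profile=GliaProfile(),
        rng_seed=13,
    )


@pytest.fixture(scope="session")
def small_glia_stack(small_glia_spec):
    return generate_stack(small_glia_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tg_synapse_stack():
    """One transgenic synapse-mode field with a central plaque (deterministic)."""
    from periplaque.studies import synapse_scene

    spec = replace(synapse_scene("NLGF", deficit={"0-10": 0.5}), rng_seed=42)
    return generate_stack(spec)
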