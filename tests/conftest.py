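import numpy as np
import pytest

from gapct.phantom import GapSpec, MaterialSpec, PhantomSpec, Radii


def noise_free_materials():
    greys = {
        "post": 0.90,
        "cement": 0.80,
        "composite": 0.70,
        "dentin": 0.55,
        "adhesive": 0.35,
        "gap": 0.05,
        "background": 0.05,
    }
    return {k: MaterialSpec(k, v, 0.0) for k, v in greys.items()}


def make_spec(
    shape=(8, 96, 96),
    gaps=(),
    noise: bool = False,
    fringe: float = 0.0,
    voxel_um: float = 0.65,
    radii=(8.0, 12.0, 16.0, 20.0, 28.0),
    seed: int = 0,
    **kw,
):
    """Small restored-tooth phantom for unit tests (20 µm interface radius)."""
    materials = None if noise else noise_free_materials()
    return PhantomSpec(
        shape=shape,
        voxel_um=voxel_um,
        radii_um=Radii(*radii),
        materials=materials,
        gaps=list(gaps),
        fringe_strength=fringe,
        noise_seed=seed,
        **kw,
    )


@pytest.fixture
def clean_spec():
    """Noise- and fringe-free phantom with one 120 deg, 5 µm gap."""
    return make_spec(gaps=[GapSpec(30.0, 120.0, 0, 8, 5.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
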