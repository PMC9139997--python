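import numpy as np
import pytest

from partmorph import experiment_designs as designs
from partmorph.part_manipulation import curved_limb_params, mirror_limb
from partmorph.skeleton_core import (
    GrowthParams,
    Part,
    attach_part,
    compose_shape,
    grow_path,
    make_main_body,
)


@pytest.fixture(scope="session")
def body():
    return make_main_body()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def two_pair_shape(body, rng):
    """A symmetric shape with two mirrored first-order limb pairs."""
    shape = compose_shape(body, [])
    for k, t in enumerate((0.2, 0.32)):
        shape = attach_part(
            shape, "body", t, "left", curved_limb_params(rng),
            rng, pair_id=k, part_id=f"L{k}",
        )
        left = shape.parts[-1]
        mirrored = mirror_limb(left, body)
        shape = compose_shape(body, shape.parts + [mirrored], meta=shape.meta)
    return shape


# ---- full-scale designs, generated once per session ----------------------

@pytest.fixture(scope="session")
def exp1_symmetry_full():
    return designs.build_experiment1("symmetry", seed=11)


@pytest.fixture(scope="session")
def exp1_curvedness_full():
    return designs.build_experiment1("curvedness", seed=12)


@pytest.fixture(scope="session")
def exp2_full():
    return designs.build_experiment2(seed=13)


@pytest.fixture(scope="session")
def exp3_full():
    return designs.build_experiment3(seed=14)
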