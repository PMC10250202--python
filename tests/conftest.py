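import numpy as np
import pytest

from embryoscreen.phantom import PhantomSpec, generate_phantom
from embryoscreen.taxonomy import ClassTaxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return ClassTaxonomy()


@pytest.fixture(scope="session")
def flat_taxonomy():
    """Taxonomy without severity tiers (10 base labels)."""
    return ClassTaxonomy(tiered_classes=())


@pytest.fixture(scope="session")
def tiny_phantom(flat_taxonomy):
    """A small deterministic plate: 1 well, 12 frames, 3-5 embryos."""
    spec = PhantomSpec(seed=3, n_wells=1, frames_per_well=12, interval_s=120.0,
                       image_size_px=256, n_embryos_range=(3, 5),
                       radius_px_range=(26, 34), onset_frame_range=(3, 6),
                       classes=("normal", "nodal_lof", "wnt_lof"))
    return generate_phantom(spec, flat_taxonomy)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
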