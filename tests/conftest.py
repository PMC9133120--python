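import numpy as np
import pytest

from atlasmorph.phantom import (
    PerturbationSpec,
    default_head_spec,
    make_atlas_phantom,
    perturb_specimen,
)


@pytest.fixture(scope="session")
def head_atlas():
    """Default 48-cube head phantom: (volume, landmarks, segmentation)."""
    return make_atlas_phantom(default_head_spec())


@pytest.fixture(scope="session")
def small_atlas():
    """A 32-cube phantom for the heavier registration tests."""
    return make_atlas_phantom(default_head_spec(lengths=(32, 32, 32), steps=(0.15, 0.15, 0.15)))


@pytest.fixture(scope="session")
def specimen_pair(head_atlas):
    """One perturbed specimen of the default atlas with ground truth."""
    atlas, lms, seg = head_atlas
    vol, true_lms, T, true_seg = perturb_specimen(
        atlas, lms, seg, PerturbationSpec(), seed=42, specimen_id="s42"
    )
    return dict(atlas=atlas, atlas_lms=lms, atlas_seg=seg, volume=vol,
                true_lms=true_lms, transform=T, seg=true_seg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
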