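import numpy as np
import pytest

from larvaforage import ArenaSpec, Patch, PatchLayout, two_patch_layout


@pytest.fixture
def two_patches() -> PatchLayout:
    """Reference design: two 25 mm yeast patches, centres 120 mm apart."""
    return two_patch_layout(substrate="yeast")


@pytest.fixture
def center_patch_layout() -> PatchLayout:
    """Single 25 mm patch in the middle of the default arena."""
    return PatchLayout(
        arena=ArenaSpec(), patches=[Patch((120.0, 120.0), 25.0, "yeast")]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
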