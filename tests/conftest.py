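"""Shared fixtures: small synthetic stacks and scenes.

Everything is generated programmatically at test time; unit tests use
reduced frames (a few hundred px) so the suite stays fast, while the
acceptance tests use the full acquisition frame.
"""

from __future__ import annotations

import numpy as np
import pytest

from gliacount import (
    DetectionParams,
    ImageStack,
    render_stack,
    sample_mosaic,
)

SMALL_SIZE = (400, 520)  # reduced frame for fast unit tests


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mosaic12():
    """A 12-cell mosaic on the full acquisition frame, rendered once."""
    scene = sample_mosaic(12, seed=42, n_slices=5)
    return render_stack(scene)


@pytest.fixture(scope="session")
def small_mosaic():
    """A 5-cell mosaic on a reduced frame for fast batch tests."""
    scene = sample_mosaic(5, seed=7, size=SMALL_SIZE, n_slices=4)
    return render_stack(scene)


@pytest.fixture()
def blank_stack():
    return ImageStack(np.zeros((3, 120, 140), dtype=np.float32))


@pytest.fixture()
def default_params():
    return DetectionParams()
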