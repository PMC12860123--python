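"""Shared fixtures: configs and cached synthetic vessels.

Synthetic stacks are generated once per session at a reduced grid
(512 px, 40 nm/px, single section) so the suite stays fast while the
geometry keeps realistic layer thicknesses.
"""

from __future__ import annotations

import numpy as np
import pytest

from pericytometry import PipelineConfig
from pericytometry.synthetic import SyntheticVesselSpec, generate_vessel

SMALL = dict(n_sections=1, grid_px=512, pixel_size_nm=40.0)


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_vessel():
    """Default-geometry vessel: ~50% coverage, 2.3% contact, 3 pegs."""
    spec = SyntheticVesselSpec(seed=7, **SMALL)
    return generate_vessel(spec)


@pytest.fixture(scope="session")
def clean_vessel():
    """No pegs, coverage 0.5, no direct contact: the cleanest geometry."""
    spec = SyntheticVesselSpec(
        seed=11,
        pericyte_arc_fraction=0.5,
        contact_arc_fraction=0.0,
        peg_count_per_section=0,
        **SMALL,
    )
    return generate_vessel(spec)


@pytest.fixture(scope="session")
def contact_vessel():
    """Coverage 0.5 with a 10% direct-contact sub-arc, no pegs."""
    spec = SyntheticVesselSpec(
        seed=13,
        pericyte_arc_fraction=0.5,
        contact_arc_fraction=0.10,
        peg_count_per_section=0,
        **SMALL,
    )
    return generate_vessel(spec)


def random_label_section(rng: np.random.Generator, n: int = 32):
    """A random (physically meaningless) six-class section."""
    from pericytometry import SegmentedSection

    labels = rng.integers(0, 6, size=(n, n)).astype(np.uint8)
    return SegmentedSection(labels=labels, pixel_size_nm=20.0)
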