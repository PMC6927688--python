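"""Shared fixtures: small single-particle renders and imaging setups."""

from __future__ import annotations

import numpy as np
import pytest

from hsafm_gating.synthetic import (
    ImagingConfig,
    MembranePatch,
    ParticleGeometry,
    render_height_map,
    tip_dilate,
)

CENTER_NM = 12.0  # single-particle patch center, nm
PX = 0.5


@pytest.fixture(scope="session")
def single_grid() -> ImagingConfig:
    return ImagingConfig(pixel_size=PX, frame_shape=(48, 48), vertical_noise_sd=0.0)


@pytest.fixture(scope="session")
def single_patch() -> MembranePatch:
    return MembranePatch(particle_centers=np.array([[CENTER_NM, CENTER_NM]]))


@pytest.fixture(scope="session")
def class_surfaces(single_grid, single_patch) -> dict[str, np.ndarray]:
    """True (pre-tip) surfaces of the four conformational classes."""
    offsets = (0.7, -0.5, 0.1, -0.3, 0.4)  # genuinely asymmetric openplus draw
    out = {}
    for lab in ("closed", "open1", "open2", "openplus"):
        geom = ParticleGeometry.for_class(
            lab, subunit_offsets=offsets if lab == "openplus" else None
        )
        out[lab] = render_height_map(geom, single_patch, single_grid)
    return out


@pytest.fixture(scope="session")
def class_topographs(class_surfaces, single_grid) -> dict[str, np.ndarray]:
    """Tip-convolved (imaged) versions of the class surfaces."""
    return {
        lab: tip_dilate(s, single_grid.tip_radius, single_grid.pixel_size)
        for lab, s in class_surfaces.items()
    }


def center_px() -> int:
    return int(round(CENTER_NM / PX))
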