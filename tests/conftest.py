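"""Shared fixtures: small grids and deterministic synthetic phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from spindletrack.features import (
    CompositeModel,
    ImageStack,
    LineFeature,
    Spot,
)
from spindletrack.simulate import line_amplitude_for_brightness

VOXEL = (0.1, 0.1, 0.5)
WIDTHS = np.array([0.15, 0.15, 0.4])


@pytest.fixture
def small_grid():
    return ImageStack(np.zeros((7, 32, 32)), VOXEL).grid


def make_monopolar_phantom(
    angles_deg,
    lengths,
    shape=(64, 64, 7),
    brightness=1.0,
    spb_brightness=3.0,
    background=0.5,
    pole=None,
    z_tips=None,
):
    """Noise-free monopolar spindle stack with explicitly placed lines.

    ``angles_deg``/``lengths`` place one line per entry radiating from the
    pole; tips stay in the mid-plane unless ``z_tips`` is given.  Returns
    ``(stack, model)`` with the model being the exact rendered truth.
    """
    nx, ny, nz = shape
    pole = (
        np.array([nx * VOXEL[0] / 2, ny * VOXEL[1] / 2, nz * VOXEL[2] / 2])
        if pole is None
        else np.asarray(pole, dtype=float)
    )
    features = [Spot(amplitude=spb_brightness, center=pole, widths=WIDTHS.copy())]
    attachments = {}
    for k, (a, L) in enumerate(zip(angles_deg, lengths)):
        phi = np.deg2rad(a)
        tip_z = pole[2] if z_tips is None else z_tips[k]
        tip = np.array(
            [pole[0] + L * np.cos(phi), pole[1] + L * np.sin(phi), tip_z]
        )
        amp = line_amplitude_for_brightness(brightness, L, WIDTHS[0])
        features.append(
            LineFeature(amplitude=amp, start=pole.copy(), end=tip, widths=WIDTHS.copy())
        )
        attachments[k + 1] = 0
    model = CompositeModel(
        background=background,
        features=features,
        topology="monopolar",
        attachments=attachments,
    )
    stack_geom = ImageStack(np.zeros((nz, ny, nx)), VOXEL)
    stack = ImageStack(model.render(stack_geom.grid), VOXEL)
    return stack, model
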