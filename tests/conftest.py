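"""Shared fixtures: small disk templates and fast solver settings.

Simulation tests run on reduced disks (60 mm at 0.6 mm/pixel) so the
whole suite stays within minutes on one CPU; the physics calibration
tests in test_acceptance.py use the full-size geometry where the claim
requires it.
"""

import numpy as np
import pytest

from ablate2d.geometry import make_disk_template
from ablate2d.tissue import iir_threshold, synth_base_intensity


def small_template(pixel_size: float = 0.6, diameter: float = 60.0):
    ring = 0.45 * diameter / 2.0
    o = ring / np.sqrt(2.0)
    c = diameter / 2.0
    s = diameter / 60.0   # openings scale with the disk
    return make_disk_template(
        disk_diameter=diameter,
        pixel_size=pixel_size,
        pv_centres={
            "LSPV": (c - o, c - o), "LIPV": (c - o, c + o),
            "RSPV": (c + o, c - o), "RIPV": (c + o, c + o),
        },
        pv_radii=2.5 * s,
        laa_centre=(c - 4.0 * s, c + 5.6 * s),
        laa_radius=3.5 * s,
    )


@pytest.fixture(scope="session")
def template_small():
    return small_template()


@pytest.fixture(scope="session")
def template_full():
    return make_disk_template()


@pytest.fixture(scope="session")
def tissue_small_healthy(template_small):
    intensity = synth_base_intensity(template_small, seed=11, burden=0.0)
    t = iir_threshold(intensity, tissue_id="healthy-small")
    return t


@pytest.fixture(scope="session")
def tissue_small_fibrotic(template_small):
    intensity = synth_base_intensity(template_small, seed=12, burden=0.2,
                                     correlation_length=4.0)
    return iir_threshold(intensity, tissue_id="fibrotic-small")
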