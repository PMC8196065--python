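import numpy as np
import pytest

from droptubes import synthetic as syn
from droptubes.detection import extract_droplet_pixels


@pytest.fixture(scope="session")
def imaging():
    return syn.ImagingParams(rng_seed=7)


@pytest.fixture(scope="session")
def single_droplet_frame(imaging):
    """One fully-dispersed (f=0) droplet of radius 12 px at a known center."""
    d = syn.DropletSpec(center_row=40, center_col=40, radius_um=12, radius_px=12)
    frame = syn.render_frame([d], None, imaging, (81, 81))
    return d, frame


def render_single(radius_px=12.0, f=0.0, seed=0, tile_total=500.0, **imaging_over):
    """Render one droplet in its own small frame; return (droplet, frame, values)."""
    pad = int(np.ceil(radius_px * 1.6 + 8))
    d = syn.DropletSpec(
        center_row=pad, center_col=pad, radius_um=radius_px, radius_px=radius_px,
        tile_total=tile_total, assembled_fraction=f,
    )
    fils = syn.default_filaments(d, seed=seed) if f > 0 else None
    img = syn.ImagingParams(rng_seed=seed, **imaging_over)
    frame = syn.render_frame([d], {0: fils} if fils else None, img, (2 * pad + 1, 2 * pad + 1))
    values = extract_droplet_pixels(frame.image, (pad, pad), radius_px, 0.1)
    return d, frame, values
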