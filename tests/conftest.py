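import numpy as np
import pytest
from scipy import ndimage

from octplaque import ArcSpec, CalciumArc, Calibration, LesionSpec


@pytest.fixture
def cal10():
    """10 µm pixels, 0.2 mm frame pitch."""
    return Calibration(pixel_size=0.01, frame_pitch=0.2)


@pytest.fixture
def cal20():
    """20 µm pixels, 0.2 mm frame pitch."""
    return Calibration(pixel_size=0.02, frame_pitch=0.2)


def arc_phantom(n_frames=50, pixel_size=0.01, thickness=0.1, span=(0.0, 90.0)):
    """The reference 90°-arc cap phantom: lumen r = 1.5 mm."""
    return LesionSpec(
        n_frames=n_frames,
        lumen_radius=1.5,
        fc_arcs=[ArcSpec(span[0], span[1], thickness)],
        calibration=Calibration(pixel_size=pixel_size, frame_pitch=0.2),
    )


def calcium_phantom(n_frames=1, pixel_size=0.01):
    """Calcium shell 1.6–2.0 mm (depth 0.1, thickness 0.4) over 120°."""
    return LesionSpec(
        n_frames=n_frames,
        lumen_radius=1.5,
        calcium_arcs=[CalciumArc(0.0, 120.0, thickness=0.4, depth=0.1)],
        calibration=Calibration(pixel_size=pixel_size, frame_pitch=0.2),
    )


def random_blob_mask(rng, shape=(96, 96), label=1):
    """A random connected blob as a label mask (largest component kept)."""
    noise = rng.random(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=6)
    blob = smooth > np.quantile(smooth, 0.85)
    lab, n = ndimage.label(blob)
    if n == 0:  # degenerate draw; fall back to a disc
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        blob = (yy - shape[0] / 2) ** 2 + (xx - shape[1] / 2) ** 2 < 100
        lab, n = ndimage.label(blob)
    sizes = ndimage.sum(blob, lab, range(1, n + 1))
    mask = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8) * label
    return mask
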