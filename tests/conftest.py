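import numpy as np
import pytest

from golgimap import enface, image_core, synthetic


@pytest.fixture
def ring_scene():
    """Noiseless thin ring (radius 40, width 3) at a fractional center."""
    spec = synthetic.SceneSpec(
        image_size_px=128,
        pixel_size_nm=50.0,
        structures=[
            synthetic.StructureSpec(
                "giantin", "ring", (63.3, 64.7), 1e4, radius_px=40, ring_width_px=3
            )
        ],
        psf_sigma_nm=0.0,
    )
    img, truth = synthetic.render_scene(spec)
    return spec, img, truth


@pytest.fixture
def two_channel_image():
    rng = np.random.default_rng(7)
    a = rng.uniform(0, 10, size=(24, 24))
    b = rng.uniform(0, 10, size=(24, 24))
    return image_core.MultiChannelImage({"a": a, "b": b}, pixel_size_nm=50.0)


# ---------------------------------------------------------------------------
# Independent oracles (brute-force / closed-form; never share code with the
# implementations they check)
# ---------------------------------------------------------------------------

def brute_centroid(arr):
    """Loop-based intensity-weighted mean pixel position (x, y)."""
    sx = sy = s = 0.0
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            v = arr[y, x]
            s += v
            sx += v * x
            sy += v * y
    return sx / s, sy / s


def brute_gyradius(arr, cx, cy):
    """Loop-based intensity-weighted RMS distance from (cx, cy)."""
    num = den = 0.0
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            v = arr[y, x]
            num += v * ((x - cx) ** 2 + (y - cy) ** 2)
            den += v
    return (num / den) ** 0.5


def brute_annular_means(arr, cx, cy, r_max):
    """Loop-based radial mean over annuli [r-0.5, r+0.5), r = 1..r_max."""
    sums = np.zeros(r_max + 1)
    counts = np.zeros(r_max + 1)
    for y in range(arr.shape[0]):
        for x in range(arr.shape[1]):
            d = np.hypot(x - cx, y - cy)
            r = int(np.floor(d + 0.5))
            if 1 <= r <= r_max:
                sums[r] += arr[y, x]
                counts[r] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means[1:]
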