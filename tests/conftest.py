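import numpy as np
import pytest

from nerveseg import GrayImage, SceneSpec, generate_scene


@pytest.fixture()
def uniform_histogram_image() -> GrayImage:
    """256x256 image in which every intensity 0-255 occurs exactly 256 times."""
    px = np.repeat(np.arange(256, dtype=np.uint8), 256).reshape(256, 256)
    return GrayImage(px)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free default scene: ten myelinated fibers, exact truth."""
    return generate_scene(SceneSpec(noise_sd=0, seed=1))


def brute_force_fill(points, height, width):
    """Even-odd point-in-polygon rasterization oracle, plus boundary pixels.

    Independent of the package's rasterizer: ray casting per pixel center
    and naive line walking for the boundary.
    """
    pts = [(float(x), float(y)) for x, y in points]
    n = len(pts)
    out = np.zeros((height, width), dtype=np.uint8)
    for yy in range(height):
        for xx in range(width):
            inside = False
            for i in range(n):
                x1, y1 = pts[i]
                x2, y2 = pts[(i + 1) % n]
                if (y1 > yy) != (y2 > yy):
                    xi = x1 + (yy - y1) * (x2 - x1) / (y2 - y1)
                    if xx < xi:
                        inside = not inside
            if inside:
                out[yy, xx] = 1
    # boundary: textbook integer Bresenham along each edge
    for i in range(n):
        x1, y1 = (int(round(c)) for c in pts[i])
        x2, y2 = (int(round(c)) for c in pts[(i + 1) % n])
        dx, dy = abs(x2 - x1), -abs(y2 - y1)
        sx = 1 if x1 < x2 else -1
        sy = 1 if y1 < y2 else -1
        err = dx + dy
        while True:
            if 0 <= y1 < height and 0 <= x1 < width:
                out[y1, x1] = 1
            if (x1, y1) == (x2, y2):
                break
            e2 = 2 * err
            if e2 >= dy:
                err += dy
                x1 += sx
            if e2 <= dx:
                err += dx
                y1 += sy
    return out
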