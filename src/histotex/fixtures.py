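"""Seeded synthetic 4-class texture tiles.

The generator emulates the visual structure of the four HE-stained breast
tissue classes at the level a texture pipeline cares about — not their
histology:

1. **stroma** — smooth pink low-variance field with sparse blue nuclei;
2. **adipose** — bright "bubbles" (packed pale discs with thin pink membranes);
3. **ducts** — ring/annulus structures with pale lumina on a pink background;
4. **carcinoma** — dense small dark-blue blobs, a high-frequency speckle.

All tiles are 8-bit RGB with additive Gaussian noise and are byte-identical
for a given (seed, spec).  Default class counts mirror the study cohort
(170/103/163/192 tiles of 200×200 px); tests and demos use smaller tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PINK = np.array([231.0, 180.0, 205.0])
BLUE = np.array([70.0, 70.0, 160.0])
WHITE = np.array([246.0, 242.0, 246.0])
DARK_BLUE = np.array([55.0, 50.0, 130.0])


@dataclass
class SyntheticSpec:
    n_per_class: tuple[int, int, int, int] = (170, 103, 163, 192)
    tile_size: int = 200
    seed: int = 0
    noise_sd: float = 12.0
    class_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tile_size < 32:
            raise ValueError("tile_size must be >= 32")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("need at least one tile per class")


def _smooth_field(rng: np.random.Generator, t: int, sigma: float) -> np.ndarray:
    """Low-frequency random field in [−1, 1] via Fourier-domain smoothing."""
    noise = rng.standard_normal((t, t))
    f = np.fft.fft2(noise)
    yy = np.minimum(np.arange(t), t - np.arange(t))
    r2 = yy[:, None] ** 2 + yy[None, :] ** 2
    f *= np.exp(-r2 / (2.0 * (t / (2 * np.pi * sigma)) ** 2))
    field = np.fft.ifft2(f).real
    m = np.abs(field).max()
    return field / m if m > 0 else field


def _stamp_disc(img: np.ndarray, cy: float, cx: float, r: float,
                colour: np.ndarray, ring: float | None = None) -> None:
    t = img.shape[0]
    lo_y, hi_y = max(int(cy - r - 2), 0), min(int(cy + r + 3), t)
    lo_x, hi_x = max(int(cx - r - 2), 0), min(int(cx + r + 3), t)
    if lo_y >= hi_y or lo_x >= hi_x:
        return
    yy = np.arange(lo_y, hi_y)[:, None] - cy
    xx = np.arange(lo_x, hi_x)[None, :] - cx
    d = np.hypot(yy, xx)
    mask = (np.abs(d - r) <= ring) if ring is not None else (d <= r)
    img[lo_y:hi_y, lo_x:hi_x][mask] = colour


def _tile_stroma(rng, t, p) -> np.ndarray:
    img = np.empty((t, t, 3))
    field = _smooth_field(rng, t, sigma=t / 10)
    for c in range(3):
        img[..., c] = PINK[c] + 18.0 * field
    n_nuclei = max(1, int(p.get("stroma_nuclei_density", 0.004) * t * t))
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, t, 2)
        _stamp_disc(img, cy, cx, rng.uniform(1.0, 2.2), BLUE)
    return img


def _tile_adipose(rng, t, p) -> np.ndarray:
    img = np.empty((t, t, 3))
    img[:] = PINK
    r_mean = p.get("bubble_radius", t / 9)
    n_bubbles = int(p.get("bubble_count_factor", 3.2) * (t / r_mean) ** 2 / 4)
    for _ in range(n_bubbles):
        cy, cx = rng.uniform(0, t, 2)
        r = rng.uniform(0.6, 1.3) * r_mean
        _stamp_disc(img, cy, cx, r, WHITE)
        _stamp_disc(img, cy, cx, r, PINK * 0.92, ring=1.2)
    return img


def _tile_ducts(rng, t, p) -> np.ndarray:
    img = np.empty((t, t, 3))
    field = _smooth_field(rng, t, sigma=t / 8)
    for c in range(3):
        img[..., c] = PINK[c] + 10.0 * field
    n_rings = max(2, int(p.get("ring_density", 8) * (t / 100) ** 2))
    for _ in range(n_rings):
        cy, cx = rng.uniform(0, t, 2)
        r = rng.uniform(0.06, 0.14) * t
        _stamp_disc(img, cy, cx, r * 0.8, WHITE)          # lumen
        _stamp_disc(img, cy, cx, r, DARK_BLUE, ring=2.0)  # epithelial ring
    return img


def _tile_carcinoma(rng, t, p) -> np.ndarray:
    img = np.empty((t, t, 3))
    field = _smooth_field(rng, t, sigma=t / 12)
    for c in range(3):
        img[..., c] = (PINK[c] * 0.75 + BLUE[c] * 0.25) + 12.0 * field
    n_nuclei = max(10, int(p.get("carcinoma_nuclei_density", 0.05) * t * t))
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, t, 2)
        shade = rng.uniform(0.75, 1.15)
        _stamp_disc(img, cy, cx, rng.uniform(1.0, 2.8), DARK_BLUE * shade)
    return img


_RECIPES = {1: _tile_stroma, 2: _tile_adipose, 3: _tile_ducts, 4: _tile_carcinoma}


def generate_tile(cls: int, rng: np.random.Generator, tile_size: int,
                  noise_sd: float = 12.0, class_params: dict | None = None) -> np.ndarray:
    img = _RECIPES[cls](rng, tile_size, class_params or {})
    img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate(spec: SyntheticSpec | None = None):
    """All tiles of the given SyntheticSpec, class-ordered. Returns (images, labels)."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for cls, n in zip((1, 2, 3, 4), spec.n_per_class):
        for _ in range(n):
            images.append(generate_tile(cls, rng, spec.tile_size, spec.noise_sd,
                                        spec.class_params))
            labels.append(cls)
    return images, np.array(labels)


def pink_blue_contrast(img) -> float:
    """Mean(R) − mean(B): the construction statistic separating eosin-pink
    content (positive) from hematoxylin-blue-dominated tiles (negative)."""
    a = np.asarray(img, dtype=float)
    return float(a[..., 0].mean() - a[..., 2].mean())


def save_tiles(images, labels, out_dir) -> list[Path]:
    """Write tiles as PNGs into per-class subdirectories (class_1/ … class_4/)."""
    from PIL import Image
    out_dir = Path(out_dir)
    paths = []
    counters: dict[int, int] = {}
    for img, lab in zip(images, labels):
        sub = out_dir / f"class_{lab}"
        sub.mkdir(parents=True, exist_ok=True)
        counters[lab] = counters.get(lab, 0) + 1
        path = sub / f"tile_{counters[lab]:04d}.png"
        Image.fromarray(img).save(path)
        paths.append(path)
    return paths


def load_tiles(data_dir):
    """Read a class_*/ directory tree back into (images, labels)."""
    from PIL import Image
    data_dir = Path(data_dir)
    images, labels = [], []
    for sub in sorted(data_dir.glob("class_*")):
        cls = int(sub.name.split("_")[1])
        for path in sorted(sub.glob("*.png")) + sorted(sub.glob("*.tif")):
            images.append(np.asarray(Image.open(path).convert("RGB")))
            labels.append(cls)
    return images, np.array(labels)
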