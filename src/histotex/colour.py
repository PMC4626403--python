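"""Colour representations of RGB tissue tiles.

Hematoxylin–eosin stained tissue occupies a narrow pink/blue colour gamut, and
different colour models separate its luminance and chrominance structure in
different ways.  This module converts an 8-bit RGB tile into one of eight
representations — RGB, CMYK, HSV, Lab, Luv, a spherical coordinate transform
(SCT), and the two synthetic combinations Lbb = (L, b, b) and Hbb = (H, b, b) —
and reduces any of them to a single scalar plane, the unit every texture
descriptor in this package consumes.

Channels are stored in their native units (hue in degrees, L in 0–100, signed
a/b, …).  :func:`rescale8` maps each channel onto the common 8-bit range
[0, 255] using the model's nominal channel ranges so that histogram and
co-occurrence statistics are comparable across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from skimage import color as _skcolor


class ColourModel(str, Enum):
    RGB = "rgb"
    CMYK = "cmyk"
    HSV = "hsv"
    LAB = "lab"
    LUV = "luv"
    SCT = "sct"
    LBB = "lbb"
    HBB = "hbb"


#: Nominal (low, high) range of each channel, used for the 8-bit rescale.
_CHANNEL_RANGES: dict[ColourModel, list[tuple[float, float]]] = {
    ColourModel.RGB: [(0, 255)] * 3,
    ColourModel.CMYK: [(0, 1)] * 4,
    ColourModel.HSV: [(0, 360), (0, 1), (0, 1)],
    ColourModel.LAB: [(0, 100), (-128, 127), (-128, 127)],
    ColourModel.LUV: [(0, 100), (-134, 220), (-140, 122)],
    ColourModel.SCT: [(0, 255 * np.sqrt(3.0)), (0, 90), (0, 90)],
    ColourModel.LBB: [(0, 100), (-128, 127), (-128, 127)],
    ColourModel.HBB: [(0, 360), (-128, 127), (-128, 127)],
}

_CHANNEL_NAMES: dict[ColourModel, list[str]] = {
    ColourModel.RGB: ["R", "G", "B"],
    ColourModel.CMYK: ["C", "M", "Y", "K"],
    ColourModel.HSV: ["H", "S", "V"],
    ColourModel.LAB: ["L", "a", "b"],
    ColourModel.LUV: ["L", "u", "v"],
    ColourModel.SCT: ["M", "phi", "theta"],
    ColourModel.LBB: ["L", "b", "b"],
    ColourModel.HBB: ["H", "b", "b"],
}


@dataclass
class ColourImage:
    """H×W×C image in one of the supported colour representations."""

    pixels: np.ndarray
    model: ColourModel
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("ColourImage pixels must be H×W×C")
        if not self.channel_names:
            self.channel_names = list(_CHANNEL_NAMES[self.model])


@dataclass
class ChannelImage:
    """Single scalar plane derived from a colour image.

    This is the carrier every descriptor consumes: the intensity bank, the
    space-frequency filters, M-LBP and the texton machinery all operate on a
    2-D real image.
    """

    pixels: np.ndarray
    source_model: ColourModel = ColourModel.RGB
    reduction: str = "channel_mean"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ChannelImage pixels must be finite")


def _as_rgb_array(img) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    return a.astype(float)


def rgb_to_sct(img) -> ColourImage:
    """Spherical coordinate transform of RGB.

    Treats (R, G, B) as a Cartesian vector: M is its length (native range
    [0, 255·√3]; :func:`rescale8` maps it to 8 bits), phi the angle from the
    blue axis to the RG plane, theta the angle between the R and G axes.
    Angles are in degrees.
    Degenerate pixels: M = 0 ⇒ phi := 0; R = 0 ⇒ theta := 90° if G > 0 else 0.
    """
    a = _as_rgb_array(img)
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    m = np.sqrt(r * r + g * g + b * b)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.degrees(np.arccos(np.clip(np.where(m > 0, b / np.where(m > 0, m, 1), 1), -1, 1)))
        theta = np.degrees(np.arctan2(g, r))
    phi = np.where(m > 0, phi, 0.0)
    theta = np.where(r > 0, theta, np.where(g > 0, 90.0, 0.0))
    pixels = np.stack([m, phi, theta], axis=-1)
    return ColourImage(pixels, ColourModel.SCT)


def rgb_to_cmyk(img) -> ColourImage:
    """Standard subtractive conversion; C=M=Y=0 on pure-black pixels."""
    a = _as_rgb_array(img) / 255.0
    k = 1.0 - a.max(axis=-1)
    denom = np.where(k < 1.0, 1.0 - k, 1.0)
    c = np.where(k < 1.0, (1.0 - a[..., 0] - k) / denom, 0.0)
    m = np.where(k < 1.0, (1.0 - a[..., 1] - k) / denom, 0.0)
    y = np.where(k < 1.0, (1.0 - a[..., 2] - k) / denom, 0.0)
    return ColourImage(np.stack([c, m, y, k], axis=-1), ColourModel.CMYK)


def _rgb_to_hsv_deg(a: np.ndarray) -> np.ndarray:
    hsv = _skcolor.rgb2hsv(a / 255.0)
    hsv[..., 0] *= 360.0
    return hsv


def convert(img, model: ColourModel | str) -> ColourImage:
    """Convert an 8-bit RGB tile to any of the eight supported models.

    Lab/Luv use the D65 reference white with sRGB linearization.  Lbb is
    assembled from Lab's (L, b) and Hbb from HSV's hue plus Lab's b; both carry
    the b plane twice so every representation is at least three channels.
    """
    try:
        model = ColourModel(model.lower() if isinstance(model, str) else model)
    except ValueError:
        raise ValueError(
            f"unknown colour model {model!r}; supported: "
            + ", ".join(m.value for m in ColourModel)
        ) from None
    a = _as_rgb_array(img)
    if model is ColourModel.RGB:
        return ColourImage(a.copy(), model)
    if model is ColourModel.SCT:
        return rgb_to_sct(a)
    if model is ColourModel.CMYK:
        return rgb_to_cmyk(a)
    if model is ColourModel.HSV:
        return ColourImage(_rgb_to_hsv_deg(a), model)
    if model is ColourModel.LAB:
        return ColourImage(_skcolor.rgb2lab(a / 255.0), model)
    if model is ColourModel.LUV:
        return ColourImage(_skcolor.rgb2luv(a / 255.0), model)
    if model is ColourModel.LBB:
        lab = _skcolor.rgb2lab(a / 255.0)
        pixels = np.stack([lab[..., 0], lab[..., 2], lab[..., 2]], axis=-1)
        return ColourImage(pixels, model)
    if model is ColourModel.HBB:
        lab = _skcolor.rgb2lab(a / 255.0)
        h = _rgb_to_hsv_deg(a)[..., 0]
        pixels = np.stack([h, lab[..., 2], lab[..., 2]], axis=-1)
        return ColourImage(pixels, model)
    raise AssertionError("unreachable")


def rescale8(img: ColourImage) -> ColourImage:
    """Map every channel onto [0, 255] using its nominal range (clipped)."""
    ranges = _CHANNEL_RANGES[img.model]
    out = np.empty_like(img.pixels)
    for c, (lo, hi) in enumerate(ranges):
        out[..., c] = np.clip((img.pixels[..., c] - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    return ColourImage(out, img.model, list(img.channel_names))


def to_channel(img: ColourImage, reduction: str = "channel_mean",
               channel: int = 0) -> ChannelImage:
    """Reduce a colour image to one scalar plane.

    ``channel_mean`` (default) takes the arithmetic mean across channels —
    one texture bank per colour model; ``single_channel`` selects ``channel``.
    """
    if reduction == "channel_mean":
        plane = img.pixels.mean(axis=-1)
    elif reduction == "single_channel":
        plane = img.pixels[..., channel]
    else:
        raise ValueError("reduction must be 'channel_mean' or 'single_channel'")
    return ChannelImage(plane, img.model, reduction)


def channel_plane(img, model: ColourModel | str) -> ChannelImage:
    """convert → rescale8 → channel mean: the plane the descriptors consume."""
    return to_channel(rescale8(convert(img, model)))
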