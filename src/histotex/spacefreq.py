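"""Space-frequency filtered image stacks: Fourier bands, wavelet details, Gabor.

Each descriptor turns one scalar tile into exactly four filtered images (one
per frequency band / decomposition level / filter scale); the statistics bank
is then run on each, giving 4 × 241 = 964 features per descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import fftconvolve

from .colour import ChannelImage


@dataclass
class FilteredStack:
    """The four filtered images a space-frequency descriptor produces."""

    images: list[ChannelImage]
    descriptor: str
    level_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.level_labels:
            self.level_labels = [f"{self.descriptor}{k + 1}" for k in range(len(self.images))]
        if len(self.level_labels) != len(self.images):
            raise ValueError("one label per image required")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class WaveletConfig:
    levels: int = 4
    family: str = "db5"


@dataclass
class GaborBankConfig:
    """Multiresolution Gabor bank: octave-spaced scales × four orientations.

    ``f1`` is the highest central frequency in cycles/pixel; scale l uses
    f1 / 2^(l−1).  ``gamma``/``eta`` set the Gaussian envelope sharpness along
    the wave / orthogonal axes.
    """

    scales: int = 4
    orientations: int = 4
    f1: float = 0.25
    gamma: float = 1.0
    eta: float = 1.0

    @property
    def frequencies(self) -> list[float]:
        return [self.f1 / 2 ** l for l in range(self.scales)]

    @property
    def thetas(self) -> list[float]:
        return [180.0 * o / self.orientations for o in range(self.orientations)]


def _plane(ch) -> np.ndarray:
    return ch.pixels if isinstance(ch, ChannelImage) else np.asarray(ch, dtype=float)


def fourier_bands(ch, n_bands: int = 4) -> FilteredStack:
    """Partition the centred spectrum into equal-width annuli and invert each.

    The masks are disjoint and exhaustive, so the band images sum back to the
    original tile; band 1 contains the DC term (image mean).
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    img = _plane(ch)
    spec = np.fft.fftshift(np.fft.fft2(img))
    h, w = img.shape
    yy = np.arange(h) - h // 2
    xx = np.arange(w) - w // 2
    r = np.hypot(yy[:, None], xx[None, :])
    edges = np.linspace(0.0, r.max(), n_bands + 1)
    images = []
    for k in range(n_bands):
        mask = (r >= edges[k]) & (r < edges[k + 1]) if k < n_bands - 1 else (r >= edges[k])
        band = np.fft.ifft2(np.fft.ifftshift(spec * mask)).real
        images.append(ChannelImage(band))
    return FilteredStack(images, "fourier", [f"band{k + 1}" for k in range(n_bands)])


def wavelet_details(ch, cfg: WaveletConfig | None = None) -> FilteredStack:
    """Undecimated wavelet decomposition; per level, the three detail images
    (horizontal + vertical + diagonal) are summed into one; the approximation
    is discarded.

    Level labels run from the finest scale (level 1) to the coarsest.  The
    stationary transform needs dimensions divisible by 2^levels, so the tile
    is symmetrically padded and the result cropped back.
    """
    cfg = cfg or WaveletConfig()
    img = _plane(ch)
    block = 2 ** cfg.levels
    wav = pywt.Wavelet(cfg.family)
    if min(img.shape) < wav.dec_len:
        raise ValueError("image smaller than the wavelet filter support")
    pad_h = (-img.shape[0]) % block
    pad_w = (-img.shape[1]) % block
    padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="symmetric")
    coeffs = pywt.swt2(padded, wav, level=cfg.levels)
    # pywt returns the coarsest level first; reorder finest-first
    images = []
    for _, (ch_h, ch_v, ch_d) in reversed(coeffs):
        detail = (ch_h + ch_v + ch_d)[: img.shape[0], : img.shape[1]]
        images.append(ChannelImage(detail))
    return FilteredStack(images, "wavelet", [f"lvl{k + 1}" for k in range(cfg.levels)])


def gabor_kernel(f: float, theta_deg: float, gamma: float = 1.0,
                 eta: float = 1.0) -> np.ndarray:
    """Complex Gabor filter in the spatial domain, DC-corrected.

    G(x, y) = (f²/(π γ η)) · exp(−(f²/γ² x′² + f²/η² y′²)) · exp(j 2π f x′)
    with x′ along the orientation; the kernel mean is subtracted so the
    response to a constant image is zero.
    """
    if f <= 0:
        raise ValueError("central frequency must be positive")
    theta = np.deg2rad(theta_deg)
    half = int(np.ceil(2.5 * max(gamma, eta) / f))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(f ** 2 / gamma ** 2 * xp ** 2 + f ** 2 / eta ** 2 * yp ** 2))
    kern = (f ** 2 / (np.pi * gamma * eta)) * envelope * np.exp(2j * np.pi * f * xp)
    return kern - kern.mean()


def gabor_energies(ch, cfg: GaborBankConfig | None = None) -> FilteredStack:
    """Per scale, the pixelwise sum over orientations of |G * I|."""
    cfg = cfg or GaborBankConfig()
    img = _plane(ch)
    images = []
    for l, f in enumerate(cfg.frequencies):
        energy = np.zeros_like(img)
        for theta in cfg.thetas:
            kern = gabor_kernel(f, theta, cfg.gamma, cfg.eta)
            resp = fftconvolve(img, kern, mode="same")
            energy += np.abs(resp)
        images.append(ChannelImage(energy))
    return FilteredStack(images, "gabor", [f"scale{k + 1}" for k in range(cfg.scales)])
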