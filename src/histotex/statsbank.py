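"""First- and second-order Haralick texture statistics.

The bank comprises 13 first-order statistics of the 256-bin grey-level
histogram and 19 second-order statistics of the grey-level co-occurrence
matrix (GLCM), the latter evaluated at distances {1, 3, 5} pixels and angles
{0°, 45°, 90°, 135°} — 13 + 19·12 = 241 features per scalar image.

Conventions (degenerate inputs matter on synthetic fixtures):

* entropies use the natural logarithm with the non-negative sign convention
  −Σ p log p;
* correlation-type statistics are defined as 0 when a marginal standard
  deviation vanishes (constant image);
* the histogram mode breaks ties toward the smaller grey value, and quartiles
  are the grey values where the cumulative histogram first reaches 1/4, 1/2,
  3/4;
* the GLCM is symmetrized (each pair counted in both directions) and
  normalized to sum 1, computed globally over the tile.

Input images are expected on the 8-bit scale; values are rounded and clipped
to [0, 255] before binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import graycomatrix

from .colour import ChannelImage

DEFAULT_DISTANCES = (1, 3, 5)
DEFAULT_ANGLES = (0, 45, 90, 135)

FIRST_ORDER_NAMES = (
    "mean", "mode", "variance", "q1", "q2", "q3", "iqr",
    "min", "max", "range", "entropy", "skewness", "kurtosis",
)

SECOND_ORDER_NAMES = (
    "energy", "contrast", "correlation", "variance", "sum_average",
    "sum_entropy", "sum_variance", "homogeneity1", "entropy",
    "difference_variance", "difference_entropy", "info_corr1", "info_corr2",
    "homogeneity2", "cluster_shade", "cluster_prominence", "autocorrelation",
    "dissimilarity", "max_probability",
)


@dataclass
class StatFeatureVector:
    """Named real-valued feature vector."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return self.values.size

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    @staticmethod
    def concat(parts: list["StatFeatureVector"]) -> "StatFeatureVector":
        names: list[str] = []
        vals: list[np.ndarray] = []
        for p in parts:
            names.extend(p.names)
            vals.append(p.values)
        return StatFeatureVector(names, np.concatenate(vals) if vals else np.empty(0))


def _quantize(ch) -> np.ndarray:
    px = ch.pixels if isinstance(ch, ChannelImage) else np.asarray(ch, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    return np.clip(np.rint(px), 0, 255).astype(np.uint8)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def grey_histogram(ch, n_levels: int = 256) -> np.ndarray:
    """Normalized grey-level histogram h(i), Σh = 1."""
    q = _quantize(ch)
    h = np.bincount(q.ravel(), minlength=n_levels).astype(float)
    return h / h.sum()


def first_order(ch) -> StatFeatureVector:
    """The 13 histogram statistics (kurtosis is the raw fourth moment ratio)."""
    h = grey_histogram(ch)
    i = np.arange(h.size, dtype=float)
    mu = float((i * h).sum())
    var = float(((i - mu) ** 2 * h).sum())
    sigma = np.sqrt(var)
    present = np.flatnonzero(h > 0)
    # np.argmax returns the first maximiser, i.e. the smaller grey value on ties
    mode = float(np.argmax(h))
    cum = np.cumsum(h)
    q1, q2, q3 = (float(np.searchsorted(cum, q, side="left")) for q in (0.25, 0.5, 0.75))
    mn, mx = float(present.min()), float(present.max())
    skew = float(((i - mu) ** 3 * h).sum() / sigma**3) if sigma > 0 else 0.0
    kurt = float(((i - mu) ** 4 * h).sum() / sigma**4) if sigma > 0 else 0.0
    values = [mu, mode, var, q1, q2, q3, q3 - q1, mn, mx, mx - mn,
              _entropy(h), skew, kurt]
    return StatFeatureVector([f"fo_{n}" for n in FIRST_ORDER_NAMES], np.array(values))


@dataclass
class GLCMatrix:
    """Normalized symmetric co-occurrence matrix with derived quantities."""

    p: np.ndarray
    distance: int
    angle: int
    px: np.ndarray = field(init=False)
    py: np.ndarray = field(init=False)
    p_sum: np.ndarray = field(init=False)   # p_{x+y}(k), k = 0 … 2(N−1)
    p_diff: np.ndarray = field(init=False)  # p_{x−y}(k), k = 0 … N−1
    mu_x: float = field(init=False)
    mu_y: float = field(init=False)
    sigma_x: float = field(init=False)
    sigma_y: float = field(init=False)
    hx: float = field(init=False)
    hy: float = field(init=False)
    hxy: float = field(init=False)
    hxy1: float = field(init=False)
    hxy2: float = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        total = p.sum()
        if not np.isclose(total, 1.0):
            p = p / total
        self.p = p
        n = p.shape[0]
        i = np.arange(n, dtype=float)
        self.px = p.sum(axis=1)
        self.py = p.sum(axis=0)
        self.mu_x = float((i * self.px).sum())
        self.mu_y = float((i * self.py).sum())
        self.sigma_x = float(np.sqrt(((i - self.mu_x) ** 2 * self.px).sum()))
        self.sigma_y = float(np.sqrt(((i - self.mu_y) ** 2 * self.py).sum()))
        # sparse view: co-occurrence matrices of a single tile are mostly empty
        iz, jz = np.nonzero(p)
        vz = p[iz, jz]
        self._iz, self._jz, self._vz = iz.astype(float), jz.astype(float), vz
        self.p_sum = np.bincount(iz + jz, weights=vz, minlength=2 * n - 1)
        self.p_diff = np.bincount(np.abs(iz - jz), weights=vz, minlength=n)
        self.hx = _entropy(self.px)
        self.hy = _entropy(self.py)
        self.hxy = _entropy(vz)
        # −Σ p(i,j)·log(px(i)py(j)) and −Σ px py·log(px py) both reduce to
        # HX + HY exactly (marginals of p are px, py; Σpx = Σpy = 1)
        self.hxy1 = self.hx + self.hy
        self.hxy2 = self.hx + self.hy

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


def glcm(ch, distance: int = 1, angle: int = 0, n_levels: int = 256) -> GLCMatrix:
    """Symmetric normalized GLCM at one (distance, angle) offset.

    Angle follows the usual convention: 0° pairs each pixel with its east
    neighbour, 90° with its north neighbour, 45°/135° with the diagonals.
    """
    q = _quantize(ch)
    if distance >= max(q.shape):
        raise ValueError("offset distance larger than the image")
    m = graycomatrix(q, [distance], [np.deg2rad(angle)], levels=n_levels,
                     symmetric=True, normed=True)[:, :, 0, 0]
    if m.sum() == 0:
        raise ValueError("offset produced no pixel pairs")
    return GLCMatrix(m, distance, angle)


def second_order(m: GLCMatrix, prefix: str = "so") -> StatFeatureVector:
    """The 19 co-occurrence statistics."""
    iz, jz, vz = m._iz, m._jz, m._vz
    diff = np.abs(iz - jz)
    k_sum = np.arange(2 * m.n_levels - 1, dtype=float)
    k_diff = np.arange(m.n_levels, dtype=float)

    energy = float((vz ** 2).sum())
    contrast = float((k_diff ** 2 * m.p_diff).sum())
    ij_moment = float((iz * jz * vz).sum())
    if m.sigma_x > 0 and m.sigma_y > 0:
        correlation = float((ij_moment - m.mu_x * m.mu_y) / (m.sigma_x * m.sigma_y))
    else:
        correlation = 0.0
    mu = (m.mu_x + m.mu_y) / 2.0
    variance = float(((iz - mu) ** 2 * vz).sum())
    sum_average = float((k_sum * m.p_sum).sum())
    sum_entropy = _entropy(m.p_sum)
    sum_variance = float(((k_sum - sum_entropy) ** 2 * m.p_sum).sum())
    homogeneity1 = float((vz / (1.0 + (iz - jz) ** 2)).sum())
    entropy = m.hxy
    difference_variance = float((k_diff ** 2 * m.p_diff).sum())
    difference_entropy = _entropy(m.p_diff)
    denom = max(m.hx, m.hy)
    info_corr1 = float((m.hxy - m.hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (m.hxy2 - m.hxy))
    info_corr2 = float(np.sqrt(max(arg, 0.0)))
    homogeneity2 = float((vz / (1.0 + diff)).sum())
    cs_base = iz + jz - m.mu_x - m.mu_y
    cluster_shade = float((cs_base ** 3 * vz).sum())
    cluster_prominence = float((cs_base ** 4 * vz).sum())
    autocorrelation = ij_moment
    dissimilarity = float((diff * vz).sum())
    max_probability = float(vz.max())

    values = [energy, contrast, correlation, variance, sum_average, sum_entropy,
              sum_variance, homogeneity1, entropy, difference_variance,
              difference_entropy, info_corr1, info_corr2, homogeneity2,
              cluster_shade, cluster_prominence, autocorrelation,
              dissimilarity, max_probability]
    names = [f"{prefix}_d{m.distance}_a{m.angle}_{s}" for s in SECOND_ORDER_NAMES]
    return StatFeatureVector(names, np.array(values))


def statistical_bank(ch, distances=DEFAULT_DISTANCES,
                     angles=DEFAULT_ANGLES) -> StatFeatureVector:
    """Full 241-feature bank: first-order then second-order, distance-major."""
    parts = [first_order(ch)]
    for d in distances:
        for a in angles:
            parts.append(second_order(glcm(ch, d, a)))
    return StatFeatureVector.concat(parts)
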