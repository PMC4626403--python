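"""Transformed-space texture images: mean local binary patterns and textons.

M-LBP thresholds each pixel's eight ring neighbours against the *mean of those
neighbours* (the centre pixel plays no role), producing an 8-bit code image on
which the statistics bank runs directly.

Spatial textons quantize 3×3 intensity patches: per class, k-means compresses
all patch vectors into 60 representative centroids; the concatenated
vocabulary (240 entries for four classes) then relabels every pixel of any
image with the index of its nearest texton, giving a texton map — a second
transformed image for the bank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .colour import ChannelImage

# ring offsets (row, col), p = 0 at the east neighbour, clockwise
_OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class LBPConfig:
    points: int = 8
    radius: int = 1
    variant: str = "mlbp"


def _plane(ch) -> np.ndarray:
    return ch.pixels if isinstance(ch, ChannelImage) else np.asarray(ch, dtype=float)


def mlbp_image(ch, cfg: LBPConfig | None = None) -> ChannelImage:
    """Mean-LBP code image (codes in [0, 255], borders edge-replicated).

    H(0) = 1: a neighbour equal to the neighbourhood mean sets its bit, so a
    constant image codes to 255 everywhere.  Codes are invariant to adding a
    constant to the image and to positive rescaling.
    """
    cfg = cfg or LBPConfig()
    if cfg.points != 8 or cfg.radius != 1:
        raise ValueError("only the (P=8, R=1) ring is supported")
    img = _plane(ch)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3×3")
    padded = np.pad(img, 1, mode="edge")
    h, w = img.shape
    neigh = np.stack([padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
                      for dr, dc in _OFFSETS])
    mean = neigh.mean(axis=0)
    # tolerance keeps the H(0) = 1 tie rule robust to the float summation
    # error of the mean (e.g. eight identical values whose computed mean is
    # one ulp above them must still set every bit)
    tol = 1e-9 * np.maximum(1.0, np.abs(mean))
    bits = (neigh >= mean - tol).astype(np.uint16)
    weights = (2 ** np.arange(8, dtype=np.uint16)).reshape(8, 1, 1)
    codes = (bits * weights).sum(axis=0)
    return ChannelImage(codes.astype(float))


@dataclass
class TextonVocabulary:
    """K patch centroids (9-dim) with the class each was learned from."""

    textons: np.ndarray
    class_of_origin: np.ndarray

    def __post_init__(self) -> None:
        self.textons = np.asarray(self.textons, dtype=float)
        self.class_of_origin = np.asarray(self.class_of_origin)
        if self.textons.ndim != 2 or self.textons.shape[1] != 9:
            raise ValueError("textons must be K×9")
        if len(self.class_of_origin) != len(self.textons):
            raise ValueError("one origin label per texton required")
        if not np.all(np.isfinite(self.textons)):
            raise ValueError("texton centroids must be finite")

    def __len__(self) -> int:
        return len(self.textons)


@dataclass
class TextonMap:
    indices: np.ndarray

    def as_channel(self, k_total: int | None = None) -> ChannelImage:
        """Index map rescaled to [0, 255] for the statistics bank."""
        k = k_total if k_total is not None else max(int(self.indices.max()), 1)
        denom = max(k - 1, 1)
        return ChannelImage(self.indices.astype(float) / denom * 255.0)


def patch_vectors(ch) -> np.ndarray:
    """All 3×3 patches as 9-vectors, one per pixel (edges replicated)."""
    img = _plane(ch)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3×3")
    padded = np.pad(img, 1, mode="edge")
    h, w = img.shape
    cols = [padded[dr:dr + h, dc:dc + w].ravel()
            for dr in range(3) for dc in range(3)]
    return np.stack(cols, axis=1)


def build_vocabulary(images, labels, k_per_class: int = 60, seed: int = 0,
                     max_patches_per_class: int | None = 100_000) -> TextonVocabulary:
    """Per-class k-means over pooled patch vectors; centroids concatenated.

    ``max_patches_per_class`` caps the pooled patch count by seeded
    subsampling, which keeps the fit tractable on full-size tiles without
    changing the centroids appreciably.  If a class yields fewer distinct
    patches than k, k is reduced for that class with a warning.
    """
    labels = np.asarray(labels)
    if len(images) != len(labels):
        raise ValueError("images/labels length mismatch")
    rng = np.random.default_rng(seed)
    centroids: list[np.ndarray] = []
    origins: list[np.ndarray] = []
    for cls in np.unique(labels):
        pool = np.concatenate([patch_vectors(img)
                               for img, lab in zip(images, labels) if lab == cls])
        if max_patches_per_class and len(pool) > max_patches_per_class:
            idx = rng.choice(len(pool), size=max_patches_per_class, replace=False)
            pool = pool[idx]
        n_distinct = len(np.unique(pool, axis=0))
        k = min(k_per_class, n_distinct)
        if k < k_per_class:
            import warnings
            warnings.warn(
                f"class {cls}: only {n_distinct} distinct patches; k reduced to {k}",
                stacklevel=2)
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                    random_state=int(rng.integers(2**31)))
        km.fit(pool)
        centroids.append(km.cluster_centers_)
        origins.append(np.full(k, cls))
    return TextonVocabulary(np.concatenate(centroids), np.concatenate(origins))


def texton_map(ch, vocab: TextonVocabulary, chunk: int = 8192) -> TextonMap:
    """Assign every pixel the index of its Euclidean-nearest texton (1-NN,
    ties broken toward the lowest index)."""
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    vecs = patch_vectors(ch)
    out = np.empty(len(vecs), dtype=np.int64)
    for start in range(0, len(vecs), chunk):
        d = cdist(vecs[start:start + chunk], vocab.textons)
        out[start:start + chunk] = np.argmin(d, axis=1)  # first min wins ties
    return TextonMap(out.reshape(_plane(ch).shape))
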