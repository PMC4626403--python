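"""Feature assembly: colour models × descriptors → named feature vectors.

For each selected colour model the tile is reduced to one scalar plane and the
selected descriptors are run on it; every resulting image gets the 241-entry
statistics bank.  Single-image descriptors (intensity, M-LBP, spatial textons)
contribute 241 features each, four-image descriptors (Fourier, wavelets,
Gabor) 964, so one colour model with all six descriptors yields
3·241 + 3·964 = 3615 features.

Feature names are ``model:descriptor:band:stat`` (e.g.
``sct:gabor:scale2:so_d3_a45_contrast``) and parse back to their provenance
with :func:`parse_feature_name`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import statsbank
from .colour import ChannelImage, ColourModel, channel_plane
from .spacefreq import (FilteredStack, GaborBankConfig, WaveletConfig,
                        fourier_bands, gabor_energies, wavelet_details)
from .transformed import LBPConfig, TextonVocabulary, mlbp_image, texton_map

#: fixed descriptor order; the first three are "single image", the rest "quad"
DESCRIPTOR_ORDER = ("intensity", "fourier", "wavelet", "gabor", "mlbp", "stextons")
SINGLE_IMAGE_DESCRIPTORS = ("intensity", "mlbp", "stextons")
QUAD_IMAGE_DESCRIPTORS = ("fourier", "wavelet", "gabor")


@dataclass
class ExtractionConfig:
    """Which colour models and descriptors to extract, and with what settings."""

    colour_models: Sequence[ColourModel | str] = (ColourModel.RGB,)
    descriptors: Sequence[str] = ("intensity",)
    distances: Sequence[int] = statsbank.DEFAULT_DISTANCES
    angles: Sequence[int] = statsbank.DEFAULT_ANGLES
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    gabor: GaborBankConfig = field(default_factory=GaborBankConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    #: one vocabulary per colour model, required when 'stextons' is selected
    vocabularies: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.colour_models = [ColourModel(m) for m in self.colour_models]
        if not self.colour_models or not self.descriptors:
            raise ValueError("colour model and descriptor selections must be non-empty")
        unknown = set(self.descriptors) - set(DESCRIPTOR_ORDER)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        # canonical order for reproducible columns
        self.descriptors = [d for d in DESCRIPTOR_ORDER if d in self.descriptors]

    def n_features(self) -> int:
        """Closed-form column count for this configuration."""
        bank = 13 + 19 * len(self.distances) * len(self.angles)
        s = sum(1 for d in self.descriptors if d in SINGLE_IMAGE_DESCRIPTORS)
        q = sum(1 for d in self.descriptors if d in QUAD_IMAGE_DESCRIPTORS)
        return len(self.colour_models) * (bank * s + bank * 4 * q)


@dataclass
class FeatureTable:
    """Samples × named features with class labels (1–4)."""

    frame: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.frame):
            raise ValueError("one label per row required")
        if self.frame.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if len(self.frame) and not np.all(np.isfinite(self.frame.to_numpy())):
            raise ValueError("features must be finite")

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, columns: Sequence[str]) -> "FeatureTable":
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing[:5]}")
        return FeatureTable(self.frame[list(columns)], self.labels)

    def subset_rows(self, idx) -> "FeatureTable":
        return FeatureTable(self.frame.iloc[idx], self.labels[idx])

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return FeatureTable(df, labels)


def parse_feature_name(name: str) -> tuple[str, str, str, str]:
    """Invert the ``model:descriptor:band:stat`` naming scheme."""
    model, descriptor, band, stat = name.split(":", 3)
    return model, descriptor, band, stat


def _descriptor_images(plane: ChannelImage, descriptor: str,
                       cfg: ExtractionConfig, model: ColourModel):
    """Yield (band_label, ChannelImage) pairs, bank-ready on the 8-bit scale."""
    if descriptor == "intensity":
        return [("img", plane)]
    if descriptor == "mlbp":
        return [("img", mlbp_image(plane, cfg.lbp))]
    if descriptor == "stextons":
        vocab = cfg.vocabularies.get(model)
        if vocab is None:
            raise ValueError(
                f"'stextons' selected but no texton vocabulary for model {model.value!r}")
        tm = texton_map(plane, vocab)
        return [("map", tm.as_channel(len(vocab)))]
    if descriptor == "fourier":
        stack = fourier_bands(plane)
    elif descriptor == "wavelet":
        stack = wavelet_details(plane, cfg.wavelet)
    elif descriptor == "gabor":
        stack = gabor_energies(plane, cfg.gabor)
    else:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    return [(lab, _rescale_to_8bit(im)) for lab, im in zip(stack.level_labels, stack.images)]


def _rescale_to_8bit(ch: ChannelImage) -> ChannelImage:
    """Min-max rescale a filtered image to [0, 255] (constant image → 0)."""
    px = ch.pixels
    lo, hi = px.min(), px.max()
    if hi - lo < 1e-12:
        return ChannelImage(np.zeros_like(px))
    return ChannelImage((px - lo) / (hi - lo) * 255.0)


def extract(img, cfg: ExtractionConfig) -> statsbank.StatFeatureVector:
    """Feature row for one RGB tile under the given configuration."""
    parts: list[statsbank.StatFeatureVector] = []
    for model in cfg.colour_models:
        plane = channel_plane(img, model)
        for descriptor in cfg.descriptors:
            for band_label, band_img in _descriptor_images(plane, descriptor, cfg, model):
                bank = statsbank.statistical_bank(band_img, cfg.distances, cfg.angles)
                names = [f"{model.value}:{descriptor}:{band_label}:{n}" for n in bank.names]
                parts.append(statsbank.StatFeatureVector(names, bank.values))
    return statsbank.StatFeatureVector.concat(parts)


def feature_columns(cfg: ExtractionConfig) -> list[str]:
    """The exact column header ``extract`` produces, without computing features."""
    bank_names = ([f"fo_{n}" for n in statsbank.FIRST_ORDER_NAMES]
                  + [f"so_d{d}_a{a}_{s}" for d in cfg.distances for a in cfg.angles
                     for s in statsbank.SECOND_ORDER_NAMES])
    band_labels = {"intensity": ["img"], "mlbp": ["img"], "stextons": ["map"],
                   "fourier": [f"band{k+1}" for k in range(4)],
                   "wavelet": [f"lvl{k+1}" for k in range(4)],
                   "gabor": [f"scale{k+1}" for k in range(4)]}
    cols = []
    for model in cfg.colour_models:
        for descriptor in cfg.descriptors:
            for band in band_labels[descriptor]:
                cols.extend(f"{model.value}:{descriptor}:{band}:{n}" for n in bank_names)
    return cols


def build_vocabularies(images, labels, cfg: ExtractionConfig, k_per_class: int = 60,
                       seed: int = 0, max_patches_per_class: int | None = 20_000) -> dict:
    """One texton vocabulary per selected colour model, learned from ``images``."""
    from .transformed import build_vocabulary
    vocabs = {}
    for i, model in enumerate(cfg.colour_models):
        planes = [channel_plane(img, model) for img in images]
        vocabs[model] = build_vocabulary(planes, labels, k_per_class=k_per_class,
                                         seed=seed + i,
                                         max_patches_per_class=max_patches_per_class)
    return vocabs


def extract_dataset(images, labels, cfg: ExtractionConfig,
                    sample_ids: Sequence | None = None) -> FeatureTable:
    """Row-per-tile feature table with a consistent, deterministic header."""
    labels = np.asarray(labels)
    if len(images) != len(labels):
        raise ValueError("images/labels length mismatch")
    header = feature_columns(cfg)
    if len(images) == 0:
        return FeatureTable(pd.DataFrame(columns=header, dtype=float), labels)
    rows = np.empty((len(images), len(header)))
    for i, img in enumerate(images):
        fv = extract(img, cfg)
        if fv.names != header:
            raise AssertionError("extracted names diverge from declared header")
        rows[i] = fv.values
    ids = list(sample_ids) if sample_ids is not None else list(range(len(images)))
    return FeatureTable(pd.DataFrame(rows, columns=header, index=ids), labels)
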