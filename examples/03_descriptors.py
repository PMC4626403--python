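"""The six texture descriptors applied to one tile.

Every descriptor maps the scalar tile to one or more filtered images, and the
241-feature statistics bank is then computed on each:

* intensity  — the plane itself                          → 241 features
* fourier    — four ring-shaped frequency bands          → 964
* wavelet    — four undecimated db5 detail levels        → 964
* gabor      — four multiresolution Gabor energy scales  → 964
* mlbp       — mean-thresholded local binary pattern map → 241
* stextons   — nearest-texton index map (240-word vocabulary) → 241

per colour model: 241 × 2 + 964 × 3 + 241 = 3615 features.

Run:  python examples/03_descriptors.py
"""

import numpy as np

from histotex.colour import channel_plane
from histotex.features import ExtractionConfig, build_vocabularies, extract
from histotex.fixtures import SyntheticSpec, generate
from histotex.spacefreq import fourier_bands, gabor_energies, wavelet_details
from histotex.transformed import build_vocabulary, mlbp_image, texton_map


def main() -> None:
    images, labels = generate(SyntheticSpec((2, 2, 2, 2), 64, seed=5))
    plane = channel_plane(images[0], "rgb")

    for name, stack in (("fourier", fourier_bands(plane)),
                        ("wavelet", wavelet_details(plane)),
                        ("gabor", gabor_energies(plane))):
        energies = [float((im.pixels ** 2).mean()) for im in stack.images]
        print(f"{name:8} bands {stack.level_labels}  "
              f"mean energies {np.round(energies, 2)}")

    codes = mlbp_image(plane)
    print(f"mlbp     codes in [{codes.pixels.min():.0f}, "
          f"{codes.pixels.max():.0f}], "
          f"{len(np.unique(codes.pixels))} distinct patterns")

    planes = [channel_plane(img, "rgb").pixels for img in images]
    vocab = build_vocabulary(planes, labels, k_per_class=10, seed=0)
    tm = texton_map(plane, vocab)
    print(f"stextons {len(vocab)}-word vocabulary, "
          f"{len(np.unique(tm.indices))} textons used on this tile")

    # and the whole thing through the feature extractor
    cfg = ExtractionConfig(colour_models=["rgb"],
                           descriptors=["intensity", "fourier", "wavelet",
                                        "gabor", "mlbp", "stextons"])
    cfg.vocabularies = build_vocabularies(images, labels, cfg, k_per_class=10,
                                          seed=0)
    fv = extract(images[0], cfg)
    print(f"\nfull extraction: {len(fv)} features; first 3 names:")
    for n in fv.names[:3]:
        print(f"  {n}")


if __name__ == "__main__":
    main()
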