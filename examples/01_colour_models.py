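"""Walk one synthetic tile through all eight colour models.

Each tissue tile is re-expressed in RGB, CMYK, HSV, CIELAB, CIELUV, the
spherical SCT model and the two hybrid models Lb (L, b, b) and Hb (H, b, b).
For texture analysis every converted image is collapsed to a single scalar
plane: channels are rescaled to the 8-bit range and averaged.  This script
prints the native channel ranges and the resulting scalar-plane statistics so
you can see what each model emphasises.

Run:  python examples/01_colour_models.py
"""

import numpy as np

from histotex.colour import channel_plane, convert
from histotex.fixtures import SyntheticSpec, generate

MODELS = ["rgb", "cmyk", "hsv", "lab", "luv", "sct", "lbb", "hbb"]


def main() -> None:
    images, labels = generate(SyntheticSpec((1, 1, 1, 1), 64, seed=0))
    tile = images[0]  # a stroma tile: pink field with sparse blue nuclei

    print(f"tile: {tile.shape}, dtype {tile.dtype}, "
          f"mean RGB {tile.reshape(-1, 3).mean(axis=0).round(1)}\n")
    header = f"{'model':6} {'channels':28} {'plane mean':>10} {'plane sd':>9}"
    print(header)
    print("-" * len(header))
    for model in MODELS:
        img = convert(tile, model)
        ranges = ", ".join(
            f"{img.pixels[..., c].min():.0f}..{img.pixels[..., c].max():.0f}"
            for c in range(img.pixels.shape[-1]))
        plane = channel_plane(tile, model)
        print(f"{model:6} {ranges:28} {plane.pixels.mean():10.2f} "
              f"{plane.pixels.std():9.2f}")

    # the hybrid models duplicate the chromatic b channel on purpose: pink
    # (eosin) vs blue (hematoxylin) content lives mostly on the b axis
    lab = convert(tile, "lab")
    lbb = convert(tile, "lbb")
    assert np.array_equal(lbb.pixels[..., 1], lab.pixels[..., 2])
    print("\nLb model = (L, b, b): its two chroma planes equal CIELAB b.")


if __name__ == "__main__":
    main()
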