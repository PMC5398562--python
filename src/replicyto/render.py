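"""Synthetic fluorescence image formation.

Renders a population table into a multi-channel 16-bit image: one channel for
the DNA stain, one for the replication label (specific + background signal),
and one per protein channel.  Nuclei are hard discs whose pixel values
integrate to ``pixel_scale x signal``; optics and camera are modelled as
Gaussian PSF blur, a constant offset, Poisson shot noise and Gaussian read
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, PlacementError
from .params import ImageModel
from .population import protein_columns


@dataclass(frozen=True)
class MultiChannelImage:
    """A (C, H, W) uint16 stack with named channels."""

    data: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channels):
            raise ParameterError("data must be (C, H, W) with one name per channel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channels.index(name)
        except ValueError:
            raise ParameterError(
                f"no channel {name!r}; available: {', '.join(self.channels)}"
            ) from None
        return self.data[i]

    def save_tiff(self, path) -> None:
        """Write a multi-page TIFF, one page per channel, channel name in the
        page description tag."""
        with tifffile.TiffWriter(str(path)) as tif:
            for name, page in zip(self.channels, self.data):
                tif.write(page, description=name, photometric="minisblack")

    @classmethod
    def load_tiff(cls, path) -> "MultiChannelImage":
        with tifffile.TiffFile(str(path)) as tif:
            pages = [p.asarray() for p in tif.pages]
            names = [p.description or f"channel_{i}" for i, p in enumerate(tif.pages)]
        return cls(np.stack(pages), tuple(names))


def channel_signals(pop: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-channel total AU signal of each nucleus.

    ``dna`` carries the DNA content; ``label`` the sum of specific and
    background signal (unlabelled nuclei therefore show background only);
    protein channels carry their per-cell values.
    """
    n = len(pop)
    out = {
        "dna": pop["dna_content"].to_numpy() if n else np.array([]),
        "label": (
            (pop["specific_signal"] + pop["background_signal"]).to_numpy()
            if n
            else np.array([])
        ),
    }
    for ch in protein_columns(pop):
        out[f"protein_{ch}"] = pop[f"protein_{ch}"].to_numpy()
    return out


def disc_mask(radius: float) -> np.ndarray:
    """Boolean disc of the given radius sampled at pixel centres."""
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= radius * radius


def fit_image_model(pop: pd.DataFrame, **overrides) -> ImageModel:
    """An :class:`ImageModel` sized so every nucleus fits at its radius.

    Uses the layout extent recorded by the simulator when available,
    otherwise the bounding box of the discs plus a margin.  Keyword overrides
    are forwarded to :class:`ImageModel`.
    """
    if len(pop):
        margin = 4
        w = int(math.ceil((pop["center_x"] + pop["radius"]).max())) + margin
        h = int(math.ceil((pop["center_y"] + pop["radius"]).max())) + margin
        w = max(w, int(pop.attrs.get("field_width", 0)))
        h = max(h, int(pop.attrs.get("field_height", 0)))
    else:
        w = h = 256
    overrides.setdefault("width", w)
    overrides.setdefault("height", h)
    return ImageModel(**overrides)


def render_image(
    pop: pd.DataFrame, model: ImageModel, seed: int = 0
) -> MultiChannelImage:
    """Render a population into a multi-channel 16-bit image.

    Each nucleus is drawn as a filled disc whose pixel sum equals
    ``pixel_scale x signal`` exactly (the per-pixel value divides by the
    disc's actual pixel count, so discretisation does not lose flux).  The
    stack is then blurred by the PSF, offset, and corrupted by Poisson and
    read noise when enabled; output is clipped to the 16-bit range.
    Deterministic for a fixed seed.
    """
    h, w = model.height, model.width
    signals = channel_signals(pop)
    names = tuple(signals)
    stack = np.zeros((len(names), h, w), dtype=np.float64)

    if len(pop):
        cx = pop["center_x"].to_numpy()
        cy = pop["center_y"].to_numpy()
        rad = pop["radius"].to_numpy()
        bad = (cx - rad < 0) | (cx + rad > w - 1) | (cy - rad < 0) | (cy + rad > h - 1)
        if bad.any():
            ids = pop["nucleus_id"].to_numpy()[bad][:5]
            raise PlacementError(
                f"{int(bad.sum())} nuclei fall outside the {w}x{h} image "
                f"bounds at their radius (first ids: {ids.tolist()})"
            )
        per_channel = np.stack([signals[name] for name in names])
        for i in range(len(pop)):
            mask = disc_mask(rad[i])
            npix = int(mask.sum())
            r = mask.shape[0] // 2
            x0, y0 = int(round(cx[i])) - r, int(round(cy[i])) - r
            ys = slice(max(y0, 0), min(y0 + mask.shape[0], h))
            xs = slice(max(x0, 0), min(x0 + mask.shape[1], w))
            sub = mask[ys.start - y0 : ys.stop - y0, xs.start - x0 : xs.stop - x0]
            for c in range(len(names)):
                stack[c, ys, xs][sub] += model.pixel_scale * per_channel[c, i] / npix

    if model.psf_sigma > 0:
        for c in range(len(names)):
            stack[c] = gaussian_filter(stack[c], model.psf_sigma, mode="reflect")

    stack += model.background_offset

    rng = np.random.default_rng(seed)
    if model.poisson_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
    if model.read_noise_sigma > 0:
        stack += rng.normal(0.0, model.read_noise_sigma, stack.shape)

    out = np.clip(np.rint(stack), 0, model.max_count).astype(np.uint16)
    return MultiChannelImage(out, names)


def expected_pixel_sum(pop: pd.DataFrame, model: ImageModel) -> dict[str, float]:
    """Noise-free total flux per channel: offset area + pixel_scale x signals."""
    area = model.width * model.height
    return {
        name: model.background_offset * area + model.pixel_scale * float(sig.sum())
        for name, sig in channel_signals(pop).items()
    }


__all__ = [
    "MultiChannelImage",
    "channel_signals",
    "disc_mask",
    "expected_pixel_sum",
    "fit_image_model",
    "render_image",
]
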