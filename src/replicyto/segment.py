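"""Nuclear segmentation and per-nucleus quantification.

The CellProfiler-equivalent stage: DNA channel -> label image -> measurement
table.  Pipeline: Gaussian smoothing, global threshold (Otsu or fixed),
8-connected components, optional distance-transform watershed split of
touching nuclei, minimum-area filter, consecutive relabelling.

Coordinates follow the image convention used throughout the package: origin
at the top-left pixel centre, x = column, y = row.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.segmentation import relabel_sequential, watershed

from .errors import ParameterError
from .params import SegmentationParams
from .render import MultiChannelImage

log = logging.getLogger(__name__)


def segment_nuclei(
    dna_channel: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Segment nuclei in a DNA-stain image.

    Returns an integer label image of the same shape: 0 is background and
    labels 1..K are nuclei, consecutive, each of at least ``min_area``
    pixels.  A constant image under Otsu thresholding yields an empty result
    with a degenerate-threshold warning rather than an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(dna_channel, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError(f"expected a 2D image, got shape {img.shape}")
    if img.size and img.min() < 0:
        raise ParameterError("image must be non-negative")

    smoothed = (
        gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
        if params.smoothing_sigma > 0
        else img
    )

    if params.threshold_method == "fixed":
        thr = params.fixed_threshold
    else:
        if smoothed.min() == smoothed.max():
            warnings.warn(
                "constant image: Otsu threshold is degenerate; returning an "
                "empty segmentation",
                RuntimeWarning,
                stacklevel=2,
            )
            return np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)

    mask = smoothed > thr
    labels = cc_label(mask, connectivity=2)

    if params.split_touching and labels.max() > 0:
        distance = ndi.distance_transform_edt(mask)
        # Marker spacing tied to the smallest acceptable nucleus size.
        min_dist = max(3, int(round(np.sqrt(params.min_area))))
        coords = peak_local_max(
            distance, min_distance=min_dist, labels=labels, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        if len(coords):
            labels = watershed(-distance, markers, mask=mask)

    if labels.max() > 0 and params.min_area > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < params.min_area)
        small = small[small > 0]
        if len(small):
            labels[np.isin(labels, small)] = 0

    labels, _, _ = relabel_sequential(labels)
    log.info(
        "segment_nuclei: %d nuclei (threshold=%.4g, method=%s)",
        labels.max(), thr, params.threshold_method,
    )
    return labels.astype(np.int32)


#: Measurement-table schema version (bumps when columns change).
MEASUREMENT_SCHEMA_VERSION = 1


def quantify_nuclei(
    labels: np.ndarray, image: MultiChannelImage
) -> pd.DataFrame:
    """Measure every labelled nucleus in a multi-channel image.

    Returns one row per label with ``nucleus_id``, ``area``, ``centroid_x``,
    ``centroid_y`` and, per channel, ``mean_<channel>`` and
    ``integrated_<channel>`` (mean x area).  The camera background offset is
    *not* subtracted here; that is a statistics-layer choice.
    """
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise ParameterError(
            f"label image shape {labels.shape} does not match image {image.shape}"
        )
    base = regionprops_table(
        labels, properties=("label", "area", "centroid")
    )
    table = pd.DataFrame(
        {
            "nucleus_id": base["label"].astype(np.int64),
            "area": base["area"].astype(float),
            "centroid_x": base["centroid-1"],
            "centroid_y": base["centroid-0"],
        }
    )
    for name in image.channels:
        props = regionprops_table(
            labels,
            intensity_image=image.channel(name).astype(np.float64),
            properties=("label", "intensity_mean"),
        )
        table[f"mean_{name}"] = props["intensity_mean"]
        table[f"integrated_{name}"] = props["intensity_mean"] * table["area"]
    log.info("quantify_nuclei: %d nuclei x %d channels", len(table), len(image.channels))
    return table


__all__ = ["MEASUREMENT_SCHEMA_VERSION", "quantify_nuclei", "segment_nuclei"]
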