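"""Per-frame binary lumen masks.

Three mask sources are supported: ground-truth passthrough (an existing
binary array), a classical baseline segmenter (global Otsu threshold plus
connected-component selection), and an adapter that reads per-frame mask
PNGs produced by an external model (see :mod:`aortapipe.io`).

The baseline is not a trained model: on the synthetic imagery the lumen is
the brightest coherent structure, so a global threshold followed by
selection of the large central component recovers it. Component selection
also guards against segmenting a physiological lumen or cavity other than
the aorta, which is the failure mode the downstream QC cascade targets.
"""

from __future__ import annotations

import numpy as np
from skimage import filters, measure

__all__ = ["segment_frame_baseline", "select_primary_component", "MIN_COMPONENT_PX"]

# below the 3 cm² QC floor at default spacing; suppresses speckle
MIN_COMPONENT_PX = 20


def select_primary_component(
    mask: np.ndarray,
    reference_point: tuple[float, float] | None = None,
) -> np.ndarray:
    """Keep the single component maximizing size / (1 + distance-to-reference).

    ``reference_point`` is a (row, col) pixel coordinate; it defaults to the
    image centre, where the ascending aorta sits by acquisition protocol.
    An empty mask is returned unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    if reference_point is None:
        reference_point = ((mask.shape[0] - 1) / 2.0, (mask.shape[1] - 1) / 2.0)
    labels = measure.label(mask, connectivity=2)
    best_label, best_score = 0, -np.inf
    for region in measure.regionprops(labels):
        dist = np.hypot(
            region.centroid[0] - reference_point[0],
            region.centroid[1] - reference_point[1],
        )
        score = region.area / (1.0 + dist)
        if score > best_score:
            best_score, best_label = score, region.label
    return labels == best_label


def segment_frame_baseline(
    image: np.ndarray,
    reference_point: tuple[float, float] | None = None,
    min_size: int = MIN_COMPONENT_PX,
) -> np.ndarray:
    """Otsu threshold → component selection → binary lumen mask.

    Returns an all-zero mask (never raises) when the image is constant or
    no component passes the minimum-size floor.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D brightness image")
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=bool)
    threshold = filters.threshold_otsu(image.astype(float))
    foreground = image > threshold
    labels = measure.label(foreground, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes >= min_size
    if not keep.any():
        return np.zeros(image.shape, dtype=bool)
    foreground = keep[labels]
    return select_primary_component(foreground, reference_point)
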