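"""Derive weak annotations from full instance masks and from nucleus images.

Two machine-generatable weak-annotation channels are supported:

* an *image-level mask* — the union of all cell masks, carrying no
  instance identity;
* *locations-of-interest* (LOIs) — one approximate point per cell,
  either the center of mass of a known instance mask or a blob detected
  in a nucleus-stain channel (e.g. DAPI) with a difference-of-Gaussian
  (DoG) band-pass filter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import InstanceSet, WeakAnnotation, as_loi_array

__all__ = [
    "instances_to_image_mask",
    "instances_to_lois",
    "detect_lois_dog",
    "weak_annotation_from_instances",
    "otsu_image_mask",
]

#: DoG scales (pixels) used for nucleus blob detection by default.
DEFAULT_SIGMA_LOW = 4.2
DEFAULT_SIGMA_HIGH = 5.0

# 4-connected neighborhood footprint for local-maximum search
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def instances_to_image_mask(
    instances: InstanceSet, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Union of all instance masks: pixel is foreground iff it belongs to >=1 cell.

    An empty instance set yields an all-background mask (``shape`` must
    then be given).
    """
    if len(instances) == 0:
        if shape is None:
            raise ValueError("shape required for an empty instance set")
        return np.zeros(shape, dtype=bool)
    out = np.zeros(instances.shape, dtype=bool)
    for m in instances.masks:
        out |= m
    return out


def instances_to_lois(instances: InstanceSet) -> np.ndarray:
    """Center of mass of each instance mask, in instance order.

    Returns an (n, 2) float array of (row, col); centroids may be
    fractional.  Empty masks are rejected by the :class:`InstanceSet`
    invariant before we get here.
    """
    lois = [ndimage.center_of_mass(m) for m in instances.masks]
    return as_loi_array(lois)


def dog_filter(
    image: np.ndarray,
    sigma_low: float = DEFAULT_SIGMA_LOW,
    sigma_high: float = DEFAULT_SIGMA_HIGH,
) -> np.ndarray:
    """Difference-of-Gaussian band-pass response (low minus high scale)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("nucleus image must be single-channel 2-D")
    if not sigma_low < sigma_high:
        raise ValueError("sigma_low must be smaller than sigma_high")
    return ndimage.gaussian_filter(image, sigma_low) - ndimage.gaussian_filter(
        image, sigma_high
    )


def detect_lois_dog(
    nucleus_image: np.ndarray,
    sigma_low: float = DEFAULT_SIGMA_LOW,
    sigma_high: float = DEFAULT_SIGMA_HIGH,
    min_peak: float | None = None,
) -> np.ndarray:
    """Detect nucleus LOIs as 4-connected local maxima of the DoG response.

    Parameters
    ----------
    nucleus_image
        Single-channel 2-D intensity image (any dtype).
    sigma_low, sigma_high
        Gaussian scales in pixels of the band-pass filter (defaults
        4.2 and 5).
    min_peak
        Minimum DoG value of a reported maximum.  When ``None`` a robust
        noise floor is used: 3 x 1.4826 x MAD of the DoG image.

    Returns
    -------
    (n, 2) float array of integer-valued (row, col) peak locations.
    Plateaus of equal maximal value are collapsed to their (rounded)
    centroid so ties never produce duplicate LOIs.  Maxima near the
    border are kept; nuclei at the image edge are real cells.
    """
    dog = dog_filter(nucleus_image, sigma_low, sigma_high)
    if min_peak is None:
        mad = np.median(np.abs(dog - np.median(dog)))
        min_peak = 3.0 * 1.4826 * mad
    # local maxima under 4-connectivity; plateaus pass the >= comparison
    local_max = dog >= ndimage.maximum_filter(dog, footprint=_CROSS, mode="nearest")
    candidates = local_max & (dog > min_peak)
    if not candidates.any():
        return as_loi_array([])
    # collapse each 4-connected plateau of equal value to one LOI
    labels, n = ndimage.label(candidates, structure=_CROSS)
    lois = []
    for idx in range(1, n + 1):
        rr, cc = np.nonzero(labels == idx)
        vals = dog[rr, cc]
        if np.ptp(vals) < 1e-12 * max(1.0, abs(vals[0])):
            r, c = rr.mean(), cc.mean()
        else:  # ridge of unequal values: keep the true maximum
            k = int(np.argmax(vals))
            r, c = rr[k], cc[k]
        lois.append((round(float(r)), round(float(c))))
    lois.sort()
    return as_loi_array(lois)


def weak_annotation_from_instances(instances: InstanceSet) -> WeakAnnotation:
    """Full -> weak conversion: union mask plus center-of-mass LOIs."""
    return WeakAnnotation(
        image_mask=instances_to_image_mask(instances),
        lois=instances_to_lois(instances),
    )


def otsu_image_mask(image: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Convenience Otsu-threshold foreground mask.

    A fallback for when no externally produced image-level mask exists;
    not part of the core method (real pipelines typically use an
    interactive graph-cut tool).
    """
    from skimage.filters import threshold_otsu

    img = ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), smooth_sigma)
    return img > threshold_otsu(img)
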