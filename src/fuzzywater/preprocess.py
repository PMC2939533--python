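"""Image conditioning stages: Gaussian smoothing, normalization, background removal.

These are the first three of the six consecutive operations applied to a
perfusion volume before edge detection and segmentation:

(i)   isotropic Gaussian 3D smoothing with the filter *radius* as the first
      tunable parameter (radius is interpreted as the Gaussian sigma in
      voxels, kernel truncated at 4 sigma, reflect boundary handling);
(ii)  intensity normalization to (0, 1] so unit intensity corresponds to
      maximum brain activity;
(iii) soft background elimination against a threshold theta in (0, 1): the
      positive difference ``max(v - theta, 0)`` is passed, negative
      differences are set to zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import as_array, wrap_like

#: kernel truncation, in units of sigma
GAUSSIAN_TRUNCATE = 4.0


@dataclasses.dataclass(frozen=True)
class PipelineParams:
    """The three tunable parameters of the analysis pipeline.

    gaussian_radius
        sigma of the isotropic smoothing kernel, in voxels (> 0).
    background_threshold
        normalized-intensity threshold theta in (0, 1).
    region_cutoff
        critical number of watershed regions separating the reduced-count
        (AD-like) class from the control-like class (> 0).
    """

    gaussian_radius: float
    background_threshold: float
    region_cutoff: float

    def __post_init__(self):
        if not self.gaussian_radius > 0:
            raise ValueError("gaussian_radius must be > 0")
        if not 0 < self.background_threshold < 1:
            raise ValueError("background_threshold must lie in (0, 1)")
        if not self.region_cutoff > 0:
            raise ValueError("region_cutoff must be > 0")


def gaussian_smooth(vol, radius: float):
    """Convolve with an isotropic 3D Gaussian of standard deviation ``radius``.

    The kernel is normalized to unit sum and truncated at 4 sigma; volume
    boundaries are handled by reflection so constant volumes are preserved
    exactly.  Output shape equals input shape.
    """
    if not radius > 0:
        raise ValueError("smoothing radius must be > 0")
    arr = as_array(vol)
    out = ndimage.gaussian_filter(arr, sigma=float(radius), mode="reflect",
                                  truncate=GAUSSIAN_TRUNCATE)
    return wrap_like(vol, out)


def normalize_intensity(vol):
    """Divide by the global maximum so the output maximum is exactly 1."""
    arr = as_array(vol)
    peak = arr.max()
    if not peak > 0:
        raise ValueError("cannot normalize zero volume")
    return wrap_like(vol, arr / peak)


def eliminate_background(vol, threshold: float):
    """Soft-threshold a normalized volume: ``out = max(v - threshold, 0)``.

    The positive difference itself is passed (not the original value);
    negative differences are set to zero.  Input must already be
    normalized to [0, 1].
    """
    if not 0 < threshold < 1:
        raise ValueError("background threshold must lie in (0, 1)")
    arr = as_array(vol)
    if arr.min() < 0 or arr.max() > 1 + 1e-12:
        raise ValueError("eliminate_background expects a normalized volume in [0, 1]")
    return wrap_like(vol, np.maximum(arr - threshold, 0.0))
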