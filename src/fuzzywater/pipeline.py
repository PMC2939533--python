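"""End-to-end processing of one volume: the six consecutive operations.

smoothing -> normalization -> background elimination -> fuzzy edge
detection -> watershed segmentation -> ROI region counting.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fuzzy_edge import fuzzy_edge_volume
from .preprocess import eliminate_background, gaussian_smooth, normalize_intensity
from .volume_io import BrainVolume, as_array, default_parietal_rois
from .watershed import count_regions_per_side, watershed_transform


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    count_total: int
    count_left: int
    count_right: int
    labels: np.ndarray
    intermediates: dict | None = None


def process_volume(
    vol,
    radius: float,
    threshold: float,
    rois=None,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Run the full pipeline on one volume and count ROI watershed regions.

    ``rois`` defaults to the mirrored parietal boxes for the volume's shape.
    With ``keep_intermediates`` the smoothed, normalized, thresholded and
    edge volumes are returned alongside the label volume.
    """
    arr = as_array(vol)
    if isinstance(vol, np.ndarray):
        vol = BrainVolume(arr)
    if rois is None:
        rois = default_parietal_rois(arr.shape)
    def stage(name, fn, *args):
        try:
            return fn(*args)
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc

    smoothed = stage("smoothing", gaussian_smooth, arr, radius)
    normalized = stage("normalization", normalize_intensity, smoothed)
    foreground = stage("background elimination", eliminate_background,
                       normalized, threshold)
    edges = stage("fuzzy edge detection", fuzzy_edge_volume, foreground)
    labels = stage("watershed", watershed_transform, edges)
    counts = stage("region counting", count_regions_per_side, labels, rois)
    intermediates = None
    if keep_intermediates:
        intermediates = {
            "smoothed": smoothed,
            "normalized": normalized,
            "thresholded": foreground,
            "edges": edges,
        }
    return PipelineResult(
        count_total=counts["total"],
        count_left=counts["left"],
        count_right=counts["right"],
        labels=labels,
        intermediates=intermediates,
    )
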