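"""Mask construction: tissue, nuclei, marker-positive cells, vessels.

This stage mirrors a slide-scanner quantification workflow: a tissue mask
normalizes intensities to the imaged tissue area, Hoechst nuclei are
detected by smoothing, thresholding and optional watershed splitting, and
each marker channel (IBA1, GFAP, PDGFRB, lectin, OATP) is thresholded
within tissue and decomposed into connected objects.  Pixels positive for
both IBA1 and lectin are assigned to vessels (vessel priority), so
peri-vascular myeloid signal is not double counted; the rule is
configurable.

Conventions: foreground is strictly greater than the threshold,
connectivity is 8-neighbor, and coordinates are 0-based (row, col) with
the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as _cc_label
from skimage.morphology import disk as _disk_footprint
from skimage.segmentation import watershed as _watershed

from .types import CHANNELS, CaseImage, SegmentationResult

__all__ = [
    "SegmentationParams",
    "otsu_threshold",
    "threshold_channel",
    "tissue_mask",
    "segment_nuclei",
    "marker_objects",
    "segment_case",
    "control_percentile_thresholds",
]


@dataclass
class SegmentationParams:
    """Explicit parameters of the mask-building stage.

    ``threshold_method`` is one of ``otsu`` (per channel, per case),
    ``fixed`` (values from ``fixed_thresholds``) or ``control_percentile``
    (per-channel thresholds precomputed as a quantile of pooled
    control-cohort pixel or object values, supplied through
    ``fixed_thresholds``).  ``min_object_area`` of 30 px at 0.325 um/px
    discards sub-nuclear fragments of roughly 3 um^2.
    """

    threshold_method: str = "otsu"
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    control_percentile: float = 0.99
    min_object_area: int = 30
    nucleus_radius_range: tuple[int, int] = (3, 8)
    watershed_split: bool = True
    morphological_cleanup: int = 1  # opening radius, px
    smooth_sigma: float = 1.0
    vessel_priority: bool = True

    def validate(self) -> None:
        if not (0.0 < self.control_percentile < 1.0):
            raise ValueError("control_percentile must lie in (0, 1)")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if self.threshold_method not in ("otsu", "fixed", "control_percentile"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


def otsu_threshold(intensity_histogram) -> float:
    """Threshold maximizing between-class variance over a value histogram.

    ``intensity_histogram`` is a pair ``(values, counts)`` of distinct
    intensity values and their pixel counts (an image array is also
    accepted and histogrammed over its distinct values).  Pixels strictly
    greater than the returned threshold are foreground.  The maximizer is
    found by exhaustive scan of every candidate split.
    """
    if isinstance(intensity_histogram, tuple) and len(intensity_histogram) == 2:
        values = np.asarray(intensity_histogram[0], dtype=float)
        counts = np.asarray(intensity_histogram[1], dtype=float)
        keep = counts > 0
        values, counts = values[keep], counts[keep]
        order = np.argsort(values)
        values, counts = values[order], counts[order]
    else:
        img = np.asarray(intensity_histogram, dtype=float).ravel()
        if img.size == 0:
            raise ValueError("empty histogram")
        values, counts = np.unique(img, return_counts=True)
        counts = counts.astype(float)
    if values.size == 0:
        raise ValueError("empty histogram")
    if values.size == 1:
        raise ValueError("degenerate histogram: single distinct value")
    total = counts.sum()
    csum = np.cumsum(counts)
    cmean = np.cumsum(counts * values)
    grand = cmean[-1]
    # candidate thresholds: each value except the last (foreground = v > t)
    w0 = csum[:-1]
    w1 = total - w0
    mu0 = cmean[:-1] / w0
    mu1 = (grand - cmean[:-1]) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(values[np.argmax(between)])


def _background_stats(channel: np.ndarray, bins: int = 256) -> tuple[float, float]:
    """Background level and noise scale of one channel.

    The background population is located as the lowest-intensity histogram
    peak (first bin reaching half the maximum count, so a bright foreground
    population never wins even when it covers most of the frame); its
    median and standard deviation are estimated from the pixels in a
    window around that peak.
    """
    vmin, vmax = float(channel.min()), float(channel.max())
    if vmax == vmin:
        return vmin, 0.0
    counts, edges = np.histogram(channel, bins=bins, range=(vmin, vmax))
    # background = the dimmest substantial population: the lowest local
    # peak of the (lightly smoothed) histogram holding at least 20% of the
    # maximum count, so a bright population never wins merely by covering
    # most of the frame
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    left = np.r_[-np.inf, smooth[:-1]]
    right = np.r_[smooth[1:], -np.inf]
    peaks = np.nonzero((smooth >= left) & (smooth >= right) & (smooth >= 0.2 * smooth.max()))[0]
    k = int(peaks[0]) if peaks.size else int(np.argmax(smooth))
    bg = 0.5 * (edges[k] + edges[k + 1])
    below = bg - channel[channel < bg]
    sigma = 1.4826 * float(np.median(below)) if below.size else 0.0
    return bg, sigma


def threshold_channel(
    channel: np.ndarray,
    params: SegmentationParams,
    channel_name: str | None = None,
    within: np.ndarray | None = None,
) -> float:
    """Resolve the threshold for one channel according to ``params``.

    With Otsu on a degenerate (single-valued) channel, falls back to the
    fixed threshold for that channel if one is provided, else raises.
    """
    params.validate()
    if params.threshold_method in ("fixed", "control_percentile"):
        if channel_name is None or channel_name not in params.fixed_thresholds:
            raise KeyError(f"no fixed threshold provided for channel {channel_name!r}")
        return float(params.fixed_thresholds[channel_name])
    pixels = channel[within] if within is not None else channel
    try:
        thr = otsu_threshold(pixels)
    except ValueError:
        if channel_name is not None and channel_name in params.fixed_thresholds:
            return float(params.fixed_thresholds[channel_name])
        raise
    # floor at the above-background criterion so a markerless channel
    # (unimodal noise) yields no foreground instead of split noise
    bg, sigma = _background_stats(channel)
    return max(thr, bg + 4.0 * sigma)


def tissue_mask(case: CaseImage | dict[str, np.ndarray], params: SegmentationParams) -> np.ndarray:
    """Binary tissue mask: union of per-channel above-background pixels.

    Background of each channel is estimated as its modal value; a pixel is
    above background when it exceeds the mode by four robust (MAD-based)
    standard deviations.  The union is morphologically closed and
    hole-filled.  Used to normalize integrated intensities to imaged
    tissue (ROI) area.
    """
    channels = case.channels if isinstance(case, CaseImage) else case
    arrays = list(channels.values())
    if not arrays or arrays[0].size == 0:
        raise ValueError("empty image")
    union = np.zeros(arrays[0].shape, dtype=bool)
    for ch in arrays:
        bg, sigma = _background_stats(ch)
        union |= ch > bg + 4.0 * sigma
    radius = max(1, params.morphological_cleanup) + 1
    fp = _disk_footprint(radius)
    # pad so closing does not erode objects touching the image border
    padded = np.pad(union, radius, mode="edge")
    closed = ndimage.binary_closing(padded, structure=fp)[radius:-radius, radius:-radius]
    return ndimage.binary_fill_holes(closed)


def _relabel_filtered(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Drop objects below ``min_area`` px and relabel contiguously from 1."""
    if labels.max() == 0:
        return labels.astype(np.int32)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return lut[labels]


def segment_nuclei(hoechst: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Label map of nuclei from the Hoechst counterstain.

    Gaussian smoothing, Otsu threshold, optional watershed split on the
    distance transform (seeded at local maxima at least one minimum
    nucleus radius apart), then an area filter.
    """
    params.validate()
    if hoechst.size == 0:
        raise ValueError("empty raster")
    smoothed = ndimage.gaussian_filter(hoechst.astype(float), params.smooth_sigma)
    try:
        thr = otsu_threshold(smoothed)
    except ValueError:
        return np.zeros(hoechst.shape, dtype=np.int32)
    mask = smoothed > thr
    if params.morphological_cleanup > 0:
        mask = ndimage.binary_opening(mask, structure=_disk_footprint(params.morphological_cleanup))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(hoechst.shape, dtype=np.int32)
    if params.watershed_split:
        distance = ndimage.distance_transform_edt(mask)
        min_dist = max(1, int(params.nucleus_radius_range[0]))
        peaks = peak_local_max(distance, min_distance=min_dist, labels=mask, exclude_border=False)
        markers = np.zeros(mask.shape, dtype=np.int32)
        for k, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = k
        if markers.max() == 0:
            labels = _cc_label(mask, connectivity=2)
        else:
            labels = _watershed(-distance, markers=markers, mask=mask)
    else:
        labels = _cc_label(mask, connectivity=2)
    return _relabel_filtered(np.asarray(labels), params.min_object_area)


def marker_objects(
    channel: np.ndarray,
    tissue: np.ndarray,
    params: SegmentationParams,
    channel_name: str | None = None,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Labeled marker-positive objects within the tissue mask.

    Threshold per ``params.threshold_method`` (computed over tissue
    pixels), morphological opening by the cleanup radius, 8-connected
    components, area filter.  ``exclude`` removes pixels claimed by a
    higher-priority compartment before labeling.
    """
    if channel.shape != tissue.shape:
        raise ValueError("channel and tissue mask must share shape")
    if not tissue.any():
        return np.zeros(channel.shape, dtype=np.int32)
    thr = threshold_channel(channel, params, channel_name=channel_name, within=tissue)
    mask = (channel > thr) & tissue
    if exclude is not None:
        mask &= ~exclude
    if params.morphological_cleanup > 0:
        mask = ndimage.binary_opening(mask, structure=_disk_footprint(params.morphological_cleanup))
    labels = _cc_label(mask, connectivity=2)
    return _relabel_filtered(np.asarray(labels), params.min_object_area)


def control_percentile_thresholds(
    control_cases: list[CaseImage],
    params: SegmentationParams,
    channels: tuple[str, ...] = CHANNELS,
) -> dict[str, float]:
    """Per-channel thresholds as a quantile of pooled control-cohort pixels.

    Offers a single staining-batch-wide positivity convention: the q-th
    percentile (default 0.99) of all control pixel values per channel.
    """
    pooled: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}
    for case in control_cases:
        for ch in channels:
            pooled[ch].append(case.channels[ch].ravel())
    return {
        ch: float(np.quantile(np.concatenate(chunks), params.control_percentile))
        for ch, chunks in pooled.items()
        if chunks
    }


def segment_case(case: CaseImage, params: SegmentationParams) -> SegmentationResult:
    """Run the full mask stage for one case.

    Produces the tissue mask, nuclei label map, IBA1+ myeloid objects,
    lectin+ vessel objects (taking priority over myeloid on shared
    pixels), and a binary positivity mask per non-Hoechst channel.
    """
    params.validate()
    tissue = tissue_mask(case, params)
    nuclei = segment_nuclei(case.channels["hoechst"], params)
    nuclei = _relabel_filtered((nuclei * tissue).astype(np.int32), params.min_object_area)

    marker_masks: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        if ch == "hoechst":
            continue
        labs = marker_objects(case.channels[ch], tissue, params, channel_name=ch)
        marker_masks[ch] = labs > 0

    vessels = marker_objects(case.channels["lectin"], tissue, params, channel_name="lectin")
    exclude = (vessels > 0) if params.vessel_priority else None
    myeloid = marker_objects(
        case.channels["iba1"], tissue, params, channel_name="iba1", exclude=exclude
    )
    return SegmentationResult(
        tissue_mask=tissue,
        nuclei=nuclei,
        myeloid=myeloid,
        vessels=vessels,
        marker_masks=marker_masks,
    )
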