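"""Intensity quantification: tissue-wide, per-object, per-case, per-group.

Measures follow the fluorescence-IHC conventions of the analysis this
package reproduces:

* *integrated intensity* - sum of channel values over the OATP-positive
  mask; the *mean* form normalizes to the ROI (tissue) area;
* *percent area coverage* - marker-positive area as % of tissue area;
* *single-cell average intensity* - per-object mean of a channel within a
  cell-type label map, averaged per case, then compared across groups;
* *fold change* - ratio of group means (GBM over control) with a
  two-sided Mann-Whitney U test on the per-case values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats as _stats
from .types import CHANNELS, REGION_CODES, REGION_NAMES, CaseImage, SegmentationResult

__all__ = [
    "ObjectMeasurement",
    "CaseSummary",
    "FoldChange",
    "integrated_intensity",
    "percent_area",
    "object_mean_intensities",
    "positive_fraction",
    "measure_image",
    "summarize_case",
    "cohort_table",
    "group_fold_change",
    "regional_quantify",
]


@dataclass
class ObjectMeasurement:
    """One segmented object: type, area, centroid, per-channel mean."""

    case_id: str
    object_id: int
    type: str
    area_px: int
    centroid: tuple[float, float]
    mean_intensity: dict[str, float]


@dataclass
class CaseSummary:
    """Per-case row of the cohort table (averaged over a case's images)."""

    case_id: str
    group: str
    isoform: str
    tissue_integrated_intensity: float
    tissue_mean_integrated_intensity: float
    percent_area_coverage: float
    myeloid_mean_oatp: float
    vessel_mean_oatp: float
    n_myeloid: float
    n_vessels: float
    iba1_tissue_mean: float
    gfap_tissue_mean: float
    pdgfrb_tissue_mean: float
    lectin_tissue_mean: float
    myeloid_positive_fraction: float = float("nan")
    vessel_positive_fraction: float = float("nan")


@dataclass
class FoldChange:
    measure: str
    fold: float
    test: _stats.TestResult
    group_means: dict[str, float] = field(default_factory=dict)


def integrated_intensity(channel: np.ndarray, mask: np.ndarray, mean: bool = False) -> float:
    """Sum of channel values over mask pixels; mean form divides by count."""
    if channel.shape != mask.shape:
        raise ValueError("channel and mask must share shape")
    total = float(channel[mask].sum())
    if not mean:
        return total
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI")
    return total / n


def percent_area(marker_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """100 * |marker AND tissue| / |tissue|."""
    if marker_mask.shape != tissue_mask.shape:
        raise ValueError("masks must share shape")
    denom = int(tissue_mask.sum())
    if denom == 0:
        raise ValueError("empty tissue mask")
    return 100.0 * int((marker_mask & tissue_mask).sum()) / denom


def object_mean_intensities(
    channels: dict[str, np.ndarray] | np.ndarray,
    objects: np.ndarray,
    case_id: str,
    type: str,
) -> list[ObjectMeasurement]:
    """One record per label with the mean of each channel over its pixels."""
    if not isinstance(channels, dict):
        channels = {"value": channels}
    for ch in channels.values():
        if ch.shape != objects.shape:
            raise ValueError("channel and label map must share shape")
    n = int(objects.max())
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(objects), objects, index=index).astype(int)
    centroids = ndimage.center_of_mass(np.ones_like(objects), objects, index=index)
    means = {
        name: ndimage.mean(ch, labels=objects, index=index) for name, ch in channels.items()
    }
    out = []
    for k, oid in enumerate(index):
        out.append(
            ObjectMeasurement(
                case_id=case_id,
                object_id=int(oid),
                type=type,
                area_px=int(areas[k]),
                centroid=(float(centroids[k][0]), float(centroids[k][1])),
                mean_intensity={name: float(m[k]) for name, m in means.items()},
            )
        )
    return out


def positive_fraction(
    measurements: list[ObjectMeasurement], channel: str, threshold: float
) -> float:
    """Fraction of objects whose mean intensity strictly exceeds threshold."""
    if not measurements:
        raise ValueError("no measurements")
    hits = sum(1 for m in measurements if m.mean_intensity[channel] > threshold)
    return hits / len(measurements)


def measure_image(
    case: CaseImage, seg: SegmentationResult
) -> tuple[dict[str, float], list[ObjectMeasurement]]:
    """All per-image measures plus per-object measurements for one image."""
    oatp = case.channels["oatp"]
    tissue = seg.tissue_mask
    oatp_mask = seg.marker_masks["oatp"] & tissue
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        raise ValueError("empty tissue mask")

    measures: dict[str, float] = {
        "tissue_integrated_intensity": integrated_intensity(oatp, oatp_mask),
        "tissue_mean_integrated_intensity": integrated_intensity(oatp, oatp_mask) / tissue_area,
        "percent_area_coverage": percent_area(oatp_mask, tissue),
    }
    for marker in ("iba1", "gfap", "pdgfrb", "lectin"):
        mmask = seg.marker_masks[marker] & tissue
        measures[f"{marker}_tissue_mean"] = (
            integrated_intensity(case.channels[marker], mmask) / tissue_area
        )

    objects: list[ObjectMeasurement] = []
    objects += object_mean_intensities(case.channels, seg.myeloid, case.case_id, "myeloid")
    objects += object_mean_intensities(case.channels, seg.vessels, case.case_id, "vessel")

    myeloid = [m for m in objects if m.type == "myeloid"]
    vessels = [m for m in objects if m.type == "vessel"]
    measures["myeloid_mean_oatp"] = (
        float(np.mean([m.mean_intensity["oatp"] for m in myeloid])) if myeloid else float("nan")
    )
    measures["vessel_mean_oatp"] = (
        float(np.mean([m.mean_intensity["oatp"] for m in vessels])) if vessels else float("nan")
    )
    measures["n_myeloid"] = float(len(myeloid))
    measures["n_vessels"] = float(len(vessels))
    return measures, objects


def summarize_case(
    images: list[CaseImage], segmentations: list[SegmentationResult]
) -> tuple[CaseSummary, list[ObjectMeasurement]]:
    """Average per-image measures with equal weight into one case row.

    A case may contribute several serial-section images; repeated images
    are averaged so each case enters group statistics exactly once.
    """
    if not images:
        raise ValueError("need at least one image per case")
    if len(images) != len(segmentations):
        raise ValueError("one segmentation per image required")
    isoforms = {img.isoform for img in images}
    if len(isoforms) > 1:
        raise ValueError(f"mixed isoforms within one case panel: {sorted(isoforms)}")
    groups = {img.group for img in images}
    if len(groups) > 1:
        raise ValueError("mixed groups within one case")

    per_image = []
    all_objects: list[ObjectMeasurement] = []
    for img, seg in zip(images, segmentations):
        measures, objects = measure_image(img, seg)
        per_image.append(measures)
        all_objects.extend(objects)
    keys = per_image[0].keys()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN -> NaN
        averaged = {k: float(np.nanmean([m[k] for m in per_image])) for k in keys}
    summary = CaseSummary(
        case_id=images[0].case_id,
        group=images[0].group,
        isoform=images[0].isoform,
        tissue_integrated_intensity=averaged["tissue_integrated_intensity"],
        tissue_mean_integrated_intensity=averaged["tissue_mean_integrated_intensity"],
        percent_area_coverage=averaged["percent_area_coverage"],
        myeloid_mean_oatp=averaged["myeloid_mean_oatp"],
        vessel_mean_oatp=averaged["vessel_mean_oatp"],
        n_myeloid=averaged["n_myeloid"],
        n_vessels=averaged["n_vessels"],
        iba1_tissue_mean=averaged["iba1_tissue_mean"],
        gfap_tissue_mean=averaged["gfap_tissue_mean"],
        pdgfrb_tissue_mean=averaged["pdgfrb_tissue_mean"],
        lectin_tissue_mean=averaged["lectin_tissue_mean"],
    )
    return summary, all_objects


def cohort_table(summaries: list[CaseSummary]) -> pd.DataFrame:
    """One row per case; raises on duplicate case ids."""
    rows = [vars(s).copy() for s in summaries]
    df = pd.DataFrame(rows)
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case ids: {dupes}")
    return df


def group_fold_change(
    cohort: pd.DataFrame, measure: str, use_median: bool = False
) -> FoldChange:
    """GBM:control ratio of group means with a Mann-Whitney comparison.

    The ratio uses group means by default (matching "x-fold" summaries of
    skewed per-case values); ``use_median`` switches to medians.  Missing
    per-case values are excluded.
    """
    if measure not in cohort.columns:
        raise KeyError(f"unknown measure {measure!r}")
    grouped = {
        g: cohort.loc[cohort["group"] == g, measure].dropna().to_numpy() for g in ("gbm", "control")
    }
    for g, vals in grouped.items():
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cases with {measure!r}")
    center = np.median if use_median else np.mean
    m_ctrl = float(center(grouped["control"]))
    m_gbm = float(center(grouped["gbm"]))
    if m_ctrl == 0:
        raise ZeroDivisionError("undefined fold: control mean is 0")
    test = _stats.mann_whitney_u(grouped["gbm"], grouped["control"])
    return FoldChange(
        measure=measure,
        fold=m_gbm / m_ctrl,
        test=test,
        group_means={"gbm": m_gbm, "control": m_ctrl},
    )


def regional_quantify(channel: np.ndarray, regions: np.ndarray) -> dict[str, float]:
    """Mean channel intensity per anatomical niche (CT, PPN, PNZ).

    Background and necrotic-core pixels are excluded; a region absent from
    the label map is reported as NaN (missing), never as zero.
    """
    if channel.shape != regions.shape:
        raise ValueError("channel and region map must share shape")
    valid_codes = set(REGION_NAMES)
    present = set(np.unique(regions).tolist())
    unknown = present - valid_codes
    if unknown:
        raise ValueError(f"invalid region codes: {sorted(unknown)}")
    out: dict[str, float] = {}
    for name in ("CT", "PPN", "PNZ"):
        mask = regions == REGION_CODES[name]
        out[name] = float(channel[mask].mean()) if mask.any() else float("nan")
    return out
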