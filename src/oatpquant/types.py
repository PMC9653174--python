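"""Shared container types and constants.

A *case* is one tissue section from one patient, imaged in a six-channel
multiplexed immunofluorescence panel: a Hoechst nuclear counterstain, one
OATP isoform (AlexaFluor 488), the pan-myeloid marker IBA1, the
astrocyte/tumor marker GFAP, the endothelial marker UEA-1 lectin, and the
stromal/pericyte marker PDGFRB.  All rasters are 2D, float internally,
quantized to 16-bit only on TIFF export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order used everywhere (TIFF page order, CSV columns).
CHANNELS: tuple[str, ...] = ("hoechst", "oatp", "iba1", "gfap", "lectin", "pdgfrb")

#: Cell-type compartments simulated and measured.
CELL_TYPES: tuple[str, ...] = ("myeloid", "astrocyte_tumor", "stromal")

#: Marker channel that defines each segmentable compartment.
TYPE_MARKER: dict[str, str] = {
    "myeloid": "iba1",
    "astrocyte_tumor": "gfap",
    "stromal": "pdgfrb",
    "vessel": "lectin",
}

#: Integer codes for the anatomical niche label map (cellular tumor,
#: pseudo-palisading cells around necrosis, peri-necrotic zone).
REGION_CODES: dict[str, int] = {
    "background": 0,
    "CT": 1,
    "PPN": 2,
    "PNZ": 3,
    "necrotic_core": 4,
}

REGION_NAMES: dict[int, str] = {v: k for k, v in REGION_CODES.items()}

GROUPS: tuple[str, str] = ("gbm", "control")

ISOFORMS: tuple[str, ...] = ("OATP1A2", "OATP2B1", "OATP1C1", "OATP4A1")


@dataclass
class CaseImage:
    """Named channel raster set for one case (one OATP isoform panel)."""

    case_id: str
    group: str
    isoform: str
    channels: dict[str, np.ndarray]
    pixel_size: float  # micrometres per pixel

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels of a case must share one shape")

    @property
    def area_mm2(self) -> float:
        r, c = self.shape
        return r * c * (self.pixel_size * 1e-3) ** 2


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic case.

    ``objects`` has one row per rendered object with columns
    ``case_id, object_id, type, row, col, area_px`` and one
    ``true_mean_<channel>`` column per channel.  ``labels`` is the object
    label map (0 = background), ``regions`` the niche label map using
    :data:`REGION_CODES`.
    """

    objects: "pd.DataFrame"  # noqa: F821 - imported lazily by callers
    labels: np.ndarray
    regions: np.ndarray
    seed: int

    def footprint(self, object_id: int) -> np.ndarray:
        return self.labels == object_id


@dataclass
class SegmentationResult:
    """Masks produced by the segmentation stage for one image."""

    tissue_mask: np.ndarray
    nuclei: np.ndarray
    myeloid: np.ndarray
    vessels: np.ndarray
    marker_masks: dict[str, np.ndarray] = field(default_factory=dict)
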