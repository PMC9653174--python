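"""Synthetic multiplexed-IHC case generator with full ground truth.

Real OATP panels image 7 um sections of glioblastoma (GBM) and non-tumor
temporal-lobe tissue in six channels.  No patient images are distributed
with the study this package re-implements, so every downstream stage is
exercised against synthetic cases whose statistical structure mirrors the
real cohorts: 25 GBM versus 8 non-tumor cases, OATP signal carried by
myeloid cells, astrocyte/tumor cells, stromal cells and vessels, a
configurable GBM:control fold change per compartment, and an optional
peri-necrotic niche with a decaying OATP4A1 gradient.

Geometry is deliberately simple - cells are filled disks with a co-located
nuclear disk, vessels are random-walk tubes carrying lectin with a
PDGFRB-positive rim - which is sufficient to exercise mask construction,
object splitting and per-object intensity measurement.  Cells are placed
by hard-core rejection sampling (no two somata overlap, and somata avoid
vessel lumina), matching the non-goal of morphological realism.

Intensity model, per object and channel::

    value = control_mean * group_fold * case_factor * object_factor

where ``case_factor`` and ``object_factor`` are unit-mean lognormal
variates (coefficients of variation ``case_cv`` and ``object_cv``); the
group fold is 1 for controls and ``oatp_fold[tissue] * oatp_fold[type]``
for the OATP channel of GBM objects.  Rendering replaces (never adds to)
earlier pixels, the noiseless scene is Gaussian-blurred, then Poisson shot
noise and Gaussian read noise are applied and the result clipped at zero.
Ground-truth per-object channel means are measured on the noiseless,
unblurred scene, so they are exact for every rendering order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.morphology import disk as _disk_footprint

from .types import (
    CELL_TYPES,
    CHANNELS,
    GROUPS,
    REGION_CODES,
    TYPE_MARKER,
    CaseImage,
    GroundTruth,
)

__all__ = [
    "GeneratorConfig",
    "ExpressionConfig",
    "ExpressionTable",
    "default_intensity_profile",
    "generate_case_image",
    "generate_cohort",
    "generate_expression_table",
    "derive_case_seed",
]


def default_intensity_profile() -> dict[str, dict[str, float]]:
    """Control-group per-type channel means in arbitrary fluorescence units.

    Channels absent from a type render at the background level.  The
    nucleus entry is the Hoechst intensity of the nuclear disk drawn inside
    every cell; the vessel rim entry is the PDGFRB intensity of the
    pericyte sheath around each tube.
    """
    return {
        "myeloid": {"iba1": 1500.0, "oatp": 400.0},
        "astrocyte_tumor": {"gfap": 1800.0, "oatp": 500.0},
        "stromal": {"pdgfrb": 1200.0, "oatp": 350.0},
        "vessel": {"lectin": 2500.0, "oatp": 450.0},
        "nucleus": {"hoechst": 3000.0},
        "vessel_rim": {"pdgfrb": 1500.0},
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic case generator.

    Defaults emulate the study conditions: 25 GBM and 8 control cases,
    512x512 fields at 0.325 um/px (20x scan), moderate shot + read noise,
    and compartment OATP folds representative of the OATP1A2 panel
    (myeloid 18x, vessel 6x).  ``oatp_fold["tissue"]`` is a global
    multiplier applied to the OATP channel of every GBM compartment on top
    of the per-compartment folds.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.325  # um per pixel
    cohort_sizes: dict[str, int] = field(default_factory=lambda: {"gbm": 25, "control": 8})
    # objects per mm^2 of tissue
    cell_densities: dict[str, float] = field(
        default_factory=lambda: {"myeloid": 800.0, "astrocyte_tumor": 2000.0, "stromal": 300.0}
    )
    radius_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"myeloid": (6, 9), "astrocyte_tumor": (6, 10), "stromal": (5, 8)}
    )
    nucleus_radius_fraction: float = 0.6
    vessel_params: dict[str, float] = field(
        default_factory=lambda: {"count": 5, "width_px": 8, "tortuosity": 0.25, "rim_px": 2}
    )
    intensity_profile: dict[str, dict[str, float]] = field(default_factory=default_intensity_profile)
    case_cv: float = 0.10  # case-to-case multiplicative intensity dispersion
    object_cv: float = 0.20  # object-to-object dispersion within a case
    oatp_fold: dict[str, float] = field(
        default_factory=lambda: {
            "tissue": 1.0,
            "myeloid": 18.0,
            "vessel": 6.0,
            "astrocyte_tumor": 6.0,
            "stromal": 3.0,
        }
    )
    necrosis_params: dict[str, float] = field(
        default_factory=lambda: {
            "enabled": False,
            "core_fraction": 0.08,
            "ppn_band_px": 25,
            "ppn_density_factor": 2.0,
            "oatp4a1_gradient_scale": 40.0,
            "oatp4a1_gradient_amplitude": 3.0,
        }
    )
    noise: dict[str, float] = field(
        default_factory=lambda: {"background_level": 100.0, "gaussian_sd": 20.0, "poisson": True}
    )
    blur_sigma: float = 1.0
    isoform: str = "OATP1A2"
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_shape
        if rows < 64 or cols < 64:
            raise ValueError("image_shape must be at least 64 px on each side")
        for g in ("gbm", "control"):
            if self.cohort_sizes.get(g, 0) < 1:
                raise ValueError("cohort sizes must be >= 1")
        for t, d in self.cell_densities.items():
            if d < 0:
                raise ValueError(f"negative density for {t}")
        for t, (lo, hi) in self.radius_ranges.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid radius range for {t}")
        for k, v in self.oatp_fold.items():
            if v <= 0:
                raise ValueError(f"oatp_fold[{k}] must be > 0")
        if self.case_cv < 0 or self.object_cv < 0:
            raise ValueError("dispersions must be >= 0")
        if self.noise["background_level"] < 0 or self.noise["gaussian_sd"] < 0:
            raise ValueError("noise levels must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        for tdict in self.intensity_profile.values():
            for v in tdict.values():
                if v < 0:
                    raise ValueError("intensity means must be >= 0")
        area_px = rows * cols
        expected = sum(self.cell_densities.values()) * self._area_mm2()
        if expected > area_px / 4.0:
            raise ValueError("overcrowded configuration")

    def _area_mm2(self) -> float:
        rows, cols = self.image_shape
        return rows * cols * (self.pixel_size * 1e-3) ** 2

    def copy(self, **changes) -> "GeneratorConfig":
        import copy as _copy

        cfg = _copy.deepcopy(self)
        return replace(cfg, **changes)


def derive_case_seed(config_seed: int, group: str, case_index: int) -> int:
    """Stable per-case seed: SeedSequence hash of (seed, group code, index)."""
    gcode = GROUPS.index(group)
    ss = np.random.SeedSequence([int(config_seed), gcode, int(case_index)])
    return int(ss.generate_state(1)[0])


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _region_map(shape, necrosis, enabled: bool, rng: np.random.Generator):
    """Niche label map; without necrosis the whole field is cellular tumor."""
    rows, cols = shape
    regions = np.full(shape, REGION_CODES["CT"], dtype=np.uint8)
    core_center = None
    core_radius = 0.0
    if enabled:
        core_radius = math.sqrt(float(necrosis["core_fraction"]) * rows * cols / math.pi)
        band = float(necrosis["ppn_band_px"])
        cr = rng.uniform(rows * 0.3, rows * 0.7)
        cc = rng.uniform(cols * 0.3, cols * 0.7)
        core_center = (cr, cc)
        rr, cc_idx = np.mgrid[0:rows, 0:cols]
        dist = np.hypot(rr - cr, cc_idx - cc)
        regions[dist <= core_radius] = REGION_CODES["necrotic_core"]
        regions[(dist > core_radius) & (dist <= core_radius + band)] = REGION_CODES["PPN"]
        regions[(dist > core_radius + band) & (dist <= core_radius + 2 * band)] = REGION_CODES["PNZ"]
    return regions, core_center, core_radius


def _vessel_masks(config: GeneratorConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Random-walk tubes of fixed width, one boolean mask per vessel."""
    rows, cols = config.image_shape
    count = int(config.vessel_params["count"])
    width = float(config.vessel_params["width_px"])
    tort = float(config.vessel_params["tortuosity"])
    masks = []
    for _ in range(count):
        edge = rng.integers(4)
        if edge == 0:
            r, c, heading = 0.0, rng.uniform(0, cols - 1), math.pi / 2
        elif edge == 1:
            r, c, heading = rows - 1.0, rng.uniform(0, cols - 1), -math.pi / 2
        elif edge == 2:
            r, c, heading = rng.uniform(0, rows - 1), 0.0, 0.0
        else:
            r, c, heading = rng.uniform(0, rows - 1), cols - 1.0, math.pi
        path = np.zeros((rows, cols), dtype=bool)
        max_steps = 4 * max(rows, cols)
        for _step in range(max_steps):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < rows and 0 <= ci < cols):
                break
            path[ri, ci] = True
            heading += rng.normal(0.0, tort)
            # heading convention: 0 = +col, pi/2 = +row
            r += math.sin(heading)
            c += math.cos(heading)
        if not path.any():
            continue
        lumen = ndimage.binary_dilation(path, structure=_disk_footprint(max(1, int(round(width / 2)))))
        masks.append(lumen)
    return masks


def _place_cells(
    config: GeneratorConfig,
    rng: np.random.Generator,
    vessel_dist: np.ndarray,
    regions: np.ndarray,
    core_center,
    core_radius: float,
):
    """Hard-core placement of cell centers; returns list of (type, r, c, radius).

    Somata never overlap each other, vessel lumina, or the necrotic core;
    the pseudo-palisading band (PPN) receives extra cells according to
    ``ppn_density_factor``, emulating the hypercellular wave around
    necrosis.
    """
    rows, cols = config.image_shape
    area = config._area_mm2()
    necrosis_on = core_center is not None
    ppn_mask = regions == REGION_CODES["PPN"] if necrosis_on else None
    ppn_coords = np.argwhere(ppn_mask) if necrosis_on else None

    placed: list[tuple[str, int, int, int]] = []

    def try_place(cell_type: str, in_ppn: bool) -> None:
        lo, hi = config.radius_ranges[cell_type]
        for _attempt in range(200):
            radius = int(rng.integers(lo, hi + 1))
            if in_ppn:
                k = rng.integers(len(ppn_coords))
                r, c = (int(v) for v in ppn_coords[k])
                if not (radius < r < rows - radius - 1 and radius < c < cols - radius - 1):
                    continue
            else:
                r = int(rng.integers(radius + 1, rows - radius - 1))
                c = int(rng.integers(radius + 1, cols - radius - 1))
            if vessel_dist[r, c] <= radius + 1:
                continue
            if necrosis_on and not in_ppn:
                d = math.hypot(r - core_center[0], c - core_center[1])
                if d <= core_radius + radius:
                    continue
            if necrosis_on and in_ppn:
                d = math.hypot(r - core_center[0], c - core_center[1])
                if d <= core_radius + 1:
                    continue
            ok = True
            for _t, pr, pc, prad in placed:
                if (pr - r) ** 2 + (pc - c) ** 2 <= (prad + radius + 1) ** 2:
                    ok = False
                    break
            if ok:
                placed.append((cell_type, r, c, radius))
                return

    for cell_type in CELL_TYPES:
        lam = config.cell_densities.get(cell_type, 0.0) * area
        n_base = int(rng.poisson(lam)) if lam > 0 else 0
        for _ in range(n_base):
            try_place(cell_type, in_ppn=False)
        if necrosis_on and len(ppn_coords) > 0:
            factor = float(config.necrosis_params.get("ppn_density_factor", 1.0))
            ppn_area_mm2 = ppn_mask.sum() * (config.pixel_size * 1e-3) ** 2
            lam_extra = max(factor - 1.0, 0.0) * config.cell_densities.get(cell_type, 0.0) * ppn_area_mm2
            n_extra = int(rng.poisson(lam_extra)) if lam_extra > 0 else 0
            for _ in range(n_extra):
                try_place(cell_type, in_ppn=True)
    return placed


def generate_case_image(
    config: GeneratorConfig, group: str, case_seed: int, case_id: str | None = None
) -> tuple[CaseImage, GroundTruth]:
    """Render one synthetic case and its ground truth.

    Identical ``(config, group, case_seed)`` give bit-identical outputs.
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(case_seed)
    rows, cols = config.image_shape
    bg = float(config.noise["background_level"])
    profile = config.intensity_profile
    necrosis_on = bool(config.necrosis_params.get("enabled", False)) and group == "gbm"

    regions, core_center, core_radius = _region_map(
        config.image_shape, config.necrosis_params, necrosis_on, rng
    )
    vessels = _vessel_masks(config, rng)
    if vessels:
        vessel_union = np.any(vessels, axis=0)
        vessel_dist = ndimage.distance_transform_edt(~vessel_union)
    else:
        vessel_dist = np.full(config.image_shape, np.inf)

    cells = _place_cells(config, rng, vessel_dist, regions, core_center, core_radius)

    # one multiplicative staining factor per channel per case
    case_factor = {ch: float(_lognormal_factor(rng, config.case_cv)) for ch in CHANNELS}

    def group_fold(cell_type: str) -> float:
        if group != "gbm":
            return 1.0
        return float(config.oatp_fold.get("tissue", 1.0)) * float(
            config.oatp_fold.get(cell_type, 1.0)
        )

    def gradient_multiplier(r: float, c: float) -> float:
        if not necrosis_on or config.isoform != "OATP4A1":
            return 1.0
        scale = float(config.necrosis_params["oatp4a1_gradient_scale"])
        amp = float(config.necrosis_params["oatp4a1_gradient_amplitude"])
        d = max(0.0, math.hypot(r - core_center[0], c - core_center[1]) - core_radius)
        return 1.0 + amp * math.exp(-d / scale)

    scene = {ch: np.full(config.image_shape, bg, dtype=float) for ch in CHANNELS}
    labels = np.zeros(config.image_shape, dtype=np.int32)
    rows_out = []
    object_id = 0

    def object_values(kind: str, cell_type: str, r: float, c: float) -> dict[str, float]:
        vals = {}
        for ch, mean in profile.get(kind, {}).items():
            v = mean
            if ch == "oatp":
                v *= group_fold(cell_type) * gradient_multiplier(r, c)
            v *= case_factor[ch] * float(_lognormal_factor(rng, config.object_cv))
            vals[ch] = v
        return vals

    # cells first (draw order irrelevant among non-overlapping somata)
    for cell_type, r, c, radius in cells:
        object_id += 1
        rr, cc = _draw_disk((r, c), radius, shape=config.image_shape)
        vals = object_values(cell_type, cell_type, r, c)
        for ch, v in vals.items():
            scene[ch][rr, cc] = v
        nuc_r = max(2, int(round(radius * config.nucleus_radius_fraction)))
        nrr, ncc = _draw_disk((r, c), nuc_r, shape=config.image_shape)
        nuc_vals = object_values("nucleus", cell_type, r, c)
        for ch, v in nuc_vals.items():
            scene[ch][nrr, ncc] = v
        labels[rr, cc] = object_id
        rows_out.append({"object_id": object_id, "type": cell_type, "row": r, "col": c})

    # vessels last; later-drawn structures replace earlier pixels
    rim_w = int(config.vessel_params.get("rim_px", 2))
    for lumen in vessels:
        object_id += 1
        com = ndimage.center_of_mass(lumen)
        vals = object_values("vessel", "vessel", com[0], com[1])
        rim = ndimage.binary_dilation(lumen, structure=_disk_footprint(max(1, rim_w))) & ~lumen
        rim_vals = object_values("vessel_rim", "vessel", com[0], com[1])
        for ch, v in rim_vals.items():
            scene[ch][rim] = v
        for ch, v in vals.items():
            scene[ch][lumen] = v
        labels[lumen] = object_id
        rows_out.append(
            {"object_id": object_id, "type": "vessel", "row": float(com[0]), "col": float(com[1])}
        )

    # keep only objects that survived overdrawing; relabel contiguously
    surviving = np.unique(labels)
    surviving = surviving[surviving > 0]
    remap = {old: new for new, old in enumerate(surviving, start=1)}
    new_labels = np.zeros_like(labels)
    truth_rows = []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=surviving)
    cid = case_id if case_id is not None else f"{group}_{case_seed}"
    for (old, new), area in zip(remap.items(), areas):
        new_labels[labels == old] = new
        meta = rows_out[old - 1]
        row = {
            "case_id": cid,
            "object_id": new,
            "type": meta["type"],
            "row": meta["row"],
            "col": meta["col"],
            "area_px": int(area),
        }
        truth_rows.append(row)
    # exact per-object channel means measured on the noiseless, unblurred scene
    for ch in CHANNELS:
        if truth_rows:
            means = ndimage.mean(scene[ch], labels=new_labels, index=np.arange(1, len(truth_rows) + 1))
        else:
            means = []
        for row, m in zip(truth_rows, means):
            row[f"true_mean_{ch}"] = float(m)

    columns = ["case_id", "object_id", "type", "row", "col", "area_px"] + [
        f"true_mean_{ch}" for ch in CHANNELS
    ]
    objects = pd.DataFrame(truth_rows, columns=columns)

    # optics and camera: blur the scene, then shot noise, then read noise
    channels_out = {}
    for ch in CHANNELS:
        img = scene[ch]
        if config.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=config.blur_sigma)
        if config.noise.get("poisson", False):
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        sd = float(config.noise["gaussian_sd"])
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=img.shape)
        channels_out[ch] = np.clip(img, 0.0, None)

    case = CaseImage(
        case_id=cid,
        group=group,
        isoform=config.isoform,
        channels=channels_out,
        pixel_size=config.pixel_size,
    )
    truth = GroundTruth(objects=objects, labels=new_labels, regions=regions, seed=int(case_seed))
    return case, truth


def generate_cohort(config: GeneratorConfig) -> list[tuple[CaseImage, GroundTruth]]:
    """Generate the full two-group cohort (defaults: 25 GBM + 8 control).

    Per-case seeds are derived from ``config.seed`` with a stable hash
    (:func:`derive_case_seed`), so cases are reproducible individually and
    mutually independent.
    """
    config.validate()
    out = []
    for group in GROUPS:
        n = int(config.cohort_sizes[group])
        for idx in range(n):
            seed = derive_case_seed(config.seed, group, idx)
            case_id = f"{group}_{idx + 1:02d}"
            out.append(generate_case_image(config, group, seed, case_id=case_id))
    return out


def iter_cohort(config: GeneratorConfig) -> Iterable[tuple[CaseImage, GroundTruth]]:
    """Memory-lean generator variant of :func:`generate_cohort`."""
    config.validate()
    for group in GROUPS:
        for idx in range(int(config.cohort_sizes[group])):
            seed = derive_case_seed(config.seed, group, idx)
            yield generate_case_image(config, group, seed, case_id=f"{group}_{idx + 1:02d}")


# ---------------------------------------------------------------------------
# Region-annotated expression tables (anatomic-niche RNAseq emulation)
# ---------------------------------------------------------------------------

HYPOXIA_GENES: tuple[str, ...] = (
    "CA9",
    "VEGFA",
    "BNIP3",
    "PDK1",
    "CXCL8",
    "NDRG1",
    "ANGPTL4",
    "TREM1",
    "ATF3",
    "EGLN3",
    "IL1R1",
)

SLCO_GENES: tuple[str, ...] = ("SLCO1A2", "SLCO1C1", "SLCO2B1", "SLCO4A1")


def _default_genes(n_background: int = 35) -> tuple[str, ...]:
    filler = tuple(f"GENE{i:03d}" for i in range(1, n_background + 1))
    return SLCO_GENES + HYPOXIA_GENES + filler


def _default_loadings() -> dict[str, float]:
    """Hypoxia-factor loadings: the hypoxia program and SLCO4A1 load
    positively; the other OATP genes and background genes do not."""
    loadings = {g: 0.0 for g in _default_genes()}
    for g, w in zip(HYPOXIA_GENES, (1.5, 1.4, 1.2, 1.0, 1.3, 1.1, 1.2, 1.0, 0.9, 1.1, 1.0)):
        loadings[g] = w
    loadings["SLCO4A1"] = 1.0
    return loadings


@dataclass
class ExpressionConfig:
    """Latent-factor model for region-annotated expression tables.

    Expression of gene g in sample s is
    ``baseline_g * exp(loading_g * factor_s + eps)`` with the hypoxia
    factor elevated in the peri-necrotic niches (PPN, PNZ) relative to
    cellular tumor (CT) and ``eps ~ N(0, noise_sd)``.
    """

    genes: tuple[str, ...] = field(default_factory=_default_genes)
    loadings: dict[str, float] = field(default_factory=_default_loadings)
    baseline_mean: dict[str, float] | float = 100.0
    noise_sd: float = 0.3
    samples_per_region: int = 10
    factor_region_mean: dict[str, float] = field(
        default_factory=lambda: {"CT": 0.0, "PPN": 2.0, "PNZ": 2.0}
    )
    factor_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValueError(f"duplicate gene names: {dupes}")
        if self.samples_per_region < 2:
            raise ValueError("need at least 2 samples per region")
        for g in self.genes:
            if not np.isfinite(self.loadings.get(g, 0.0)):
                raise ValueError(f"non-finite loading for {g}")
        if isinstance(self.baseline_mean, dict):
            if any(v <= 0 for v in self.baseline_mean.values()):
                raise ValueError("baseline means must be > 0")
        elif self.baseline_mean <= 0:
            raise ValueError("baseline means must be > 0")


@dataclass
class ExpressionTable:
    """Gene-by-sample non-negative expression with per-sample region labels."""

    values: pd.DataFrame  # genes x samples
    regions: pd.Series  # sample -> region in {CT, PPN, PNZ}

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene names in expression table")
        missing = set(self.values.columns) - set(self.regions.index)
        if missing:
            raise ValueError(f"unlabeled samples: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, region: str) -> list[str]:
        return [s for s in self.values.columns if self.regions[s] == region]


def generate_expression_table(config: ExpressionConfig) -> ExpressionTable:
    """Draw one region-annotated expression table from the latent model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = list(config.factor_region_mean)
    samples = []
    region_of = {}
    for region in regions:
        for k in range(config.samples_per_region):
            name = f"{region}_{k + 1:02d}"
            samples.append(name)
            region_of[name] = region
    factor = np.concatenate(
        [
            rng.normal(config.factor_region_mean[region], config.factor_sd, config.samples_per_region)
            for region in regions
        ]
    )
    genes = list(config.genes)
    if isinstance(config.baseline_mean, dict):
        baseline = np.array([config.baseline_mean[g] for g in genes])
    else:
        baseline = np.full(len(genes), float(config.baseline_mean))
    loadings = np.array([config.loadings.get(g, 0.0) for g in genes])
    eps = rng.normal(0.0, config.noise_sd, size=(len(genes), len(samples)))
    values = baseline[:, None] * np.exp(loadings[:, None] * factor[None, :] + eps)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionTable(values=df, regions=pd.Series(region_of, name="region"))
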