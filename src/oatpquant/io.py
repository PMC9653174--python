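"""Reading and writing cases, label maps and tables.

Cases are stored either as one multi-page 16-bit TIFF per case (page
order = channel order, channel names recorded in the file's shaped
metadata) or as six single-channel TIFFs with suffix ``_<channel>.tif``.
Ground truth goes to CSV (object table) and a single-channel TIFF of
integer niche codes; cohort membership lives in ``cases_manifest.csv``
with columns ``case_id, group, isoform``.  Images are float internally
and quantized to 16 bit only on write.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import CHANNELS, CaseImage, GroundTruth

__all__ = [
    "save_case",
    "load_case",
    "save_ground_truth",
    "load_ground_truth",
    "write_manifest",
    "read_manifest",
]


def _quantize16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def save_case(case: CaseImage, directory: str | Path, multipage: bool = True) -> Path:
    """Write one case to ``directory``; returns the written path (or dir)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "case_id": case.case_id,
        "group": case.group,
        "isoform": case.isoform,
        "pixel_size_um": case.pixel_size,
        "channels": list(CHANNELS),
    }
    if multipage:
        stack = np.stack([_quantize16(case.channels[ch]) for ch in CHANNELS])
        path = directory / f"{case.case_id}.tif"
        tifffile.imwrite(path, stack, metadata=meta)
        return path
    for ch in CHANNELS:
        tifffile.imwrite(directory / f"{case.case_id}_{ch}.tif", _quantize16(case.channels[ch]))
    with open(directory / f"{case.case_id}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def load_case(
    path: str | Path,
    case_id: str | None = None,
    group: str | None = None,
    isoform: str | None = None,
    pixel_size: float | None = None,
) -> CaseImage:
    """Load a case from a multi-page TIFF or a directory of per-channel TIFFs."""
    path = Path(path)
    if path.is_dir():
        stem = case_id
        if stem is None:
            raise ValueError("case_id required when loading from a channel directory")
        meta_path = path / f"{stem}_meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        channels = {}
        for ch in CHANNELS:
            fp = path / f"{stem}_{ch}.tif"
            if not fp.exists():
                raise FileNotFoundError(f"case {stem!r}: missing channel file {fp.name}")
            channels[ch] = tifffile.imread(fp).astype(float)
    else:
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        names = meta.get("channels", list(CHANNELS))
        if stack.ndim != 3 or stack.shape[0] != len(names):
            raise ValueError(f"{path}: expected one page per channel {names}")
        channels = {ch: stack[i].astype(float) for i, ch in enumerate(names)}
        missing = set(CHANNELS) - set(channels)
        if missing:
            raise ValueError(f"{path}: missing channels {sorted(missing)}")
    return CaseImage(
        case_id=case_id or meta.get("case_id", path.stem),
        group=group or meta.get("group", "unknown"),
        isoform=isoform or meta.get("isoform", "OATP"),
        channels=channels,
        pixel_size=pixel_size or float(meta.get("pixel_size_um", 1.0)),
    )


def save_ground_truth(truth: GroundTruth, directory: str | Path, case_id: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.objects.to_csv(directory / f"{case_id}_truth.csv", index=False)
    tifffile.imwrite(directory / f"{case_id}_regions.tif", truth.regions.astype(np.uint8))
    tifffile.imwrite(directory / f"{case_id}_labels.tif", truth.labels.astype(np.int32))


def load_ground_truth(directory: str | Path, case_id: str) -> GroundTruth:
    directory = Path(directory)
    objects = pd.read_csv(directory / f"{case_id}_truth.csv")
    regions = tifffile.imread(directory / f"{case_id}_regions.tif")
    labels = tifffile.imread(directory / f"{case_id}_labels.tif")
    return GroundTruth(objects=objects, labels=labels, regions=regions, seed=-1)


def write_manifest(rows: list[dict], directory: str | Path) -> Path:
    path = Path(directory) / "cases_manifest.csv"
    pd.DataFrame(rows, columns=["case_id", "group", "isoform"]).to_csv(path, index=False)
    return path


def read_manifest(directory: str | Path) -> pd.DataFrame:
    path = Path(directory) / "cases_manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no cases_manifest.csv in {directory}")
    return pd.read_csv(path)


def config_to_json(config, path: str | Path) -> None:
    """Echo any dataclass config to JSON for the run manifest."""
    if is_dataclass(config):
        payload = asdict(config)
    else:
        payload = dict(config)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default)
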