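"""Reading and writing the pipeline's on-disk formats.

Cine studies are stored as one PNG per frame plus a JSON sidecar carrying
the pixel spacing (mm), frame order and participant covariates — the same
information a DICOM series provides through its PixelSpacing tag (an
optional DICOM writer is available when pydicom is installed). Masks use
the same per-frame PNG layout, which doubles as the adapter contract for
external segmentation models. Tables (summary statistics, features,
phenotypes) are tab-delimited.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synth import SUMSTAT_COLUMNS, CineStudy

__all__ = [
    "write_study",
    "read_study",
    "write_masks",
    "read_masks",
    "write_summary_stats",
    "read_summary_stats",
    "write_dicom_study",
]

_FRAME_RE = re.compile(r"(\d+)\.png$")


def write_study(study: CineStudy, directory: str | Path, masks: np.ndarray | None = None) -> Path:
    """Write per-frame PNGs and the JSON sidecar; optionally truth masks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    for i in range(study.n_frames):
        name = f"frame_{i:03d}.png"
        Image.fromarray(study.images[i]).save(directory / name)
        frames.append(name)
    sidecar = {
        "participant_id": study.participant_id,
        "pixel_spacing_mm": list(study.pixel_spacing),
        "frames": frames,
        "covariates": {k: (None if v is None else float(v)) for k, v in study.covariates.items()},
    }
    (directory / "study.json").write_text(json.dumps(sidecar, indent=2))
    if masks is not None:
        write_masks(masks, directory / "masks")
    return directory


def read_study(directory: str | Path) -> CineStudy:
    directory = Path(directory)
    sidecar = json.loads((directory / "study.json").read_text())
    images = np.stack(
        [np.asarray(Image.open(directory / name)) for name in sidecar["frames"]]
    )
    return CineStudy(
        participant_id=sidecar["participant_id"],
        images=images,
        pixel_spacing=tuple(sidecar["pixel_spacing_mm"]),
        covariates=sidecar.get("covariates", {}),
    )


def write_masks(masks: np.ndarray, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(len(masks)):
        Image.fromarray((masks[i].astype(np.uint8)) * 255).save(directory / f"mask_{i:03d}.png")
    return directory


def read_masks(directory: str | Path) -> np.ndarray:
    """External-model adapter: per-frame mask PNGs, ordered by the frame
    index embedded in the file name."""
    directory = Path(directory)
    entries = []
    for path in directory.glob("*.png"):
        match = _FRAME_RE.search(path.name)
        if match:
            entries.append((int(match.group(1)), path))
    if not entries:
        raise FileNotFoundError(f"no frame-indexed mask PNGs in {directory}")
    entries.sort()
    indices = [i for i, _ in entries]
    if indices != list(range(len(indices))):
        raise ValueError("mask frame indices are not contiguous from 0")
    return np.stack([np.asarray(Image.open(p)) > 0 for _, p in entries])


def write_summary_stats(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in SUMSTAT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False)
    return path


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTAT_COLUMNS if c not in table.columns and c != "N"]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return table


def write_dicom_study(study: CineStudy, directory: str | Path) -> Path:
    """Write the cine loop as DICOM files with the standard PixelSpacing tag.

    Requires the optional pydicom dependency.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for i in range(study.n_frames):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.PatientID = study.participant_id
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = study.images[i].shape
        ds.PixelSpacing = [str(study.pixel_spacing[0]), str(study.pixel_spacing[1])]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = study.images[i].tobytes()
        pydicom.dcmwrite(directory / f"frame_{i:03d}.dcm", ds)
    return directory
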