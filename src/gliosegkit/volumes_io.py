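"""Volume and label-map I/O, multi-modal study assembly, tabular reports.

All grids are indexed ``(x, y, z)`` with ``z`` running inferior to superior,
so an axial slice is a fixed-``z`` plane. Voxel indices are 0-based and the
physical position of a voxel center is ``index * spacing`` (the NIfTI affine
is preserved on read and reapplied on write, but alignment beyond rigid
registration is out of scope). Label maps use the five-code taxonomy::

    0  unaffected tissue / background
    1  necrosis
    2  edema
    3  non-enhancing tumor
    4  enhancing tumor
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

MODALITIES = ("T1w", "T1wGd", "T2w", "FLAIR")

#: label codes of the four tumor compartments (beyond code 0, unaffected)
TUMOR_CLASSES = (1, 2, 3, 4)
ALL_CLASSES = (0,) + TUMOR_CLASSES

CLASS_NAMES = {
    0: "unaffected",
    1: "necrosis",
    2: "edema",
    3: "nonenhancing",
    4: "enhancing",
}


@dataclasses.dataclass
class ImageVolume:
    """One 3D scalar MRI channel with physical voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "other"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.voxels.ndim}D"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError("volume must have >= 1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def default_affine(self) -> np.ndarray:
        if self.affine is not None:
            return self.affine
        return np.diag(list(self.spacing) + [1.0])


@dataclasses.dataclass
class LabelMap:
    """Per-voxel tissue codes on the same grid as the study it annotates."""

    codes: np.ndarray
    spacing: tuple[float, float, float]
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 3:
            raise ValueError(f"expected 3D label map, got {codes.ndim}D")
        if not np.issubdtype(codes.dtype, np.integer):
            rounded = np.rint(codes)
            if not np.allclose(codes, rounded):
                raise ValueError("label map contains non-integer codes")
            codes = rounded
        codes = codes.astype(np.uint8)
        bad = set(np.unique(codes)) - set(ALL_CLASSES)
        if bad:
            raise ValueError(f"label map contains invalid codes {sorted(bad)}")
        self.codes = codes
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.codes.shape


@dataclasses.dataclass
class MultiModalStudy:
    """The four co-acquired channels (T1w, T1wGd, T2w, FLAIR) plus optional brain mask."""

    channels: dict[str, ImageVolume]
    brain_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if tuple(self.channels.keys()) != MODALITIES:
            got = tuple(self.channels.keys())
            if set(got) != set(MODALITIES):
                raise ValueError(
                    f"four modalities required {MODALITIES}, got {got}"
                )
            # normalize ordering
            self.channels = {m: self.channels[m] for m in MODALITIES}
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.channels["T1wGd"].shape:
                raise ValueError("brain_mask shape does not match channels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels["T1wGd"].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.channels["T1wGd"].spacing

    def aligned(self) -> bool:
        """True when all four channels share one shape and one spacing."""
        shapes = {c.shape for c in self.channels.values()}
        spacings = {c.spacing for c in self.channels.values()}
        return len(shapes) == 1 and len(spacings) == 1

    def stack(self) -> np.ndarray:
        """Channels as one (X, Y, Z, 4) array in canonical modality order."""
        if not self.aligned():
            raise ValueError("channels are not on a common grid; preprocess first")
        return np.stack([self.channels[m].voxels for m in MODALITIES], axis=-1)


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(path, modality: str = "other") -> ImageVolume:
    """Read one NIfTI scalar channel; intensities are not modified."""
    data, spacing, affine = _load_nifti(path)
    return ImageVolume(
        voxels=data.astype(np.float32), spacing=spacing, modality=modality,
        affine=affine,
    )


def write_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32), volume.default_affine()
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_label_map(path) -> LabelMap:
    data, spacing, affine = _load_nifti(path)
    return LabelMap(codes=data, spacing=spacing, affine=affine)


def write_label_map(labels: LabelMap, path) -> None:
    """Label maps are written as unsigned 8-bit NIfTI (5 codes)."""
    affine = labels.affine if labels.affine is not None else np.diag(
        list(labels.spacing) + [1.0]
    )
    img = nib.Nifti1Image(labels.codes.astype(np.uint8), affine)
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))


def load_study(t1, t1c, t2, flair) -> MultiModalStudy:
    """Assemble a study from four NIfTI paths; no resampling at load time."""
    paths = dict(zip(MODALITIES, (t1, t1c, t2, flair)))
    if len({str(p) for p in paths.values()}) != 4:
        raise ValueError("four distinct modality files required (duplicate path)")
    channels = {m: read_volume(p, modality=m) for m, p in paths.items()}
    return MultiModalStudy(channels=channels)


# ---------------------------------------------------------------------------
# tabular reports

_OVERLAP_COLUMNS = [
    "region", "dice", "ppv", "sensitivity",
    "vol_auto_ml", "vol_ref_ml", "abs_err_ml", "rel_err",
]
_DIAMETER_COLUMNS = [
    "lesion_id", "slice_z", "d1_mm", "d2_mm", "product_mm2",
]
_REGION_ORDER = {"CETV": 0, "TV": 1, "TVPLUS": 2}


def write_report(rows: Sequence, path) -> None:
    """Write overlap or diameter rows to CSV with a deterministic row order.

    Overlap rows are ordered CETV, TV, TVPLUS; diameter rows by ascending
    lesion index. Re-running on the same input yields a byte-identical file.
    """
    rows = list(rows)
    kinds = {type(r).__name__ for r in rows}
    if len(kinds) > 1:
        raise ValueError(f"mixed row types in report: {sorted(kinds)}")
    dicts = [dataclasses.asdict(r) for r in rows]
    if rows and "region" in dicts[0]:
        columns = _OVERLAP_COLUMNS
        dicts.sort(key=lambda d: _REGION_ORDER.get(d["region"], 99))
    elif rows and "lesion_id" in dicts[0]:
        columns = _DIAMETER_COLUMNS
        dicts = [{k: d[k] for k in columns} for d in dicts]
        dicts.sort(key=lambda d: d["lesion_id"])
    elif rows:
        raise ValueError(f"unsupported report row type {kinds.pop()}")
    else:
        # empty list: default to the overlap schema (header-only file)
        columns = _OVERLAP_COLUMNS
    df = pd.DataFrame(dicts, columns=columns)
    df.to_csv(path, index=False, lineterminator="\n")
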