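"""Volume I/O, reference-region intensity normalization, and assembly of
the robustly scaled subject-by-voxel matrix.

Conventions fixed here and used everywhere downstream:

* masks: nonzero voxels are included; masked voxels are flattened in
  C-order raster scan, identically for every subject;
* robust scaling is per subject over masked voxels only:
  ``(x - median) / IQR`` with quartiles by linear interpolation;
* voxel indices are 0-based; affines are carried through but never used
  in computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MaskedVolume",
    "BrainMask",
    "SubjectMatrix",
    "read_volume",
    "write_volume",
    "read_mask",
    "suvr_normalize",
    "robust_scale_row",
    "build_subject_matrix",
    "unflatten_row",
    "save_matrix",
    "load_matrix",
]


class DegenerateImageError(ValueError):
    """Raised when a subject's masked intensities carry no spread (IQR == 0)."""


@dataclass
class MaskedVolume:
    """One subject's 3D image with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got ndim={self.data.ndim}"
                + (f" for subject {self.subject_id!r}" if self.subject_id else "")
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BrainMask:
    """Boolean inclusion mask plus the fixed raster ordering of its voxels.

    ``voxel_index`` maps flat column position -> (i, j, k) voxel coordinate,
    in C-order, and is identical for every subject sharing the mask.
    """

    indicator: np.ndarray
    voxel_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.indicator.any():
            raise ValueError("mask contains no voxels")
        self.voxel_index = np.argwhere(self.indicator)  # C-order raster scan

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape

    def flatten(self, volume: MaskedVolume | np.ndarray) -> np.ndarray:
        """Extract masked voxels as a 1D vector in the fixed raster order."""
        data = volume.data if isinstance(volume, MaskedVolume) else np.asarray(volume)
        if data.shape != self.shape:
            raise ValueError(f"volume shape {data.shape} != mask shape {self.shape}")
        return data[self.indicator]

    def checksum(self) -> str:
        return hashlib.sha256(np.packbits(self.indicator).tobytes()).hexdigest()


@dataclass
class SubjectMatrix:
    """Subjects x masked-voxels matrix with its scaling provenance."""

    values: np.ndarray
    subject_ids: list[str]
    scaling_record: list[tuple[float, float]] | None
    mask_ref: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject_id per row required")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def scaled(self) -> bool:
        return self.scaling_record is not None


def read_volume(path: str | Path, expected_shape: tuple[int, int, int] | None = None,
                subject_id: str | None = None) -> MaskedVolume:
    """Read a single-volume NIfTI file.

    Parameters
    ----------
    path
        Path to a NIfTI-1 file holding exactly one 3D volume.
    expected_shape
        If given, the volume shape must match exactly.
    subject_id
        Identifier stored on the returned volume; defaults to the file stem.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For 4D input or a shape mismatch against *expected_shape*.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a single 3D volume, got shape {data.shape}")
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(
            f"{path}: shape {tuple(data.shape)} does not match expected {tuple(expected_shape)}"
        )
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return MaskedVolume(data=np.asarray(data, dtype=float), affine=img.affine, subject_id=sid)


def write_volume(vol: MaskedVolume, path: str | Path) -> Path:
    """Write a volume to NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), vol.affine), path)
    return path


def read_mask(path: str | Path, expected_shape: tuple[int, int, int] | None = None) -> BrainMask:
    """Read a mask volume; nonzero voxels are included."""
    vol = read_volume(path, expected_shape=expected_shape)
    return BrainMask(indicator=vol.data != 0)


def suvr_normalize(vol: MaskedVolume, reference: BrainMask) -> MaskedVolume:
    """Divide every voxel by the mean intensity in the reference region.

    After normalization the mean over the reference region is exactly 1.
    """
    ref_mean = float(vol.data[reference.indicator].mean())
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError(
            f"reference-region mean must be finite and positive, got {ref_mean}"
            + (f" (subject {vol.subject_id!r})" if vol.subject_id else "")
        )
    return MaskedVolume(data=vol.data / ref_mean, affine=vol.affine, subject_id=vol.subject_id)


def robust_scale_row(values: np.ndarray, subject_id: str = "") -> tuple[np.ndarray, float, float]:
    """Median-center and scale a voxel vector by its interquartile range.

    Quartiles use linear interpolation between order statistics.  Returns
    ``(scaled, median, iqr)`` with ``scaled = (values - median) / iqr``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    q25, med, q75 = np.percentile(values, [25.0, 50.0, 75.0])
    iqr = q75 - q25
    if iqr <= 0:
        raise DegenerateImageError(
            f"IQR is zero (constant image)"
            + (f" for subject {subject_id!r}" if subject_id else "")
        )
    return (values - med) / iqr, float(med), float(iqr)


def build_subject_matrix(volumes: list[MaskedVolume], mask: BrainMask,
                         scale: bool = True) -> SubjectMatrix:
    """Mask, flatten, and optionally robustly scale each subject's volume.

    Row *i* holds the masked voxels of ``volumes[i]`` in the mask's fixed
    raster order.  With ``scale=True`` each row is median-centered and
    divided by its IQR (computed within the mask only).
    """
    if not volumes:
        raise ValueError("no volumes supplied")
    ids = [v.subject_id for v in volumes]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject_ids: {dupes}")
    rows = np.empty((len(volumes), mask.n_voxels), dtype=float)
    record: list[tuple[float, float]] | None = [] if scale else None
    for i, vol in enumerate(volumes):
        row = mask.flatten(vol)
        if np.isnan(row).any():
            raise ValueError(f"NaN inside mask for subject {vol.subject_id!r}")
        if scale:
            row, med, iqr = robust_scale_row(row, subject_id=vol.subject_id)
            record.append((med, iqr))
        rows[i] = row
    return SubjectMatrix(values=rows, subject_ids=list(ids),
                         scaling_record=record, mask_ref=mask.checksum())


def unflatten_row(row: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Place a flat masked-voxel vector back into the 3D grid."""
    row = np.asarray(row, dtype=float)
    if row.size != mask.n_voxels:
        raise ValueError(f"row length {row.size} != mask voxel count {mask.n_voxels}")
    out = np.full(mask.shape, fill, dtype=float)
    out[mask.indicator] = row
    return out


def save_matrix(matrix: SubjectMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Export as flat binary (float64) plus a JSON sidecar with provenance."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bin_path = prefix.with_suffix(".bin")
    json_path = prefix.with_suffix(".json")
    matrix.values.astype("<f8").tofile(bin_path)
    sidecar = {
        "shape": list(matrix.values.shape),
        "dtype": "<f8",
        "subject_ids": matrix.subject_ids,
        "scaling_record": matrix.scaling_record,
        "mask_checksum": matrix.mask_ref,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return bin_path, json_path


def load_matrix(prefix: str | Path) -> SubjectMatrix:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    values = np.fromfile(prefix.with_suffix(".bin"), dtype="<f8").reshape(sidecar["shape"])
    record = sidecar["scaling_record"]
    if record is not None:
        record = [tuple(pair) for pair in record]
    return SubjectMatrix(values=values, subject_ids=list(sidecar["subject_ids"]),
                         scaling_record=record, mask_ref=sidecar["mask_checksum"])
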