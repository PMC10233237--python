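"""Voxel-wise Z-score maps of patient groups or individuals versus controls.

The control reference stores the per-voxel mean and sample standard
deviation (ddof 1) of the control cohort; Z maps divide deviations from
the control mean by the control SD (never a pooled SD).  Voxels where
the control SD is 0 are excluded through a validity mask rather than
producing infinities.  The machinery is modality-agnostic: FDG, tau,
amyloid, or gray-matter maps all use the same procedure, with modality
carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from eigenbrains.image_io import BrainMask, MaskedVolume

__all__ = [
    "ControlReference",
    "ZMap",
    "control_reference",
    "zmap_group",
    "zmap_individual",
    "threshold_map",
]


@dataclass
class ControlReference:
    mean_map: np.ndarray  # flat, masked-voxel order
    sd_map: np.ndarray
    n_controls: int
    modality: str = ""
    validity: np.ndarray | None = None  # True where sd > 0

    def __post_init__(self) -> None:
        self.mean_map = np.asarray(self.mean_map, dtype=float)
        self.sd_map = np.asarray(self.sd_map, dtype=float)
        if self.validity is None:
            self.validity = self.sd_map > 0


@dataclass
class ZMap:
    values: np.ndarray  # flat, masked-voxel order; 0 on invalid voxels
    source: str  # "group" | "individual"
    subject_or_group_id: str
    validity: np.ndarray
    threshold_applied: float | None = None
    n_surviving: int | None = None


def _rows(volumes, mask: BrainMask) -> np.ndarray:
    rows = []
    for vol in volumes:
        row = mask.flatten(vol) if isinstance(vol, MaskedVolume) else np.asarray(vol, dtype=float)
        if row.size != mask.n_voxels:
            raise ValueError("volume does not share the mask grid")
        rows.append(row)
    return np.asarray(rows, dtype=float)


def control_reference(control_volumes, mask: BrainMask, modality: str = "") -> ControlReference:
    """Per-voxel mean and sample SD (ddof 1) of the control cohort within the mask."""
    rows = _rows(control_volumes, mask)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 controls")
    return ControlReference(
        mean_map=rows.mean(axis=0),
        sd_map=rows.std(axis=0, ddof=1),
        n_controls=rows.shape[0],
        modality=modality,
    )


def zmap_group(patient_volumes, reference: ControlReference, mask: BrainMask,
               group_id: str = "group") -> ZMap:
    """Z(v) = (mean over patients - control mean) / control SD, on valid voxels."""
    rows = _rows(patient_volumes, mask)
    if rows.shape[0] < 1:
        raise ValueError("need at least 1 patient volume")
    if rows.shape[1] != reference.mean_map.size:
        raise ValueError("patient grid does not match the control reference")
    valid = reference.validity
    z = np.zeros(reference.mean_map.size)
    z[valid] = (rows.mean(axis=0)[valid] - reference.mean_map[valid]) / reference.sd_map[valid]
    return ZMap(values=z, source="group", subject_or_group_id=group_id, validity=valid.copy())


def zmap_individual(patient_volume, reference: ControlReference, mask: BrainMask,
                    subject_id: str = "") -> ZMap:
    """Single-subject Z map versus the control reference."""
    sid = subject_id or (patient_volume.subject_id
                         if isinstance(patient_volume, MaskedVolume) else "subject")
    zm = zmap_group([patient_volume], reference, mask, group_id=sid)
    zm.source = "individual"
    return zm


def threshold_map(zmap: ZMap, z_threshold: float, direction: str = "two-sided") -> ZMap:
    """Censor voxels failing the criterion; report the surviving-voxel count.

    direction "below": keep Z <= -|threshold| handling signed input as given
    (keep Z <= threshold); "above": keep Z >= threshold; "two-sided":
    keep |Z| >= threshold.
    """
    if not np.isfinite(z_threshold):
        raise ValueError("threshold must be finite")
    z = zmap.values.copy()
    if direction == "below":
        keep = z <= z_threshold
    elif direction == "above":
        keep = z >= z_threshold
    elif direction == "two-sided":
        keep = np.abs(z) >= abs(z_threshold)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    keep &= zmap.validity
    z[~keep] = 0.0
    return ZMap(
        values=z,
        source=zmap.source,
        subject_or_group_id=zmap.subject_or_group_id,
        validity=zmap.validity.copy(),
        threshold_applied=float(z_threshold),
        n_surviving=int(keep.sum()),
    )
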