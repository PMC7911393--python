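"""Patient-level total metabolic tumour volume with organ-inclusion rules.

Per-lesion masks are combined by voxel union (each voxel counted once) so
that overlapping observer boxes — e.g. a merged delineation of an
infiltrative cluster next to per-lesion boxes — never double count.  The
documented deviation toggle ``double_count=True`` restores plain summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import LesionMask, LiverStats, MethodSpec, segment_lesion
from .volume import LesionBox, SUVVolume

__all__ = ["PatientMeasurements", "total_mtv", "organ_inclusion", "measure_patient"]


@dataclass
class PatientMeasurements:
    """Total MTV (cm^3) per (method, observer) for one patient."""

    patient_id: int
    mtv_cm3: dict[tuple[str, int], float]
    spleen_included: bool = False
    marrow_included: bool = False


def total_mtv(volume: SUVVolume, boxes: list[LesionBox], method: MethodSpec,
              liver: LiverStats | None = None,
              background: float | None = None,
              double_count: bool = False) -> float:
    """Total MTV over all lesion boxes for one method, in cm^3.

    Each box is segmented independently; the masks are united on the global
    grid.  The geometric fitting method contributes its analytic fitted
    sphere volume per box instead of voxel counts.
    """
    if not boxes:
        return 0.0
    if method.name == "fitting":
        total = 0.0
        for box in boxes:
            try:
                mask = segment_lesion(volume, box, method, liver=liver,
                                      background=background, exclusion=boxes)
            except (ValueError, RuntimeError) as exc:
                raise RuntimeError(f"lesion {box.lesion_id}: {exc}") from exc
            total += float(mask.flags["volume_cm3"])
        return total

    union = np.zeros(volume.shape, dtype=bool)
    total = 0.0
    for box in boxes:
        try:
            mask = segment_lesion(volume, box, method, liver=liver,
                                  background=background, exclusion=boxes)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"lesion {box.lesion_id}: {exc}") from exc
        if double_count:
            total += mask.n_voxels * volume.voxel_volume_cm3
        else:
            union[box.slices] |= mask.mask
    if double_count:
        return total
    return float(union.sum()) * volume.voxel_volume_cm3


def organ_inclusion(spleen_state: str, spleen_diffuse_suv: float,
                    liver_background: float, marrow_state: str) -> tuple[bool, bool]:
    """Spleen / bone-marrow inclusion rules.

    Bone marrow counts only when uptake is focal.  The spleen counts when
    uptake is focal, or diffuse and strictly higher than 150% of the liver
    background (taken as liver SUVmean); exactly 150% is excluded.
    """
    if spleen_state not in ("absent", "focal", "diffuse"):
        raise ValueError(f"unknown spleen state {spleen_state!r}")
    if marrow_state not in ("absent", "focal", "diffuse"):
        raise ValueError(f"unknown marrow state {marrow_state!r}")
    if spleen_diffuse_suv < 0 or liver_background < 0:
        raise ValueError("SUV values must be >= 0")
    marrow_included = marrow_state == "focal"
    spleen_included = (spleen_state == "focal"
                       or (spleen_state == "diffuse"
                           and spleen_diffuse_suv > 1.5 * liver_background))
    return spleen_included, marrow_included


def measure_patient(volume: SUVVolume, boxes_by_observer: dict[int, list[LesionBox]],
                    methods: list[MethodSpec], liver: LiverStats | None = None,
                    background: float | None = None,
                    patient_id: int = 0) -> PatientMeasurements:
    """Run every method for every observer on one patient."""
    mtv: dict[tuple[str, int], float] = {}
    for obs_id, boxes in boxes_by_observer.items():
        for method in methods:
            mtv[(method.name, obs_id)] = total_mtv(
                volume, boxes, method, liver=liver, background=background)
    return PatientMeasurements(patient_id=patient_id, mtv_cm3=mtv)
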