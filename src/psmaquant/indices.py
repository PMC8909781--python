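"""Per-lesion, per-compartment, and whole-body PSMA PET indices.

For each segmented lesion: SUVmax and SUVmean over the supra-threshold
voxel set, PSMA-TV (metabolic tumor volume, cm^3) as voxel count times voxel
volume, and PSMA-TL = SUVmean x PSMA-TV (cm^3*SUV, the PSMA analogue of
total lesion glycolysis). Whole-body SUVmax is the maximum lesion SUVmax;
whole-body TV/TL are sums over lesions. A compartment with no lesions is
reported as absent (None), never as zero — a SUVmax of 0 is physically
meaningless and would corrupt reduction ratios downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .segmentation import LesionSegment
from .volume_io import COMPARTMENTS, SUVVolume


@dataclass
class Lesion:
    """A quantified lesion: its voxel segment plus the four indices."""

    segment: LesionSegment
    suvmax: float
    suvmean: float
    psma_tv: float  # cm^3
    psma_tl: float  # cm^3 * SUV
    patient_id: str = ""
    timepoint: str = "pre"

    @property
    def compartment(self) -> str:
        return self.segment.compartment

    @property
    def lesion_id(self) -> int:
        return self.segment.lesion_id


@dataclass
class CompartmentIndices:
    suvmax: float
    psma_tv: float
    psma_tl: float
    n_lesions: int


@dataclass
class ScanQuantification:
    """All indices of one scan: per lesion, per compartment, whole body.

    ``compartments`` maps each compartment name to its indices or to None
    when that compartment has no lesions; the whole-body fields are None only
    when the scan has no lesions at all (the complete-response case).
    """

    patient_id: str
    timepoint: str
    lesions: list[Lesion]
    compartments: dict[str, CompartmentIndices | None]
    wb_suvmax: float | None
    wb_psma_tv: float | None
    wb_psma_tl: float | None

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)


def quantify_lesion(segment: LesionSegment, volume: SUVVolume) -> Lesion:
    """Compute SUVmax/SUVmean/PSMA-TV/PSMA-TL for one segment.

    SUVmean is the arithmetic mean over the segmented (supra-threshold)
    voxels only; PSMA-TV is exact voxel count x voxel volume in cm^3.
    """
    idx = segment.voxel_indices
    if len(idx) == 0:
        raise ValidationError("cannot quantify an empty segment")
    shape = volume.grid.shape
    if (idx < 0).any() or (idx >= np.array(shape)).any():
        raise ValidationError("segment voxels fall outside the volume")
    values = volume.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    suvmax = float(values.max())
    suvmean = float(values.mean())
    psma_tv = len(idx) * volume.voxel_volume_cm3
    return Lesion(
        segment=segment,
        suvmax=suvmax,
        suvmean=suvmean,
        psma_tv=psma_tv,
        psma_tl=suvmean * psma_tv,
        patient_id=volume.patient_id,
        timepoint=volume.timepoint,
    )


def aggregate_scan(
    lesions: list[Lesion],
    *,
    patient_id: str | None = None,
    timepoint: str | None = None,
) -> ScanQuantification:
    """Aggregate quantified lesions of one scan into compartment and whole-body indices.

    An empty lesion list (a complete metabolic response on the follow-up
    scan) yields absent indices; ``patient_id``/``timepoint`` must then be
    supplied explicitly. Mixing lesions from different patients or
    timepoints is an error.
    """
    pids = {l.patient_id for l in lesions}
    tps = {l.timepoint for l in lesions}
    if len(pids) > 1 or len(tps) > 1:
        raise ValidationError(f"lesions from multiple scans: patients {pids}, timepoints {tps}")
    if lesions:
        patient_id = patient_id if patient_id is not None else lesions[0].patient_id
        timepoint = timepoint if timepoint is not None else lesions[0].timepoint
        if pids != {patient_id} or tps != {timepoint}:
            raise ValidationError("explicit patient_id/timepoint disagree with lesions")
    elif patient_id is None or timepoint is None:
        raise ValidationError("empty scan needs explicit patient_id and timepoint")

    compartments: dict[str, CompartmentIndices | None] = {}
    for comp in COMPARTMENTS:
        ls = [l for l in lesions if l.compartment == comp]
        if ls:
            compartments[comp] = CompartmentIndices(
                suvmax=max(l.suvmax for l in ls),
                psma_tv=sum(l.psma_tv for l in ls),
                psma_tl=sum(l.psma_tl for l in ls),
                n_lesions=len(ls),
            )
        else:
            compartments[comp] = None

    if lesions:
        wb_suvmax = max(l.suvmax for l in lesions)
        wb_psma_tv = sum(l.psma_tv for l in lesions)
        wb_psma_tl = sum(l.psma_tl for l in lesions)
    else:
        wb_suvmax = wb_psma_tv = wb_psma_tl = None

    return ScanQuantification(
        patient_id=patient_id,
        timepoint=timepoint,
        lesions=list(lesions),
        compartments=compartments,
        wb_suvmax=wb_suvmax,
        wb_psma_tv=wb_psma_tv,
        wb_psma_tl=wb_psma_tl,
    )


def suv_from_activity(
    concentration_kbq_ml: float, injected_dose_mbq: float, body_weight_kg: float
) -> float:
    """Body-weight-normalized SUV from an activity concentration.

    SUV = concentration / (injected dose / body weight), with the dose
    spread over the body mass at unit density: kBq/mL divided by
    (MBq * 1000 kBq/MBq) / (kg * 1000 mL/kg). Dimensionless.
    """
    if concentration_kbq_ml <= 0 or injected_dose_mbq <= 0 or body_weight_kg <= 0:
        raise ValidationError("concentration, dose, and weight must all be > 0")
    return concentration_kbq_ml * (body_weight_kg * 1000.0) / (injected_dose_mbq * 1000.0)
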