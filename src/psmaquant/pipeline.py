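"""End-to-end drivers: scan -> segmentation -> indices -> response -> cohort table."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .indices import Lesion, ScanQuantification, aggregate_scan, quantify_lesion
from .phantom import Cohort, CohortPatient, render_scan
from .response import ResponseResult, classify_mpercist, match_lesions
from .segmentation import SegmentationConfig, segment_scan
from .volume_io import COMPARTMENTS, SUVVolume, VOIMask, lesion_table_from_rows


def quantify_scan(
    volume: SUVVolume,
    vois: Sequence[VOIMask] | dict[str, VOIMask],
    config: SegmentationConfig | None = None,
) -> ScanQuantification:
    """Segment every VOI of one scan and aggregate the lesion indices."""
    if isinstance(vois, dict):
        vois = [vois[c] for c in COMPARTMENTS if c in vois]
    segments = segment_scan(volume, vois, config)
    lesions = [quantify_lesion(seg, volume) for seg in segments]
    return aggregate_scan(
        lesions, patient_id=volume.patient_id, timepoint=volume.timepoint
    )


def analyze_patient(
    patient: CohortPatient, config: SegmentationConfig | None = None
) -> tuple[ResponseResult, ScanQuantification, ScanQuantification]:
    """Render, quantify, and classify one synthetic patient's paired scans."""
    pre_vol, pre_vois, _ = render_scan(patient.spec, "pre")
    post_vol, post_vois, _ = render_scan(patient.spec, "post")
    pre_q = quantify_scan(pre_vol, pre_vois, config)
    post_q = quantify_scan(post_vol, post_vois, config)
    paired = match_lesions(pre_q, post_q)
    result = classify_mpercist(paired, psa_pre=patient.psa_pre, psa_post=patient.psa_post)
    return result, pre_q, post_q


def analyze_cohort(
    cohort: Cohort, config: SegmentationConfig | None = None
) -> tuple[pd.DataFrame, list[ResponseResult]]:
    """Run the full pipeline on a synthetic cohort.

    Returns one row per patient holding the clinical covariates, the
    measured pre/post indices per compartment and whole-body, the reduction
    ratios, and the assigned mPERCIST category, together with the raw
    :class:`ResponseResult` objects.
    """
    rows, results = [], []
    for patient, (_, cov) in zip(cohort.patients, cohort.covariates.iterrows()):
        result, pre_q, post_q = analyze_patient(patient, config)
        results.append(result)
        row = dict(cov)
        row["category"] = result.category
        for scope, q in (("pre", pre_q), ("post", post_q)):
            for comp in COMPARTMENTS:
                ci = q.compartments[comp]
                row[f"{comp}_suvmax_{scope}"] = ci.suvmax if ci else None
                row[f"{comp}_psma_tv_{scope}"] = ci.psma_tv if ci else None
                row[f"{comp}_psma_tl_{scope}"] = ci.psma_tl if ci else None
            row[f"wb_suvmax_{scope}"] = q.wb_suvmax
            row[f"wb_psma_tv_{scope}"] = q.wb_psma_tv
            row[f"wb_psma_tl_{scope}"] = q.wb_psma_tl
        for key, val in result.reduction_ratios.items():
            row[f"rr_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows), results


def lesion_table_of_scan(q: ScanQuantification) -> pd.DataFrame:
    """Measured lesion table of one quantified scan (canonical CSV schema)."""
    rows = [
        {
            "patient_id": q.patient_id,
            "timepoint": q.timepoint,
            "compartment": l.compartment,
            "lesion_id": l.lesion_id,
            "suvmax": l.suvmax,
            "suvmean": l.suvmean,
            "psma_tv_cm3": l.psma_tv,
            "psma_tl": l.psma_tl,
        }
        for l in q.lesions
    ]
    return lesion_table_from_rows(rows)
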