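"""Pre/post lesion pairing, reduction ratios, and mPERCIST response classes.

The reduction ratio of an index is ``1 - post/pre``: 0 for no change, 1 for
complete disappearance, negative when the index increased. mPERCIST
categories are assigned in rule order:

1. **CR** — every lesion with tracer uptake disappeared (zero residual
   segmented lesions, new lesions included).
2. **PD** — at least two novel lesions, or a >= 30% increase of PSMA-TV or
   SUVmax in any matched lesion or in the whole-body indices.
3. **PR** — a > 30% reduction of both whole-body SUVmax and whole-body
   PSMA-TV.
4. **SD** — everything else.

PD is evaluated before PR and at per-lesion as well as whole-body
granularity: a growing primary tumor must yield PD even when regressing
metastases pull the whole-body burden down. "Uptake value" is
operationalized as SUVmax, the only uptake index reported per lesion and
per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryMismatchError, ValidationError
from .indices import Lesion, ScanQuantification
from .volume_io import COMPARTMENTS

CATEGORIES = ("CR", "PR", "SD", "PD")

#: Fractional change defining response (PR) and progression (PD).
RESPONSE_FRACTION = 0.30


@dataclass(frozen=True)
class LesionRecord:
    """Summary indices of one lesion, sufficient for response classification."""

    compartment: str
    lesion_id: int
    suvmax: float
    suvmean: float
    psma_tv: float
    psma_tl: float

    @classmethod
    def from_lesion(cls, lesion: Lesion) -> "LesionRecord":
        return cls(
            compartment=lesion.compartment,
            lesion_id=lesion.lesion_id,
            suvmax=lesion.suvmax,
            suvmean=lesion.suvmean,
            psma_tv=lesion.psma_tv,
            psma_tl=lesion.psma_tl,
        )


@dataclass
class PairedStudy:
    """Correspondence between baseline and follow-up lesions of one patient.

    Every post lesion belongs to exactly one of ``matches`` / ``new_lesions``
    and every pre lesion to exactly one of ``matches`` / ``disappeared``.
    """

    patient_id: str
    matches: list[tuple[LesionRecord, LesionRecord]]
    new_lesions: list[LesionRecord]
    disappeared: list[LesionRecord]

    @property
    def pre_records(self) -> list[LesionRecord]:
        return [pre for pre, _ in self.matches] + list(self.disappeared)

    @property
    def post_records(self) -> list[LesionRecord]:
        return [post for _, post in self.matches] + list(self.new_lesions)

    def validate(self) -> None:
        if not self.pre_records:
            raise ValidationError(
                "baseline scan has zero lesions; cohort inclusion requires baseline disease"
            )


@dataclass
class ResponseResult:
    """One mPERCIST category with the rule(s) that fired and all reduction ratios."""

    category: str
    triggers: list[str]
    reduction_ratios: dict[str, float | None]


def reduction_ratio(before: float, after: float) -> float:
    """``1 - after/before`` for a positive baseline and non-negative follow-up."""
    if not before > 0:
        raise ValidationError(f"baseline value must be > 0, got {before}")
    if after < 0:
        raise ValidationError(f"follow-up value must be >= 0, got {after}")
    return 1.0 - after / before


# ---------------------------------------------------------------------------
# Lesion matching


def match_lesions(pre: ScanQuantification, post: ScanQuantification) -> PairedStudy:
    """Pair follow-up lesions with baseline lesions by voxel overlap.

    A post lesion matches the pre lesion sharing the most voxels with it
    (ties broken by the smaller pre ``lesion_id`` within the compartment);
    post lesions overlapping no pre lesion are new, unmatched pre lesions
    disappeared. Both scans must be from the same patient on the same grid
    (identity alignment — same-scanner follow-up without registration).
    """
    if pre.patient_id != post.patient_id:
        raise ValidationError(
            f"patient mismatch: {pre.patient_id!r} vs {post.patient_id!r}"
        )
    pre_sets = {
        (l.compartment, l.lesion_id): l.segment.as_tuples() for l in pre.lesions
    }
    matches: list[tuple[LesionRecord, LesionRecord]] = []
    new: list[LesionRecord] = []
    matched_pre: set[tuple[str, int]] = set()
    for pl in post.lesions:
        post_set = pl.segment.as_tuples()
        best_key, best_overlap = None, 0
        for key, pre_set in sorted(pre_sets.items()):
            ov = len(post_set & pre_set)
            if ov > best_overlap:  # ties keep earlier (smaller id) pre lesion
                best_key, best_overlap = key, ov
        if best_key is None:
            new.append(LesionRecord.from_lesion(pl))
        else:
            pre_lesion = next(
                l for l in pre.lesions if (l.compartment, l.lesion_id) == best_key
            )
            matches.append(
                (LesionRecord.from_lesion(pre_lesion), LesionRecord.from_lesion(pl))
            )
            matched_pre.add(best_key)
    disappeared = [
        LesionRecord.from_lesion(l)
        for l in pre.lesions
        if (l.compartment, l.lesion_id) not in matched_pre
    ]
    study = PairedStudy(pre.patient_id, matches, new, disappeared)
    study.validate()
    return study


def pair_from_records(
    pre_records: Sequence[LesionRecord],
    post_records: Sequence[LesionRecord],
    patient_id: str = "",
) -> PairedStudy:
    """Pair lesions by ``(compartment, lesion_id)`` when voxel data are unavailable.

    This is the entry point for classification from pre-computed lesion
    tables, where correspondence is encoded in stable lesion ids rather than
    voxel overlap.
    """
    pre_by_key = {(r.compartment, r.lesion_id): r for r in pre_records}
    matches, new = [], []
    matched = set()
    for r in post_records:
        key = (r.compartment, r.lesion_id)
        if key in pre_by_key:
            matches.append((pre_by_key[key], r))
            matched.add(key)
        else:
            new.append(r)
    disappeared = [r for k, r in sorted(pre_by_key.items()) if k not in matched]
    study = PairedStudy(patient_id, matches, new, disappeared)
    study.validate()
    return study


# ---------------------------------------------------------------------------
# Classification


def _compartment_values(records: Sequence[LesionRecord]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for comp in COMPARTMENTS:
        rs = [r for r in records if r.compartment == comp]
        if rs:
            out[comp] = {
                "suvmax": max(r.suvmax for r in rs),
                "psma_tv": sum(r.psma_tv for r in rs),
                "psma_tl": sum(r.psma_tl for r in rs),
            }
    return out


def _wb_values(records: Sequence[LesionRecord]) -> dict[str, float] | None:
    if not records:
        return None
    return {
        "suvmax": max(r.suvmax for r in records),
        "psma_tv": sum(r.psma_tv for r in records),
        "psma_tl": sum(r.psma_tl for r in records),
    }


def _all_reduction_ratios(
    paired: PairedStudy, psa_pre: float | None, psa_post: float | None
) -> dict[str, float | None]:
    """Reduction ratios for every index at every compartment and whole-body.

    Absent baseline compartment -> None (excluded from statistics). A
    compartment whose lesions all disappeared has ratio 1.0 for every index
    (post burden 0 / post uptake absent against a positive baseline).
    """
    pre_c = _compartment_values(paired.pre_records)
    post_c = _compartment_values(paired.post_records)
    ratios: dict[str, float | None] = {}
    for comp in COMPARTMENTS:
        for index in ("suvmax", "psma_tv", "psma_tl"):
            key = f"{comp}_{index}"
            if comp not in pre_c:
                ratios[key] = None
            elif comp not in post_c:
                ratios[key] = 1.0
            else:
                ratios[key] = reduction_ratio(pre_c[comp][index], post_c[comp][index])
    pre_wb = _wb_values(paired.pre_records)
    post_wb = _wb_values(paired.post_records)
    for index in ("suvmax", "psma_tv", "psma_tl"):
        key = f"wb_{index}"
        if post_wb is None:
            ratios[key] = 1.0
        else:
            ratios[key] = reduction_ratio(pre_wb[index], post_wb[index])
    if psa_pre is not None and psa_post is not None:
        ratios["psa"] = reduction_ratio(psa_pre, psa_post)
    return ratios


def classify_mpercist(
    paired: PairedStudy,
    psa_pre: float | None = None,
    psa_post: float | None = None,
) -> ResponseResult:
    """Assign the mPERCIST category of one paired study (rule order CR, PD, PR, SD).

    Threshold semantics: an increase of exactly +30% triggers PD (``>=``);
    a reduction of exactly 30% does not qualify for PR (strictly ``>``).
    Comparisons are made multiplicatively (``post >= 1.3 * pre``,
    ``post < 0.7 * pre``) so that boundary cases do not depend on the
    rounding of the derived ratio.
    """
    paired.validate()
    ratios = _all_reduction_ratios(paired, psa_pre, psa_post)
    triggers: list[str] = []

    if not paired.post_records:
        return ResponseResult("CR", ["all_lesions_disappeared"], ratios)

    f = RESPONSE_FRACTION
    if len(paired.new_lesions) >= 2:
        triggers.append("new_lesions>=2")
    for pre_r, post_r in paired.matches:
        if post_r.psma_tv >= (1 + f) * pre_r.psma_tv:
            triggers.append(
                f"lesion_volume_increase:{pre_r.compartment}:{pre_r.lesion_id}"
            )
        if post_r.suvmax >= (1 + f) * pre_r.suvmax:
            triggers.append(
                f"lesion_uptake_increase:{pre_r.compartment}:{pre_r.lesion_id}"
            )
    pre_wb = _wb_values(paired.pre_records)
    post_wb = _wb_values(paired.post_records)
    if post_wb["psma_tv"] >= (1 + f) * pre_wb["psma_tv"]:
        triggers.append("wb_volume_increase")
    if post_wb["suvmax"] >= (1 + f) * pre_wb["suvmax"]:
        triggers.append("wb_uptake_increase")
    if triggers:
        return ResponseResult("PD", triggers, ratios)

    if post_wb["suvmax"] < (1 - f) * pre_wb["suvmax"] and post_wb["psma_tv"] < (
        1 - f
    ) * pre_wb["psma_tv"]:
        return ResponseResult("PR", ["wb_uptake_and_volume_reduction>30%"], ratios)

    return ResponseResult("SD", [], ratios)


def classify_cohort(results: Sequence[ResponseResult]) -> pd.DataFrame:
    """Tabulate category counts and percentages over a cohort of results."""
    if not results:
        raise ValidationError("need at least one study to tabulate")
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    n = len(results)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "percent": [100.0 * counts[c] / n for c in CATEGORIES],
        }
    )
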