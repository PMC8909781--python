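"""Synthetic paired pre/post PSMA PET phantoms with known ground truth.

Each phantom scan is a uniform soft-tissue background on which lesions are
rendered as hard ellipsoidal plateaus (additive height ``peak_suv``), then
blurred with a Gaussian point-spread function and corrupted with additive
Gaussian noise truncated at zero. The hard-plateau/ellipsoid choice gives an
analytic ground-truth volume (4/3*pi*a*b*c) for every lesion, so the whole
segmentation/quantification pipeline can be checked against closed-form
answers. At the follow-up timepoint each lesion's peak is scaled by
``post_multiplier_suv`` and its volume by ``post_multiplier_volume``
(semi-axes scale with the cube root); a multiplier of 0 encodes complete
disappearance.

The cohort generator plants per-patient response categories by sampling
multipliers inside the region of multiplier space implied by the intended
mPERCIST category (with margins away from the +/-30% boundaries so that PSF
blur cannot flip a category) and then verifies each patient with the
classifier itself. Baseline SUVmax and reduction-ratio distributions default
to the calibration of an advanced-prostate-cancer cohort after three months
of androgen deprivation; disease-spread patterns, PSA kinetics, and
ISUP/ADT covariates are drawn to mimic the same cohort. Non-lesion hot
regions (urinary tracer pooling in the bladder) are occasionally added
outside every VOI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .response import LesionRecord, PairedStudy, classify_mpercist
from .volume_io import COMPARTMENTS, SUVVolume, VOIMask, lesion_table_from_rows

# Default grid: a cropped torso stand-in that keeps tests fast.
DEFAULT_SHAPE = (96, 96, 96)
DEFAULT_SPACING = (2.73, 2.73, 5.0)
DEFAULT_BACKGROUND = 1.0
DEFAULT_NOISE_SD = 0.2
DEFAULT_PSF_FWHM = 5.0  # mm, matching the axial slice thickness as a resolution proxy

#: Voxels of isotropic dilation turning a true lesion mask into its VOI.
VOI_MARGIN_VOXELS = 3

# Disjoint compartment zones (voxel coordinates on the default 96^3 grid).
_ZONE_Y = {"node": 16, "prostate": 48, "bone": 80}
_SLOT_X = {"node": (16, 48, 80), "prostate": (16, 80), "bone": (16, 48, 80)}
_SLOT_Z = (16, 40, 64, 84)
_BLADDER_CENTER = (48, 48, 40)


@dataclass
class PhantomLesionSpec:
    """Ground truth for one planted lesion."""

    compartment: str
    center: tuple[float, float, float]  # voxel coordinates
    semi_axes: tuple[float, float, float]  # mm
    peak_suv: float
    post_multiplier_suv: float = 1.0
    post_multiplier_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if any(s <= 0 for s in self.semi_axes):
            raise ValidationError("semi_axes must all be > 0")
        if self.post_multiplier_suv < 0 or self.post_multiplier_volume < 0:
            raise ValidationError("post multipliers must be >= 0")

    def semi_axes_at(self, timepoint: str) -> tuple[float, float, float]:
        if timepoint == "pre":
            return self.semi_axes
        scale = self.post_multiplier_volume ** (1.0 / 3.0)
        return tuple(s * scale for s in self.semi_axes)

    def peak_at(self, timepoint: str) -> float:
        return self.peak_suv if timepoint == "pre" else self.peak_suv * self.post_multiplier_suv

    def analytic_volume_cm3(self, timepoint: str = "pre") -> float:
        a, b, c = self.semi_axes_at(timepoint)
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass
class PhantomSpec:
    """Full description of one simulated patient's paired scans."""

    lesions: list[PhantomLesionSpec]
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    background_suv: float = DEFAULT_BACKGROUND
    noise_sd: float = DEFAULT_NOISE_SD
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM
    contaminant_regions: list[tuple[tuple[float, float, float], tuple[float, float, float], float]] = field(
        default_factory=list
    )  # (center_vox, semi_axes_mm, suv_height)
    seed: int = 0
    patient_id: str = "P000"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValidationError("psf_fwhm_mm must be >= 0")
        for i, lesion in enumerate(self.lesions):
            if lesion.peak_suv <= self.background_suv:
                raise ValidationError(
                    f"lesion {i} ({lesion.compartment}): peak_suv must exceed background"
                )
            for tp in ("pre", "post"):
                semi = lesion.semi_axes_at(tp)
                for ax in range(3):
                    lo = lesion.center[ax] - semi[ax] / self.spacing[ax]
                    hi = lesion.center[ax] + semi[ax] / self.spacing[ax]
                    if lo < 0 or hi > self.shape[ax] - 1:
                        raise ValidationError(
                            f"lesion {i} ({lesion.compartment}) at {lesion.center} "
                            f"does not fit inside the grid at timepoint {tp}"
                        )


def _ellipsoid_mask(
    shape: Sequence[int],
    spacing: Sequence[float],
    center: Sequence[float],
    semi_axes: Sequence[float],
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(
        (((g - c) * sp) / ax) ** 2
        for g, c, sp, ax in zip(grids, center, spacing, semi_axes)
    )
    return q <= 1.0


def render_scan(
    spec: PhantomSpec, timepoint: str
) -> tuple[SUVVolume, dict[str, VOIMask], pd.DataFrame]:
    """Render one timepoint of a phantom: SUV volume, VOI masks, ground truth.

    Lesion plateaus are added to the uniform background, blurred by the
    Gaussian PSF, and overlaid with truncated Gaussian noise; contaminant
    regions are rendered identically but lie outside every VOI. The VOI of
    each compartment is the union of the baseline lesion ellipsoids dilated
    by ``VOI_MARGIN_VOXELS`` voxels (a margin generous enough to cover both
    post-treatment shrinkage and the planted progression growth). The truth
    table carries the analytic ellipsoid volume in cm^3 and the planted
    plateau SUV; lesions with a zero multiplier are absent from the post
    truth table. Deterministic for a given ``spec.seed``.
    """
    if timepoint not in ("pre", "post"):
        raise ValidationError(f"timepoint must be 'pre' or 'post', got {timepoint!r}")
    shape, spacing = spec.shape, spec.spacing
    grid = np.full(shape, float(spec.background_suv))

    # per-compartment lesion ids ordered by minimum linear index of the
    # baseline ellipsoid, matching the deterministic component order the
    # segmentation module produces
    order_key: list[tuple[str, int, int]] = []
    lesion_masks: dict[int, np.ndarray] = {}
    for i, lesion in enumerate(spec.lesions):
        pre_mask = _ellipsoid_mask(shape, spacing, lesion.center, lesion.semi_axes)
        lesion_masks[i] = pre_mask
        flat = np.flatnonzero(pre_mask)
        order_key.append((lesion.compartment, int(flat[0]) if len(flat) else 0, i))
    ids: dict[int, int] = {}
    for comp in COMPARTMENTS:
        comp_keys = sorted(k for k in order_key if k[0] == comp)
        for lesion_id, (_, _, i) in enumerate(comp_keys):
            ids[i] = lesion_id

    rows = []
    for i, lesion in enumerate(spec.lesions):
        peak = lesion.peak_at(timepoint)
        semi = lesion.semi_axes_at(timepoint)
        if timepoint == "post" and (
            lesion.post_multiplier_suv == 0 or lesion.post_multiplier_volume == 0
        ):
            continue
        mask = (
            lesion_masks[i]
            if timepoint == "pre"
            else _ellipsoid_mask(shape, spacing, lesion.center, semi)
        )
        grid[mask] += peak
        plateau = spec.background_suv + peak
        tv = lesion.analytic_volume_cm3(timepoint)
        rows.append(
            {
                "patient_id": spec.patient_id,
                "timepoint": timepoint,
                "compartment": lesion.compartment,
                "lesion_id": ids[i],
                "suvmax": plateau,
                "suvmean": plateau,
                "psma_tv_cm3": tv,
                "psma_tl": plateau * tv,
            }
        )

    for center, semi_axes, height in spec.contaminant_regions:
        grid[_ellipsoid_mask(shape, spacing, center, semi_axes)] += height

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / sp
            for sp in spacing
        ]
        grid = ndimage.gaussian_filter(grid, sigma=sigma_vox)

    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 0 if timepoint == "pre" else 1])
        grid = grid + rng.normal(0.0, spec.noise_sd, size=shape)
    grid = np.clip(grid, 0.0, None)

    vois: dict[str, VOIMask] = {}
    for comp in COMPARTMENTS:
        union = np.zeros(shape, dtype=bool)
        found = False
        for i, lesion in enumerate(spec.lesions):
            if lesion.compartment == comp:
                union |= lesion_masks[i]
                found = True
        if found:
            union = ndimage.binary_dilation(
                union, structure=np.ones((3, 3, 3), bool), iterations=VOI_MARGIN_VOXELS
            )
            vois[comp] = VOIMask(union, comp, spacing)

    volume = SUVVolume(grid, spacing, patient_id=spec.patient_id, timepoint=timepoint)
    truth = lesion_table_from_rows(
        sorted(rows, key=lambda r: (r["compartment"], r["lesion_id"]))
    )
    return volume, vois, truth


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class Calibration:
    """Per-compartment calibration of baseline uptake and treatment effect.

    ``baseline_suvmax`` and the reduction-ratio entries are (mean, sd) pairs
    of normal distributions (truncated at sampling time); defaults reproduce
    the pre/post-ADT cohort this package models.
    """

    baseline_suvmax: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "prostate": (30.1, 21.4),
            "node": (27.2, 20.6),
            "bone": (28.5, 22.4),
        }
    )
    rr_suvmax: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "prostate": (0.49, 0.52),
            "node": (0.74, 0.37),
            "bone": (0.63, 0.34),
        }
    )
    rr_volume: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "prostate": (0.50, 0.94),
            "node": (0.89, 0.19),
            "bone": (0.65, 0.37),
        }
    )
    psa_rr: tuple[float, float] = (0.95, 0.06)


#: Baseline disease-spread patterns and their cohort frequencies.
PATTERNS = (
    (("prostate",), 0.30),
    (("prostate", "node"), 0.20),
    (("prostate", "bone"), 0.17),
    (("prostate", "node", "bone"), 0.33),
)

DEFAULT_RESPONSE_MIX = {"CR": 2, "PR": 24, "SD": 2, "PD": 2}

# Multiplier-space sampling regions per intended category, as reduction-ratio
# truncation bounds. Margins keep planted changes away from the 30% rule
# boundaries so PSF blur and noise cannot flip a category.
_PR_RR_BOUNDS = (0.40, 0.95)
_SD_RR_BOUNDS = (-0.10, 0.20)
_PD_VOLUME_MULT = (2.8, 4.0)  # primary-tumor volume growth factor
_PD_SUV_MULT = (0.45, 0.95)  # primary-tumor uptake multiplier (uptake falls)

_SEMI_AXES_MM = {"prostate": (8.0, 13.0), "node": (5.0, 9.0), "bone": (5.0, 12.0)}
_N_LESIONS = {"prostate": (1, 1), "node": (1, 3), "bone": (1, 4)}
_PEAK_FLOOR = 10.0
#: Post plateau (background + peak*mult) kept above this so the primary
#: tumor of a non-CR patient never vanishes below the segmentation threshold.
_MIN_VISIBLE_PEAK = 4.0


@dataclass
class CohortPatient:
    patient_id: str
    spec: PhantomSpec
    planted_category: str
    isup_group: int
    adt_scheme: str
    psa_pre: float
    psa_post: float
    planted_rr: dict[str, float]  # e.g. "prostate_suvmax" -> planted reduction ratio


@dataclass
class Cohort:
    patients: list[CohortPatient]
    covariates: pd.DataFrame


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _proxy_study(
    patient_id: str, spec: PhantomSpec, threshold: float = 3.0
) -> PairedStudy:
    """Analytic paired study implied by the planted multipliers (no rendering)."""
    ids: dict[str, int] = {}
    matches, disappeared = [], []
    for lesion in spec.lesions:
        lid = ids.setdefault(lesion.compartment, 0)
        ids[lesion.compartment] += 1
        pre = LesionRecord(
            lesion.compartment,
            lid,
            spec.background_suv + lesion.peak_suv,
            spec.background_suv + lesion.peak_suv,
            lesion.analytic_volume_cm3("pre"),
            (spec.background_suv + lesion.peak_suv) * lesion.analytic_volume_cm3("pre"),
        )
        post_peak = spec.background_suv + lesion.peak_at("post")
        gone = (
            lesion.post_multiplier_suv == 0
            or lesion.post_multiplier_volume == 0
            or post_peak <= threshold
        )
        if gone:
            disappeared.append(pre)
        else:
            post = LesionRecord(
                lesion.compartment,
                lid,
                post_peak,
                post_peak,
                lesion.analytic_volume_cm3("post"),
                post_peak * lesion.analytic_volume_cm3("post"),
            )
            matches.append((pre, post))
    return PairedStudy(patient_id, matches, [], disappeared)


def _sample_multipliers(
    rng: np.random.Generator,
    category: str,
    lesions: list[PhantomLesionSpec],
    calibration: Calibration,
    background: float,
) -> dict[str, tuple[float, float]]:
    """Per-compartment (suv, volume) reduction ratios for one patient."""
    rr: dict[str, tuple[float, float]] = {}
    comps = {l.compartment for l in lesions}
    peak = {c: min(l.peak_suv for l in lesions if l.compartment == c) for c in comps}
    for comp in comps:
        if category == "CR":
            rr[comp] = (1.0, 1.0)
        elif category == "PD" and comp == "prostate":
            rr[comp] = (
                1.0 - rng.uniform(*_PD_SUV_MULT),
                1.0 - rng.uniform(*_PD_VOLUME_MULT),
            )
        elif category == "SD":
            lo, hi = _SD_RR_BOUNDS
            m, s = calibration.rr_suvmax[comp]
            mv, sv = calibration.rr_volume[comp]
            rr[comp] = (
                _truncated_normal(rng, m, s, lo, hi),
                _truncated_normal(rng, mv, sv, lo, hi),
            )
        else:  # PR, or the regressing metastases of a PD patient
            lo, hi = _PR_RR_BOUNDS
            m, s = calibration.rr_suvmax[comp]
            mv, sv = calibration.rr_volume[comp]
            r_suv = _truncated_normal(rng, m, s, lo, hi)
            if comp == "prostate":
                # keep the primary visible post-treatment (no accidental CR)
                hi_vis = 1.0 - _MIN_VISIBLE_PEAK / peak[comp]
                r_suv = min(r_suv, hi_vis)
            rr[comp] = (r_suv, _truncated_normal(rng, mv, sv, lo, hi))
    return rr


def generate_cohort(
    n_patients: int = 30,
    calibration: Calibration | None = None,
    response_mix: dict[str, int] | None = None,
    seed: int = 0,
    *,
    noise_sd: float = DEFAULT_NOISE_SD,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    min_post_multiplier: float = 0.0,
    contaminant_probability: float = 0.3,
) -> Cohort:
    """Generate a paired synthetic cohort with planted response categories.

    Each patient receives a disease-spread pattern, planted baseline uptake
    and per-compartment reduction ratios drawn from ``calibration`` within
    the multiplier region of the intended mPERCIST category, and clinical
    covariates (PSA kinetics, ISUP grade group, ADT scheme). Every planted
    category is verified by running the classifier on the analytic
    (unrendered) study; the cohort is deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    calibration = calibration or Calibration()
    if response_mix is None:
        response_mix = _scale_mix(DEFAULT_RESPONSE_MIX, n_patients)
    if sum(response_mix.values()) != n_patients:
        raise ValidationError(
            f"response_mix sums to {sum(response_mix.values())}, expected {n_patients}"
        )
    if response_mix.get("CR", 0) > 0 and min_post_multiplier > 0:
        raise ValidationError(
            "infeasible response_mix: CR requested but min_post_multiplier > 0"
        )
    rng = np.random.default_rng(seed)
    categories = [c for c in ("CR", "PR", "SD", "PD") for _ in range(response_mix.get(c, 0))]
    rng.shuffle(categories)

    patients: list[CohortPatient] = []
    rows = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        category = categories[p]
        patient = _generate_patient(
            rng,
            pid,
            category,
            calibration,
            noise_sd=noise_sd,
            psf_fwhm_mm=psf_fwhm_mm,
            shape=shape,
            spacing=spacing,
            seed=int(rng.integers(0, 2**31 - 1)),
            contaminant_probability=contaminant_probability,
        )
        patients.append(patient)
        row = {
            "patient_id": pid,
            "isup_group": patient.isup_group,
            "isup_stratum": "eq5" if patient.isup_group == 5 else "lt5",
            "adt_scheme": patient.adt_scheme,
            "psa_pre": patient.psa_pre,
            "psa_post": patient.psa_post,
            "planted_category": category,
        }
        for key, val in patient.planted_rr.items():
            row[f"planted_rr_{key}"] = val
        rows.append(row)
    return Cohort(patients, pd.DataFrame(rows))


def _scale_mix(mix: dict[str, int], n: int) -> dict[str, int]:
    """Largest-remainder scaling of the default category mix to n patients."""
    total = sum(mix.values())
    raw = {c: n * v / total for c, v in mix.items()}
    out = {c: int(math.floor(x)) for c, x in raw.items()}
    rem = n - sum(out.values())
    for c in sorted(raw, key=lambda c: raw[c] - out[c], reverse=True)[:rem]:
        out[c] += 1
    return out


def _generate_patient(
    rng: np.random.Generator,
    patient_id: str,
    category: str,
    calibration: Calibration,
    *,
    noise_sd: float,
    psf_fwhm_mm: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    seed: int,
    contaminant_probability: float,
) -> CohortPatient:
    pattern = PATTERNS[rng.choice(len(PATTERNS), p=[w for _, w in PATTERNS])][0]

    for _attempt in range(200):
        lesions = _place_lesions(rng, pattern, calibration, category)
        rr = _sample_multipliers(rng, category, lesions, calibration, DEFAULT_BACKGROUND)
        lesions = [
            replace(
                l,
                post_multiplier_suv=max(0.0, 1.0 - rr[l.compartment][0]),
                post_multiplier_volume=max(0.0, 1.0 - rr[l.compartment][1]),
            )
            for l in lesions
        ]
        spec = PhantomSpec(
            lesions=lesions,
            shape=shape,
            spacing=spacing,
            noise_sd=noise_sd,
            psf_fwhm_mm=psf_fwhm_mm,
            seed=seed,
            patient_id=patient_id,
        )
        result = classify_mpercist(_proxy_study(patient_id, spec))
        if result.category == category:
            break
    else:
        raise ValidationError(
            f"could not realize category {category} for patient {patient_id}"
        )

    if rng.random() < contaminant_probability:
        spec.contaminant_regions.append(
            (_BLADDER_CENTER, (15.0, 15.0, 12.0), float(rng.uniform(8.0, 15.0)))
        )

    # clinical covariates; the two CR patients of the modeled cohort were in
    # the ISUP<5 stratum, so CR forces the lower stratum here as well
    if category == "CR":
        isup = int(rng.choice([2, 3, 4], p=[2 / 14, 7 / 14, 5 / 14]))
    elif rng.random() < 16 / 30:
        isup = 5
    else:
        isup = int(rng.choice([2, 3, 4], p=[2 / 14, 7 / 14, 5 / 14]))
    adt = "monotherapy" if rng.random() < 6 / 30 else "combination"
    psa_pre = float(np.clip(rng.lognormal(math.log(42.0), 1.2), 5.0, 800.0))
    psa_rr = _truncated_normal(rng, *calibration.psa_rr, 0.75, 0.999)
    psa_post = psa_pre * (1.0 - psa_rr)

    planted_rr = {}
    for comp, (r_suv, r_vol) in rr.items():
        planted_rr[f"{comp}_suvmax"] = r_suv
        planted_rr[f"{comp}_psma_tv"] = r_vol
    planted_rr["psa"] = psa_rr

    return CohortPatient(
        patient_id=patient_id,
        spec=spec,
        planted_category=category,
        isup_group=isup,
        adt_scheme=adt,
        psa_pre=psa_pre,
        psa_post=psa_post,
        planted_rr=planted_rr,
    )


def _place_lesions(
    rng: np.random.Generator,
    pattern: Sequence[str],
    calibration: Calibration,
    category: str,
) -> list[PhantomLesionSpec]:
    lesions = []
    for comp in pattern:
        lo, hi = _N_LESIONS[comp]
        n = int(rng.integers(lo, hi + 1))
        slots = [
            (x, _ZONE_Y[comp], z) for x in _SLOT_X[comp] for z in _SLOT_Z
        ]
        chosen = rng.choice(len(slots), size=n, replace=False)
        a_lo, a_hi = _SEMI_AXES_MM[comp]
        if comp == "prostate" and category == "PD":
            a_hi = min(a_hi, 12.5)  # headroom for the planted volume growth
        m, s = calibration.baseline_suvmax[comp]
        for k in chosen:
            x, y, z = slots[k]
            center = (
                x + int(rng.integers(-3, 4)),
                y + int(rng.integers(-3, 4)),
                z + int(rng.integers(-1, 2)),
            )
            semi = tuple(float(rng.uniform(a_lo, a_hi)) for _ in range(3))
            peak = _truncated_normal(rng, m, s, _PEAK_FLOOR, 90.0)
            lesions.append(
                PhantomLesionSpec(
                    compartment=comp,
                    center=center,
                    semi_axes=semi,
                    peak_suv=peak,
                )
            )
    return lesions
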