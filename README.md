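# psmaquant

Quantification and treatment-response analysis for PSMA-targeted PET/CT in
prostate cancer. The package takes paired pre/post-treatment SUV volumes
(e.g., before androgen deprivation therapy and three months into it),
segments lesions inside operator-drawn volumes of interest by SUV
thresholding, computes per-lesion and whole-body burden indices, assigns a
metabolic response category with mPERCIST-style rules, and runs the
nonparametric statistics typically reported for such cohorts. A synthetic
phantom module generates paired cohorts with known ground truth, so every
stage of the pipeline is testable without patient data.

It is aimed at imaging researchers who want a scriptable, fully tested
reference implementation of threshold-based PSMA PET quantification rather
than a clinical workstation.

## The indices and rules

For a lesion with segmented voxel set *L* (voxels with SUV above the
threshold — 3.0 by default, following the fixed bone-lesion cutoff; a 45%
SUVmax isocontour is available for method comparison):

- **SUVmax / SUVmean** — maximum / arithmetic mean SUV over *L*;
- **PSMA-TV** — metabolic tumor volume, |*L*| × voxel volume (cm³);
- **PSMA-TL** — SUVmean × PSMA-TV, the PSMA analogue of total lesion
  glycolysis;
- **wbSUVmax, wbPSMA-TV, wbPSMA-TL** — whole-body aggregates: the maximum of
  lesion SUVmax and the sums of TV and TL. Compartments (prostate, nodes,
  bone) with no lesions are reported *absent*, never zero.

The **reduction ratio** of an index is 1 − post/pre (1 = disappearance,
negative = increase). The mPERCIST classifier applies, in order: **CR** if
every lesion disappeared; **PD** if ≥ 2 new lesions appear or any matched
lesion's (or whole-body) PSMA-TV or SUVmax rises ≥ 30%; **PR** if both
wbSUVmax and wbPSMA-TV fall > 30%; otherwise **SD**.

## Worked example

A patient whose primary tumor volume grows under therapy is progressive
disease even though its uptake fell and the whole-body burden looks better —
the per-lesion rule catches it:

```python
from psmaquant.response import LesionRecord, PairedStudy, classify_mpercist

def rec(comp, lid, suvmax, tv):
    return LesionRecord(comp, lid, suvmax, suvmax, tv, suvmax * tv)

study = PairedStudy(
    "patient-1",
    matches=[(rec("prostate", 0, 59.5, 1.42), rec("prostate", 0, 30.5, 5.99))],
    new_lesions=[], disappeared=[],
)
result = classify_mpercist(study)
print(result.category, result.triggers)
print({k: round(v, 3) for k, v in result.reduction_ratios.items() if v is not None})
```

```
PD ['lesion_volume_increase:prostate:0', 'wb_volume_increase']
{'prostate_suvmax': 0.487, 'prostate_psma_tv': -3.218, 'prostate_psma_tl': -1.162,
 'wb_suvmax': 0.487, 'wb_psma_tv': -3.218, 'wb_psma_tl': -1.162}
```

SUVmax fell by 49% (ratio 0.487), but PSMA-TV rose from 1.42 to 5.99 cm³ —
a reduction ratio of −3.218, i.e., a >30% increase — so the volume-increase
clause fires and the category is PD.

An end-to-end synthetic cohort run:

```python
from psmaquant.phantom import generate_cohort
from psmaquant.pipeline import analyze_cohort
from psmaquant.response import classify_cohort

cohort = generate_cohort(n_patients=30, seed=1)        # 2 CR / 24 PR / 2 SD / 2 PD planted
records, results = analyze_cohort(cohort)              # render -> segment -> classify
print(classify_cohort(results))
print((records["category"] == records["planted_category"]).mean())
```

```
  category  count    percent
0       CR      2   6.666667
1       PR     24  80.000000
2       SD      2   6.666667
3       PD      2   6.666667
1.0
```

The pipeline recovers every planted response category at the default noise
level. The same cohort table feeds `psmaquant.stats` (paired Wilcoxon tests
per index, ISUP-stratum contrasts, PSA correlations).

A CLI mirrors the main steps: `psmaquant segment`, `psmaquant classify`,
`psmaquant stats`, and `psmaquant simulate` (see `--help` for each).

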