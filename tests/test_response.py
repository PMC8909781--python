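import numpy as np
import pytest

from oracles import best_overlap_match, mpercist_oracle

from psmaquant import (
    ValidationError,
    classify_cohort,
    classify_mpercist,
    match_lesions,
    pair_from_records,
    reduction_ratio,
)
from psmaquant.response import LesionRecord, PairedStudy


def rec(comp, lid, suvmax, tv):
    return LesionRecord(comp, lid, suvmax, suvmax, tv, suvmax * tv)


def paired(matches=(), new=(), gone=(), pid="P"):
    return PairedStudy(pid, list(matches), list(new), list(gone))


class TestReductionRatio:
    def test_no_change_is_zero(self):
        assert reduction_ratio(10.0, 10.0) == 0.0

    def test_disappearance_is_one(self):
        assert reduction_ratio(10.0, 0.0) == 1.0

    def test_increase_goes_negative(self):
        # primary tumor growing from 1.42 to 5.99 cm^3
        assert reduction_ratio(1.42, 5.99) == pytest.approx(1 - 5.99 / 1.42)
        assert reduction_ratio(1.42, 5.99) < -3.2

    @pytest.mark.parametrize("before,after", [(0.0, 1.0), (-2.0, 1.0), (5.0, -1.0)])
    def test_undefined_baselines_rejected(self, before, after):
        with pytest.raises(ValidationError):
            reduction_ratio(before, after)


class TestMatchLesions:
    @staticmethod
    def _quantified(segments_by_comp, pid="P", timepoint="pre", shape=(12, 12, 12)):
        from psmaquant import SUVVolume, aggregate_scan, quantify_lesion
        from psmaquant.segmentation import LesionSegment

        grid = np.full(shape, 5.0)
        vol = SUVVolume(grid, (1, 1, 1), patient_id=pid, timepoint=timepoint)
        lesions = []
        for comp, seg_list in segments_by_comp.items():
            for lid, voxels in enumerate(seg_list):
                seg = LesionSegment(comp, np.array(sorted(voxels)), 3.0, lesion_id=lid)
                lesions.append(quantify_lesion(seg, vol))
        return aggregate_scan(lesions, patient_id=pid, timepoint=timepoint)

    def test_identical_lesions_all_match(self):
        vox = [(1, 1, 1), (1, 1, 2)]
        pre = self._quantified({"bone": [vox]}, timepoint="pre")
        post = self._quantified({"bone": [vox]}, timepoint="post")
        study = match_lesions(pre, post)
        assert len(study.matches) == 1
        assert study.new_lesions == [] and study.disappeared == []

    def test_disjoint_post_lesion_is_new(self):
        pre = self._quantified({"bone": [[(1, 1, 1)]]}, timepoint="pre")
        post = self._quantified(
            {"bone": [[(1, 1, 1)], [(8, 8, 8)]]}, timepoint="post"
        )
        study = match_lesions(pre, post)
        assert len(study.new_lesions) == 1

    def test_patient_mismatch_rejected(self):
        pre = self._quantified({"bone": [[(1, 1, 1)]]}, pid="A")
        post = self._quantified({"bone": [[(1, 1, 1)]]}, pid="B", timepoint="post")
        with pytest.raises(ValidationError):
            match_lesions(pre, post)

    def test_matches_brute_force_overlap_oracle(self, rng):
        for _ in range(20):
            def random_sets(k):
                out = []
                for _i in range(k):
                    c = rng.integers(0, 10, size=3)
                    size = rng.integers(1, 6)
                    vox = {
                        tuple(np.clip(c + rng.integers(-1, 2, size=3), 0, 11))
                        for _ in range(size)
                    }
                    out.append(sorted(vox))
                return out

            pre_sets = random_sets(int(rng.integers(1, 4)))
            post_sets = random_sets(int(rng.integers(1, 4)))
            pre = self._quantified({"bone": pre_sets}, timepoint="pre")
            post = self._quantified({"bone": post_sets}, timepoint="post")
            study = match_lesions(pre, post)

            pre_lookup = {
                ("bone", i): set(map(tuple, s)) for i, s in enumerate(pre_sets)
            }
            for post_rec in study.post_records:
                post_vox = set(map(tuple, post_sets[post_rec.lesion_id]))
                want = best_overlap_match(pre_lookup, post_vox)
                matched_to = [
                    p for p, q in study.matches if q.lesion_id == post_rec.lesion_id
                ]
                if want is None:
                    assert post_rec in study.new_lesions
                else:
                    assert matched_to[0].lesion_id == want[1]


class TestClassify:
    def test_printed_progression_case(self):
        study = paired([(rec("prostate", 0, 59.5, 1.42), rec("prostate", 0, 30.5, 5.99))])
        result = classify_mpercist(study)
        assert result.category == "PD"
        assert any("volume_increase" in t for t in result.triggers)

    def test_all_lesions_vanishing_is_cr(self):
        study = paired(gone=[rec("prostate", 0, 20, 3.0), rec("node", 0, 15, 1.0)])
        result = classify_mpercist(study)
        assert result.category == "CR"
        assert all(v == 1.0 for v in result.reduction_ratios.values() if v is not None)

    def test_single_new_lesion_does_not_block_pr(self):
        study = paired(
            matches=[(rec("prostate", 0, 50, 10.0), rec("prostate", 0, 26, 4.5))],
            new=[rec("bone", 5, 6.0, 0.4)],
        )
        result = classify_mpercist(study)
        assert result.category == "PR"

    def test_two_new_lesions_force_pd(self):
        study = paired(
            matches=[(rec("prostate", 0, 50, 10.0), rec("prostate", 0, 26, 4.5))],
            new=[rec("bone", 5, 6.0, 0.4), rec("bone", 6, 5.0, 0.3)],
        )
        assert classify_mpercist(study).category == "PD"

    def test_exact_30pct_increase_is_pd(self):
        study = paired([(rec("prostate", 0, 10.0, 10.0), rec("prostate", 0, 10.0, 13.0))])
        assert classify_mpercist(study).category == "PD"

    def test_exact_30pct_reduction_is_not_pr(self):
        study = paired([(rec("prostate", 0, 10.0, 10.0), rec("prostate", 0, 7.0, 7.0))])
        result = classify_mpercist(study)
        assert result.category == "SD"
        assert result.triggers == []

    def test_just_beyond_30pct_reduction_is_pr(self):
        study = paired([(rec("prostate", 0, 10.0, 10.0), rec("prostate", 0, 6.99, 6.99))])
        assert classify_mpercist(study).category == "PR"

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValidationError):
            classify_mpercist(paired(new=[rec("bone", 0, 5, 1.0)]))

    def test_absent_baseline_compartment_ratio_is_none(self):
        study = paired([(rec("prostate", 0, 50, 10.0), rec("prostate", 0, 20, 4.0))])
        result = classify_mpercist(study)
        assert result.reduction_ratios["node_suvmax"] is None
        assert result.reduction_ratios["prostate_suvmax"] == pytest.approx(0.6)

    def test_psa_ratio_included_when_given(self):
        study = paired([(rec("prostate", 0, 50, 10.0), rec("prostate", 0, 20, 4.0))])
        result = classify_mpercist(study, psa_pre=8.8, psa_post=0.38)
        assert result.reduction_ratios["psa"] == pytest.approx(1 - 0.38 / 8.8)


def _random_scenario(rng):
    """A random rule-space scenario (may sit anywhere in multiplier space)."""
    comps = ["prostate", "node", "bone"]
    n_pre = int(rng.integers(1, 5))
    matches, gone = [], []
    pre_vals = []
    lid = {c: 0 for c in comps}
    for _ in range(n_pre):
        comp = comps[int(rng.integers(0, 3))]
        s0 = float(rng.uniform(5, 60))
        v0 = float(rng.uniform(0.5, 30))
        pre_vals.append((s0, v0))
        r = rec(comp, lid[comp], s0, v0)
        lid[comp] += 1
        if rng.random() < 0.15:
            gone.append(r)
            continue
        # multipliers deliberately straddle the 0.7 / 1.3 rule boundaries
        ms = float(rng.choice([0.2, 0.55, 0.7, 0.9, 1.0, 1.1, 1.3, 1.8]))
        mv = float(rng.choice([0.2, 0.55, 0.7, 0.9, 1.0, 1.1, 1.3, 1.8]))
        matches.append((r, rec(comp, r.lesion_id, s0 * ms, v0 * mv)))
    new = []
    for k in range(int(rng.integers(0, 3))):
        new.append(rec("bone", 50 + k, float(rng.uniform(4, 20)), float(rng.uniform(0.2, 5))))
    study = paired(matches, new, gone)
    oracle_args = (
        [(r.suvmax, r.psma_tv) for r in study.pre_records],
        [((p.suvmax, p.psma_tv), (q.suvmax, q.psma_tv)) for p, q in matches],
        [(r.suvmax, r.psma_tv) for r in new],
    )
    return study, oracle_args


class TestTruthTableEquivalence:
    def test_classifier_agrees_with_rule_oracle(self, rng):
        for _ in range(500):
            study, oracle_args = _random_scenario(rng)
            assert classify_mpercist(study).category == mpercist_oracle(*oracle_args)


class TestClassifyCohort:
    def test_distribution_matches_planted_mix(self):
        results = []
        for cat, n in (("CR", 2), ("PR", 24), ("SD", 2), ("PD", 2)):
            for _ in range(n):
                if cat == "CR":
                    study = paired(gone=[rec("prostate", 0, 20, 3.0)])
                elif cat == "PR":
                    study = paired([(rec("prostate", 0, 50, 10), rec("prostate", 0, 20, 4))])
                elif cat == "SD":
                    study = paired([(rec("prostate", 0, 50, 10), rec("prostate", 0, 45, 9))])
                else:
                    study = paired([(rec("prostate", 0, 50, 10), rec("prostate", 0, 45, 20))])
                results.append(classify_mpercist(study))
        table = classify_cohort(results)
        assert dict(zip(table["category"], table["count"])) == {
            "CR": 2, "PR": 24, "SD": 2, "PD": 2,
        }
        pct = dict(zip(table["category"], table["percent"]))
        assert pct["PR"] == pytest.approx(80.0)
        assert pct["CR"] == pytest.approx(100 * 2 / 30)

    def test_single_patient_cohort(self):
        result = classify_mpercist(paired(gone=[rec("prostate", 0, 20, 3.0)]))
        table = classify_cohort([result])
        assert table.loc[table["category"] == "CR", "percent"].item() == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            classify_cohort([])


class TestPairFromRecords:
    def test_matches_by_compartment_and_id(self):
        pre = [rec("prostate", 0, 50, 10), rec("node", 0, 20, 2)]
        post = [rec("prostate", 0, 20, 4), rec("bone", 0, 8, 1)]
        study = pair_from_records(pre, post)
        assert len(study.matches) == 1
        assert len(study.new_lesions) == 1
        assert len(study.disappeared) == 1

    def test_every_lesion_in_exactly_one_category(self, rng):
        comps = ["prostate", "node", "bone"]
        for _ in range(20):
            pre = [
                rec(comps[int(rng.integers(0, 3))] , i, float(rng.uniform(5, 50)), 1.0)
                for i in range(int(rng.integers(1, 5)))
            ]
            post = [
                rec(comps[int(rng.integers(0, 3))], i, float(rng.uniform(5, 50)), 1.0)
                for i in range(int(rng.integers(0, 5)))
            ]
            # dedupe keys
            pre = list({(r.compartment, r.lesion_id): r for r in pre}.values())
            post = list({(r.compartment, r.lesion_id): r for r in post}.values())
            study = pair_from_records(pre, post)
            assert len(study.matches) + len(study.new_lesions) == len(post)
            assert len(study.matches) + len(study.disappeared) == len(pre)
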