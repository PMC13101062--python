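"""Split construction: stratification, grouping, drops, and the audit."""

import numpy as np
import pytest

from oraltriage import (
    SplitAssignment,
    audit_splits,
    build_rehearsal_splits,
    priming_split,
)
from oraltriage.records import SiteRecord


def _site(sid, pid, cohort="high_prevalence", label="do_not_refer", contra=False):
    return SiteRecord(site_id=sid, patient_id=pid, cohort=cohort,
                      anatomic_label="other", referral_label=label,
                      contralateral_normal=contra)


def _prior(n_refer=50, n_dnr=50):
    sites = [_site(f"r{i}", f"pr{i}", label="refer_suspicion") for i in range(n_refer)]
    sites += [_site(f"d{i}", f"pd{i}") for i in range(n_dnr)]
    return sites


class TestPrimingSplit:
    def test_exact_stratified_counts(self):
        out = priming_split(_prior(50, 50), ratio=0.8, seed=0)
        counts = {("train", True): 0, ("train", False): 0,
                  ("validation", True): 0, ("validation", False): 0}
        for sid, part in out.mapping.items():
            counts[(part, sid.startswith("r"))] += 1
        assert counts[("train", True)] == 40 and counts[("train", False)] == 40
        assert counts[("validation", True)] == 10 and counts[("validation", False)] == 10

    def test_ratio_one_empty_validation(self):
        out = priming_split(_prior(10, 10), ratio=1.0, seed=0)
        assert all(p == "train" for p in out.mapping.values())

    def test_study_shaped_validation_referral_count(self):
        # 313 prior sites with 170 refer -> ~round(0.2 * 170) = 34 +/- 1 in validation
        sites = _prior(0, 143)
        sites += [_site(f"ro{i}", f"pro{i}", label="refer_other") for i in range(74)]
        sites += [_site(f"rs{i}", f"prs{i}", label="refer_suspicion") for i in range(96)]
        out = priming_split(sites, ratio=0.8, seed=1)
        val_refer = sum(
            1 for sid, p in out.mapping.items()
            if p == "validation" and not sid.startswith("d")
        )
        assert abs(val_refer - 34) <= 1

    def test_tiny_stratum_goes_to_train_with_warning(self):
        sites = _prior(1, 10)
        with pytest.warns(UserWarning, match="stratum"):
            out = priming_split(sites, seed=0)
        assert out.mapping["r0"] == "train"

    def test_deterministic_given_seed(self):
        a = priming_split(_prior(30, 70), seed=5)
        b = priming_split(_prior(30, 70), seed=5)
        assert a.mapping == b.mapping

    def test_rejects_low_prevalence_sites(self):
        with pytest.raises(ValueError, match="prior cohorts"):
            priming_split([_site("x", "p", cohort="low_prevalence")])


def _new_cohort(n_patients=10, sites_per=4, referred=(0,)):
    sites = []
    for p in range(n_patients):
        for k in range(sites_per):
            label = "refer_suspicion" if (p in referred and k == 0) else "do_not_refer"
            sites.append(_site(f"L{p}-{k}", f"lp{p}", cohort="low_prevalence", label=label))
    return sites


class TestRehearsalSplits:
    def _build(self, prior=None, new=None, seed=0, **kw):
        prior = prior if prior is not None else _prior(20, 20)
        new = new if new is not None else _new_cohort()
        priming = priming_split(prior, seed=seed)
        return prior, new, build_rehearsal_splits(priming, prior, new, seed=seed, **kw)

    def test_contralateral_normals_of_lesion_patients_dropped(self):
        prior = _prior(5, 5)
        # give a lesion patient a contralateral normal mirror site
        prior.append(_site("contra", "pr0", contra=True))
        priming = priming_split(prior, seed=0)
        new = _new_cohort()
        out = build_rehearsal_splits(priming, prior, new, seed=0)
        assert "contra" not in out.mapping
        assert out.notes["contra"] == "dropped_contralateral"

    def test_all_new_referrals_forced_to_test_with_patient_grouping(self):
        prior, new, out = self._build(new=_new_cohort(referred=(0, 3)))
        for s in new:
            if s.patient_id in ("lp0", "lp3"):
                assert out.mapping[s.site_id] == "test"
        assert out.notes["L0-0"] == "forced_test_referral"
        assert out.notes["L0-1"] == "grouped_with_referral"

    def test_no_referrals_still_fills_test_quota(self):
        prior, new, out = self._build(new=_new_cohort(referred=()))
        assert sum(1 for v in out.mapping.values() if v == "test") > 0

    def test_no_new_patient_spans_partitions(self):
        prior, new, out = self._build(new=_new_cohort(n_patients=17, referred=(2,)))
        by_patient = {}
        for s in new:
            by_patient.setdefault(s.patient_id, set()).add(out.mapping[s.site_id])
        assert all(len(v) == 1 for v in by_patient.values())

    def test_conservation_and_determinism(self):
        prior = _prior(20, 20) + [_site("contra", "pr0", contra=True)]
        new = _new_cohort(n_patients=12, referred=(1,))
        priming = priming_split(prior, seed=3)
        a = build_rehearsal_splits(priming, prior, new, seed=3)
        b = build_rehearsal_splits(priming, prior, new, seed=3)
        assert a.mapping == b.mapping and a.notes == b.notes
        assert set(a.mapping) | set(a.dropped) == {s.site_id for s in prior + new}

    def test_exact_target_counts_met(self):
        prior, new, out = self._build(
            new=_new_cohort(n_patients=20, referred=(0,)),
            target_counts=(52, 12, 56),
        )
        counts = {p: sum(1 for v in out.mapping.values() if v == p)
                  for p in ("train", "validation", "test")}
        assert counts == {"train": 52, "validation": 12, "test": 56}

    def test_rejects_prior_cohort_in_new_sites(self):
        priming = priming_split(_prior(4, 4), seed=0)
        with pytest.raises(ValueError, match="low-prevalence"):
            build_rehearsal_splits(priming, _prior(4, 4), [_site("x", "p")], seed=0)


class TestAudit:
    def test_valid_assignment_passes_all_checks(self):
        prior = _prior(20, 20)
        new = _new_cohort(n_patients=12, referred=(1,))
        priming = priming_split(prior, seed=2)
        out = build_rehearsal_splits(priming, prior, new, seed=2)
        report = audit_splits(out, prior + new)
        assert report["all_pass"], report["checks"]
        assert report["n_sites"] == len(out.mapping)

    def test_hand_built_patient_leak_detected(self):
        new = _new_cohort(n_patients=3, referred=())
        mapping = {s.site_id: "train" for s in new}
        mapping[new[0].site_id] = "test"  # same patient now in train and test
        bad = SplitAssignment(stage="rehearsal", mapping=mapping)
        report = audit_splits(bad, new)
        assert not report["checks"]["patient_disjointness"]["pass"]

    def test_referral_outside_test_detected(self):
        new = _new_cohort(n_patients=3, referred=(0,))
        mapping = {s.site_id: "test" for s in new}
        mapping["L0-0"] = "train"  # a referral site escapes the holdout
        bad = SplitAssignment(stage="rehearsal", mapping=mapping)
        report = audit_splits(bad, new)
        assert not report["checks"]["referrals_in_test"]["pass"]

    def test_csv_round_trip(self, tmp_path):
        prior = _prior(10, 10) + [_site("contra", "pr0", contra=True)]
        new = _new_cohort(referred=(0,))
        priming = priming_split(prior, seed=0)
        out = build_rehearsal_splits(priming, prior, new, seed=0)
        out.to_csv(tmp_path / "split.csv")
        back = SplitAssignment.from_csv(tmp_path / "split.csv", stage="rehearsal")
        assert back.mapping == out.mapping
        assert set(back.dropped) == set(out.dropped)
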