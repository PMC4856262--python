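import datetime as dt

import numpy as np
import pytest

from carelines import cohort as ch
from carelines.data_model import LabResult, Patient, SurgeryClaim
from carelines.line_segmentation import RegimenState, TherapyLine

from conftest import brute_force_regular_use

D = dt.date


def make_line(number, start, end, backbone="FP_O", bio=("bevacizumab",),
              resumption=False):
    return TherapyLine(number, start, end, backbone, frozenset(bio),
                       states=[RegimenState(start, end, backbone, frozenset(bio))],
                       resumption=resumption)


def make_patient(pid="A", death=None, last_seen=D(2013, 12, 31)):
    return Patient(pid, "male", D(1950, 1, 1), death, last_seen)


class TestSelectCohort:
    WINDOW = (D(2006, 9, 1), D(2012, 12, 31))
    CUTOFF = D(2013, 12, 31)

    def run(self, patient, lines, bev_dates):
        return ch.select_cohort([patient], {patient.patient_id: lines},
                                {patient.patient_id: bev_dates},
                                self.WINDOW, self.CUTOFF, 12)

    def test_alive_with_13_months_followup_included(self):
        lines = [make_line(1, D(2010, 1, 1), D(2010, 11, 1))]
        pat = make_patient(last_seen=D(2011, 2, 1))
        members, excl = self.run(pat, lines, [D(2010, 1, 1)])
        assert len(members) == 1 and not excl
        assert members[0].index_date == D(2010, 1, 1)

    def test_alive_with_6_months_followup_excluded(self):
        lines = [make_line(1, D(2010, 1, 1), D(2010, 5, 1))]
        pat = make_patient(last_seen=D(2010, 7, 1))
        members, excl = self.run(pat, lines, [D(2010, 1, 1)])
        assert not members
        assert excl[0].reason == "insufficient_followup"

    def test_death_within_followup_window_still_included(self):
        lines = [make_line(1, D(2010, 1, 1), D(2010, 5, 1))]
        pat = make_patient(death=D(2010, 6, 1), last_seen=D(2010, 6, 1))
        members, _ = self.run(pat, lines, [D(2010, 1, 1)])
        assert len(members) == 1

    def test_bev_only_in_second_line_excluded(self):
        lines = [make_line(1, D(2010, 1, 1), D(2010, 5, 1), bio=()),
                 make_line(2, D(2010, 6, 1), D(2010, 12, 1))]
        pat = make_patient()
        members, excl = self.run(pat, lines, [D(2010, 6, 1)])
        assert not members
        assert excl[0].reason == "no_first_line_bevacizumab"

    def test_index_outside_window_excluded(self):
        lines = [make_line(1, D(2013, 2, 1), D(2013, 8, 1))]
        pat = make_patient()
        members, excl = self.run(pat, lines, [D(2013, 2, 1)])
        assert excl[0].reason == "index_outside_window"

    def test_untreated_patient_excluded(self):
        members, excl = self.run(make_patient(), [], [])
        assert excl[0].reason == "no_systemic_therapy"


class TestClassifySurgery:
    def member(self):
        return ch.CohortMember("A", D(2010, 1, 1), "non_surgery", "FP_O")

    def test_post_index_metastasectomy_is_surgery(self):
        claims = [SurgeryClaim("A", D(2010, 7, 1), "liver_metastasectomy")]
        group, date, warns = ch.classify_surgery(self.member(), claims)
        assert group == "surgery" and date == D(2010, 7, 1) and not warns

    def test_no_claims_is_non_surgery(self):
        group, date, _ = ch.classify_surgery(self.member(), [])
        assert group == "non_surgery" and date is None

    def test_pre_index_claim_ignored_with_warning(self):
        claims = [SurgeryClaim("A", D(2009, 7, 1), "lung_metastasectomy")]
        group, date, warns = ch.classify_surgery(self.member(), claims)
        assert group == "non_surgery" and date is None
        assert warns == ["qualifying_surgery_before_index_ignored"]

    def test_other_procedures_do_not_qualify(self):
        claims = [SurgeryClaim("A", D(2010, 7, 1), "other")]
        group, _, _ = ch.classify_surgery(self.member(), claims)
        assert group == "non_surgery"


class TestRegularMedFlag:
    INDEX = D(2010, 6, 15)
    LAST = D(2012, 6, 15)

    def test_four_distinct_months_pre_index_true(self):
        dates = [D(2009, 8, 3), D(2009, 9, 3), D(2009, 11, 3), D(2010, 2, 3)]
        assert ch.regular_med_flag(dates, self.INDEX, self.LAST)

    def test_three_distinct_months_false(self):
        dates = [D(2010, 1, 3), D(2010, 2, 3), D(2010, 3, 3), D(2010, 3, 20)]
        assert not ch.regular_med_flag(dates, self.INDEX, self.LAST)

    def test_four_dispenses_in_one_month_false(self):
        dates = [D(2010, 3, d) for d in (1, 8, 15, 22)]
        assert not ch.regular_med_flag(dates, self.INDEX, self.LAST)

    def test_months_spread_beyond_any_single_window_false(self):
        dates = [D(2009, 7, 1), D(2010, 6, 1), D(2011, 5, 1), D(2012, 4, 1)]
        assert not ch.regular_med_flag(dates, self.INDEX, self.LAST)

    def test_matches_brute_force_enumeration_on_random_histories(self):
        rng = np.random.default_rng(4)
        index = D(2010, 6, 15)
        for _ in range(400):
            last = index + dt.timedelta(days=int(rng.integers(0, 900)))
            n = int(rng.integers(0, 15))
            dates = [index + dt.timedelta(days=int(rng.integers(-500, 1000)))
                     for _ in range(n)]
            assert ch.regular_med_flag(dates, index, last) == \
                brute_force_regular_use(dates, index, last)

    def test_translation_invariance(self):
        dates = [D(2009, 8, 3), D(2009, 10, 3), D(2009, 12, 3), D(2010, 2, 3)]
        shift = dt.timedelta(days=365)
        assert ch.regular_med_flag(dates, self.INDEX, self.LAST) == \
            ch.regular_med_flag([d + shift for d in dates],
                                self.INDEX + shift, self.LAST + shift)


class TestBaselineLabs:
    INDEX = D(2010, 6, 15)

    def test_most_recent_pre_index_value_chosen(self):
        labs = [LabResult("A", D(2010, 2, 1), "cea", 4.0),
                LabResult("A", D(2010, 5, 1), "cea", 7.0)]
        assert ch.baseline_labs(labs, self.INDEX) == {"cea": 7.0}

    def test_value_beyond_lookback_omitted(self):
        labs = [LabResult("A", self.INDEX - dt.timedelta(days=200), "cea", 4.0)]
        assert ch.baseline_labs(labs, self.INDEX) == {}

    def test_value_on_index_date_omitted_half_open(self):
        labs = [LabResult("A", self.INDEX, "cea", 4.0)]
        assert ch.baseline_labs(labs, self.INDEX) == {}


class TestReviewFlag:
    def test_long_treatment_free_tail_alive_no_liver_surgery(self):
        pat = make_patient(last_seen=D(2013, 12, 31))
        lines = [make_line(1, D(2010, 1, 1), D(2012, 1, 1))]
        assert ch.flag_for_review(pat, lines, [])

    def test_deceased_never_flagged(self):
        pat = make_patient(death=D(2013, 6, 1))
        lines = [make_line(1, D(2010, 1, 1), D(2011, 1, 1))]
        assert not ch.flag_for_review(pat, lines, [])

    def test_liver_resection_suppresses_flag(self):
        pat = make_patient()
        lines = [make_line(1, D(2010, 1, 1), D(2012, 1, 1))]
        claims = [SurgeryClaim("A", D(2010, 8, 1), "liver_metastasectomy")]
        assert not ch.flag_for_review(pat, lines, claims)

    def test_short_tail_not_flagged(self):
        pat = make_patient(last_seen=D(2013, 12, 31))
        lines = [make_line(1, D(2010, 1, 1), D(2013, 6, 1))]
        assert not ch.flag_for_review(pat, lines, [])

    def test_between_line_gap_flagged(self):
        pat = make_patient(last_seen=D(2013, 12, 31))
        lines = [make_line(1, D(2008, 1, 1), D(2009, 1, 1)),
                 make_line(2, D(2010, 6, 1), D(2013, 12, 1), resumption=True)]
        assert ch.flag_for_review(pat, lines, [])


class TestAntiEgfr:
    def test_cetuximab_in_second_line(self):
        lines = [make_line(1, D(2010, 1, 1), D(2010, 9, 1)),
                 make_line(2, D(2010, 10, 1), D(2011, 3, 1), bio=("cetuximab",))]
        exposed, post_policy = ch.anti_egfr_exposure(lines)
        assert exposed and post_policy

    def test_cetuximab_only_in_first_line_not_counted(self):
        lines = [make_line(1, D(2010, 1, 1), D(2010, 9, 1),
                           bio=("bevacizumab", "cetuximab"))]
        exposed, post_policy = ch.anti_egfr_exposure(lines)
        assert not exposed and not post_policy

    def test_pre_policy_second_line_reported(self):
        lines = [make_line(1, D(2007, 1, 1), D(2007, 9, 1)),
                 make_line(2, D(2007, 10, 1), D(2008, 3, 1),
                           bio=("panitumumab",))]
        exposed, post_policy = ch.anti_egfr_exposure(lines)
        assert exposed and not post_policy


def test_received_both_aggressive():
    lines = [make_line(1, D(2010, 1, 1), D(2010, 9, 1), backbone="FP_O"),
             make_line(2, D(2010, 10, 1), D(2011, 3, 1), backbone="FP_I")]
    assert ch.received_both_aggressive(lines)
    assert not ch.received_both_aggressive(lines[:1])
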