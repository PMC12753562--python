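"""Exposure-episode algebra, outcome ascertainment, ITT/PP follow-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmcohort import (
    StudyDesignConfig,
    ascertain_vte,
    build_exposure_episodes,
    exposure_end,
    incidence_rate,
    itt_followup,
    person_time_and_events,
    pp_followup,
)
from tmcohort.claims import ClaimsDataset
from tmcohort.followup import FollowUpBuilder

from conftest import make_dx, make_hosp, make_meas, make_patients, make_rx


def _rx_frame(rows):
    return pd.DataFrame(rows, columns=["date", "days_supply"])


class TestEpisodes:
    def test_gap_bridges_short_uncovered_span(self):
        """Rx day 0 supply 30 and rx day 35 supply 30 leave 5 uncovered days
        (35 - 29 - 1); a 30-day gap bridges them into one episode [0, 64]."""
        eps = build_exposure_episodes(_rx_frame([(0, 30), (35, 30)]), gap_days=30)
        assert [(e.start, e.end) for e in eps] == [(0, 64)]

    def test_gap_zero_splits_uncovered_span(self):
        eps = build_exposure_episodes(_rx_frame([(0, 30), (35, 30)]), gap_days=0)
        assert [(e.start, e.end) for e in eps] == [(0, 29), (35, 64)]

    def test_gap_zero_merges_back_to_back_refills(self):
        """Seamless refill (next start = previous end + 1) stays one episode
        even at gap 0."""
        eps = build_exposure_episodes(_rx_frame([(0, 30), (30, 30)]), gap_days=0)
        assert [(e.start, e.end) for e in eps] == [(0, 59)]

    def test_single_day_supply(self):
        eps = build_exposure_episodes(_rx_frame([(10, 1)]), gap_days=0)
        assert [(e.start, e.end) for e in eps] == [(10, 10)]

    def test_overlapping_supplies_merge_unconditionally(self):
        eps = build_exposure_episodes(_rx_frame([(0, 60), (10, 10)]), gap_days=0)
        assert [(e.start, e.end) for e in eps] == [(0, 59)]

    def test_invalid_supply_rejected(self):
        with pytest.raises(ValueError, match="days_supply"):
            build_exposure_episodes(_rx_frame([(0, 0)]), gap_days=0)

    @settings(max_examples=200, deadline=None)
    @given(
        starts=st.lists(st.integers(0, 120), min_size=1, max_size=6),
        supplies=st.lists(st.integers(1, 40), min_size=6, max_size=6),
        gap=st.sampled_from([0, 3, 10, 30]),
    )
    def test_merging_matches_day_coverage_brute_force(self, starts, supplies, gap):
        """Oracle: mark covered days on a boolean axis, close runs separated
        by <= gap uncovered days, and read the runs back off."""
        rx = _rx_frame(list(zip(starts, supplies[: len(starts)])))
        eps = build_exposure_episodes(rx, gap)
        size = 400
        covered = np.zeros(size, dtype=bool)
        for s, d in zip(starts, supplies):
            covered[s : s + d] = True
        # bridge uncovered runs of length <= gap between covered days
        bridged = covered.copy()
        i = 0
        while i < size:
            if not covered[i] and covered[:i].any() and covered[i:].any():
                j = i
                while j < size and not covered[j]:
                    j += 1
                if j - i <= gap:
                    bridged[i:j] = True
                i = j
            else:
                i += 1
        runs = []
        in_run = False
        for day in range(size):
            if bridged[day] and not in_run:
                runs.append([day, day])
                in_run = True
            elif bridged[day]:
                runs[-1][1] = day
            else:
                in_run = False
        assert [(e.start, e.end) for e in eps] == [tuple(r) for r in runs]


class TestExposureEnd:
    def test_grace_added_to_last_episode(self):
        eps = build_exposure_episodes(_rx_frame([(0, 30), (35, 30)]), gap_days=30)
        assert exposure_end(eps, 90) == 154

    def test_grace_zero_is_last_supply_day(self):
        eps = build_exposure_episodes(_rx_frame([(0, 30)]), gap_days=0)
        assert exposure_end(eps, 0) == 29

    def test_last_episode_only(self):
        eps = build_exposure_episodes(_rx_frame([(0, 10), (100, 10)]), gap_days=0)
        assert exposure_end(eps, 30) == 139

    def test_empty_episodes_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            exposure_end([], 30)


def _event_dataset(dx_rows, rx_rows, hosp_rows=()):
    return ClaimsDataset(
        patients=make_patients([(1, "F", -20000, 0, 1900)]),
        diagnoses=make_dx(dx_rows),
        prescriptions=make_rx(rx_rows),
        hospitalizations=make_hosp(list(hosp_rows)),
        measurements=make_meas([]),
    )


class TestAscertainment:
    def test_outpatient_same_facility_same_date(self, design):
        dataset = _event_dataset(
            [(1, 50, "I260", "F1", "outpatient", None)],
            [(1, 50, "B01AF01", 30, 1.0, "F1", "outpatient", None)],
        )
        event = ascertain_vte(1, (0, 100), dataset, design)
        assert event is not None and event.day == 50 and event.setting == "outpatient"

    def test_outpatient_facility_mismatch_not_an_event(self, design):
        dataset = _event_dataset(
            [(1, 50, "I260", "F1", "outpatient", None)],
            [(1, 50, "B01AF01", 30, 1.0, "F2", "outpatient", None)],
        )
        assert ascertain_vte(1, (0, 100), dataset, design) is None

    def test_inpatient_earliest_prescription_on_or_after_diagnosis(self, design):
        """Diagnosis day 60; anticoagulants on days 59 and 62 in the same
        hospitalization: the event is dated 62 (earliest on/after)."""
        dataset = _event_dataset(
            [(1, 60, "I801", "F1", "inpatient", 1)],
            [
                (1, 59, "B01AB01", 7, 1.0, "F1", "inpatient", 1),
                (1, 62, "B01AB01", 7, 1.0, "F1", "inpatient", 1),
            ],
            [(1, 1, 55, 70)],
        )
        event = ascertain_vte(1, (0, 100), dataset, design)
        assert event is not None and event.day == 62 and event.setting == "inpatient"

    def test_same_day_switch_excludes_same_day_prescription(self):
        design = StudyDesignConfig(same_day_treatment_qualifies=False)
        dataset = _event_dataset(
            [(1, 60, "I801", "F1", "inpatient", 1)],
            [(1, 60, "B01AB01", 7, 1.0, "F1", "inpatient", 1)],
            [(1, 1, 55, 70)],
        )
        assert ascertain_vte(1, (0, 100), dataset, design) is None

    def test_event_outside_window_ignored(self, design):
        dataset = _event_dataset(
            [(1, 50, "I260", "F1", "outpatient", None)],
            [(1, 50, "B01AF01", 30, 1.0, "F1", "outpatient", None)],
        )
        assert ascertain_vte(1, (60, 100), dataset, design) is None

    def test_unknown_hospitalization_id_rejected(self, design):
        dataset = _event_dataset(
            [(1, 60, "I801", "F1", "inpatient", 9)],
            [(1, 60, "B01AB01", 7, 1.0, "F1", "inpatient", 9)],
        )
        with pytest.raises(ValueError, match="unknown hospitalization"):
            ascertain_vte(1, (0, 100), dataset, design)


def _member(group="exposed", index=500, patient_id=1):
    return pd.Series(
        {
            "member_id": 0,
            "patient_id": patient_id,
            "group": group,
            "index_date": index,
        }
    )


def _followup_dataset(rx_rows, dx_rows=()):
    return ClaimsDataset(
        patients=make_patients([(1, "F", -20000, 0, 1000)]),
        diagnoses=make_dx(list(dx_rows)),
        prescriptions=make_rx(list(rx_rows)),
        hospitalizations=make_hosp([]),
        measurements=make_meas([]),
    )


OUTPATIENT_EVENT = lambda day: [
    (1, day, "I260", "F1", "outpatient", None),
]
EVENT_RX = lambda day: (1, day, "B01AF01", 30, 1.0, "F1", "outpatient", None)


class TestITT:
    def test_event_inside_window(self, design):
        dataset = _followup_dataset(
            [(1, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None), EVENT_RX(600)],
            OUTPATIENT_EVENT(600),
        )
        rec = itt_followup(_member(), dataset, design)
        assert rec["event"] and rec["end"] == 600 and rec["censor_reason"] == "event"

    def test_no_event_censored_at_observable_end(self, design):
        dataset = _followup_dataset(
            [(1, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None)]
        )
        rec = itt_followup(_member(), dataset, design)
        assert not rec["event"] and rec["end"] == 1000
        assert rec["censor_reason"] == "end_observable"

    def test_control_drug_start_ignored_under_itt(self, design):
        dataset = _followup_dataset(
            [(1, 700, "C10A2P01", 30, 0.2, "F0", "outpatient", None)]
        )
        rec = itt_followup(_member(group="control"), dataset, design)
        assert rec["end"] == 1000 and rec["censor_reason"] == "end_observable"


class TestPP:
    def test_exposed_censored_at_supply_end_grace_zero(self, design):
        """Single 30-day supply at index, grace 0, event 45 days later:
        censoring at index+29 precedes the event."""
        dataset = _followup_dataset(
            [(1, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None), EVENT_RX(545)],
            OUTPATIENT_EVENT(545),
        )
        rec = pp_followup(_member(), dataset, design, 0)
        assert not rec["event"]
        assert rec["end"] == 529 and rec["censor_reason"] == "exposure_end"

    def test_grace_retains_the_event(self, design):
        dataset = _followup_dataset(
            [(1, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None), EVENT_RX(545)],
            OUTPATIENT_EVENT(545),
        )
        rec = pp_followup(_member(), dataset, design, 90)
        assert rec["event"] and rec["end"] == 545

    def test_control_censored_at_other_fibrate(self, design):
        dataset = _followup_dataset(
            [(1, 510, "C10A2B01", 30, 400.0, "F0", "outpatient", None)]
        )
        rec = pp_followup(_member(group="control"), dataset, design, 0)
        assert rec["end"] == 510 and rec["censor_reason"] == "pemafibrate_start"

    def test_exposed_censored_at_other_fibrate(self, design):
        dataset = _followup_dataset(
            [
                (1, 500, "C10A2P01", 90, 0.2, "F0", "outpatient", None),
                (1, 520, "C10A2B01", 30, 400.0, "F0", "outpatient", None),
            ]
        )
        rec = pp_followup(_member(), dataset, design, 0)
        assert rec["end"] == 520 and rec["censor_reason"] == "other_fibrate"

    def test_restart_after_long_break_does_not_extend_pp(self, design):
        """Exposure ends with the episode containing the index prescription:
        a restart 300 days later does not stretch the on-treatment window."""
        dataset = _followup_dataset(
            [
                (1, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
                (1, 830, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
            ]
        )
        rec = pp_followup(_member(), dataset, design, 30)
        assert rec["end"] == 529 + 30 and rec["censor_reason"] == "exposure_end"


class TestPersonTime:
    def test_rates_from_counts(self):
        assert incidence_rate(1, 50.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            incidence_rate(1, 0.0)

    def test_person_time_and_events(self):
        fu = pd.DataFrame(
            {"start": [0, 0], "end": [365, 366], "event": [True, False]}
        )
        out = person_time_and_events(fu)
        assert out["events"] == 1
        assert out["person_years"] == pytest.approx(731 / 365.25)
        assert out["rate_per_100py"] == pytest.approx(100 / (731 / 365.25))

    def test_zero_events_rate_zero(self):
        fu = pd.DataFrame({"start": [0], "end": [365], "event": [False]})
        assert person_time_and_events(fu)["rate_per_100py"] == 0.0


class TestScenarioMonotonicity:
    def test_itt_person_time_dominates_pp_and_pp_monotone_in_grace(
        self, small_claims, small_cohort
    ):
        members, _, design = small_cohort
        builder = FollowUpBuilder(members, small_claims, design)
        itt = builder.itt()
        itt_days = (itt["end"] - itt["start"]).to_numpy()
        prev = None
        for g in design.gap_grace_days:
            pp = builder.pp(g)
            days = (pp["end"] - pp["start"]).to_numpy()
            assert (days <= itt_days).all()
            if prev is not None:
                assert (days >= prev).all()
            prev = days

    def test_every_event_has_qualifying_records_in_window(
        self, small_claims, small_cohort
    ):
        """Auditable back-reference: each claimed event day lies inside the
        member's window and appears in the qualifying-event index."""
        members, _, design = small_cohort
        builder = FollowUpBuilder(members, small_claims, design)
        itt = builder.itt()
        events = itt[itt["event"]]
        table = builder.events.table
        for _, row in events.head(50).iterrows():
            assert row["start"] <= row["event_date"] <= row["end"]
            match = table[
                (table["patient_id"] == row["patient_id"])
                & (table["date"] == row["event_date"])
            ]
            assert len(match) == 1
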