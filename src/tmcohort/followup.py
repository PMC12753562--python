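"""Follow-up intervals (ITT and per-protocol) and VTE outcome ascertainment.

Exposure-episode algebra
------------------------
A prescription of ``days_supply`` d starting on day s covers the closed
interval [s, s + d - 1].  Consecutive supply intervals merge into one
episode when the number of uncovered days between them
(``next_start - current_end - 1``) is at most the gap period; overlapping
supplies always merge.  Exposure for a per-protocol scenario ends at the end
of the episode containing the index prescription plus the grace period.

Outcome ascertainment
---------------------
An event requires a VTE diagnosis plus a thrombolytic/anticoagulant
prescription: outpatient — same patient, same facility, same date; inpatient
— both inside the same hospitalization, with the event dated at the earliest
qualifying prescription on/after the diagnosis (configurable to strictly
after).  The earliest event date inside the follow-up window wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._windows import first_on_or_after, pack_keys
from .claims import ClaimsDataset
from .config import StudyDesignConfig, matches_any_prefix
from .dates import DAYS_PER_YEAR

ANALYSES = ("ITT", "PP-0", "PP-30", "PP-90", "PP-180")


@dataclass(frozen=True)
class ExposureEpisode:
    start: int
    end: int  # closed interval of covered supply, before grace extension


@dataclass(frozen=True)
class VteEvent:
    patient_id: object
    day: int
    setting: str


def build_exposure_episodes(prescriptions: pd.DataFrame, gap_days: int) -> list[ExposureEpisode]:
    """Merge supply intervals of one patient's study-drug prescriptions.

    ``prescriptions`` must already be filtered to the study drug; rows are
    (date, days_supply).  Raises on days_supply < 1.
    """
    if not len(prescriptions):
        return []
    supply = np.asarray(prescriptions["days_supply"], dtype=np.int64)
    if (supply < 1).any():
        raise ValueError("days_supply must be >= 1")
    order = np.argsort(np.asarray(prescriptions["date"], dtype=np.int64), kind="stable")
    start = np.asarray(prescriptions["date"], dtype=np.int64)[order]
    end = start + supply[order] - 1
    episodes: list[list[int]] = []
    for s, e in zip(start, end):
        if episodes and s - episodes[-1][1] - 1 <= gap_days:
            episodes[-1][1] = max(episodes[-1][1], e)
        else:
            episodes.append([s, e])
    return [ExposureEpisode(s, e) for s, e in episodes]


def exposure_end(episodes: list[ExposureEpisode], grace_days: int) -> int:
    """Last covered day of the final episode plus the grace period."""
    if not episodes:
        raise ValueError("exposure_end requires a non-empty episode list")
    return episodes[-1].end + grace_days


def _episode_end_from_index(
    starts: np.ndarray, supplies: np.ndarray, index_day: int, gap_days: int
) -> int:
    """End of the exposure run containing the index prescription."""
    episodes = build_exposure_episodes(
        pd.DataFrame({"date": starts, "days_supply": supplies}), gap_days
    )
    for ep in episodes:
        if ep.start <= index_day <= ep.end:
            return ep.end
    # index is the first prescription, so this only happens on malformed input
    raise ValueError("index date not covered by any exposure episode")


class EventIndex:
    """All qualifying VTE event days per patient, precomputed once."""

    def __init__(self, dataset: ClaimsDataset, config: StudyDesignConfig):
        self.config = config
        pat_ids = dataset.patients["patient_id"].to_numpy()
        self.pid_index = pd.Index(pat_ids)
        dx = dataset.diagnoses
        rx = dataset.prescriptions
        events = []

        if len(dx) and len(rx):
            vte = dx[matches_any_prefix(dx["code"], config.vte_codes)]
            treat = rx[matches_any_prefix(rx["code"], config.thrombolytic_anticoagulant_codes)]

            # outpatient rule: same patient, same facility, same date
            vo = vte[vte["setting"] == "outpatient"]
            to = treat[treat["setting"] == "outpatient"]
            if len(vo) and len(to):
                merged = vo[["patient_id", "facility_id", "date"]].merge(
                    to[["patient_id", "facility_id", "date"]].drop_duplicates(),
                    on=["patient_id", "facility_id", "date"],
                )
                events.append(merged[["patient_id", "date"]].assign(setting="outpatient"))

            # inpatient rule: same hospitalization, event dated at the earliest
            # prescription on/after (or strictly after) the diagnosis
            vi = vte[vte["hospitalization_id"].notna()]
            ti = treat[treat["hospitalization_id"].notna()]
            if len(vi) and len(ti):
                hosp_ids = set(dataset.hospitalizations["hospitalization_id"].tolist())
                unknown = set(vi["hospitalization_id"].tolist()) | set(
                    ti["hospitalization_id"].tolist()
                )
                unknown -= hosp_ids
                if unknown:
                    raise ValueError(
                        f"records reference unknown hospitalization ids: {sorted(unknown)[:5]}"
                    )
                pairs = vi[["patient_id", "hospitalization_id", "date"]].merge(
                    ti[["hospitalization_id", "date"]],
                    on="hospitalization_id",
                    suffixes=("_dx", "_rx"),
                )
                if config.same_day_treatment_qualifies:
                    pairs = pairs[pairs["date_rx"] >= pairs["date_dx"]]
                else:
                    pairs = pairs[pairs["date_rx"] > pairs["date_dx"]]
                if len(pairs):
                    best = (
                        pairs.groupby(["patient_id", "hospitalization_id", "date_dx"])["date_rx"]
                        .min()
                        .reset_index()
                    )
                    events.append(
                        best.rename(columns={"date_rx": "date"})[["patient_id", "date"]].assign(
                            setting="inpatient"
                        )
                    )

        if events:
            table = pd.concat(events, ignore_index=True).drop_duplicates(
                subset=["patient_id", "date"]
            )
        else:
            table = pd.DataFrame({"patient_id": [], "date": [], "setting": []})
        self.table = table.sort_values(["patient_id", "date"]).reset_index(drop=True)
        pos = self.pid_index.get_indexer(self.table["patient_id"]) if len(self.table) else np.array([], dtype=np.int64)
        days = self.table["date"].to_numpy(dtype=np.int64) if len(self.table) else np.array([], dtype=np.int64)
        self.keys = pack_keys(pos, days)

    def earliest_in_window(self, positions, lo, hi) -> np.ndarray:
        """Earliest event day in [lo, hi] per member, -1 if none."""
        day = first_on_or_after(self.keys, positions, lo)
        day = np.where((day >= 0) & (day <= hi), day, -1)
        return day


def ascertain_vte(patient_id, window, dataset, config) -> VteEvent | None:
    """Earliest qualifying VTE event for one patient inside [a, b]."""
    a, b = window
    idx = EventIndex(dataset, config)
    sub = idx.table[
        (idx.table["patient_id"] == patient_id)
        & (idx.table["date"] >= a)
        & (idx.table["date"] <= b)
    ]
    if not len(sub):
        return None
    row = sub.iloc[0]
    return VteEvent(patient_id, int(row["date"]), str(row["setting"]))


class FollowUpBuilder:
    """Builds ITT and per-protocol follow-up records for a cohort."""

    def __init__(self, members: pd.DataFrame, dataset: ClaimsDataset, config: StudyDesignConfig):
        self.members = members.reset_index(drop=True)
        self.dataset = dataset
        self.config = config
        self.events = EventIndex(dataset, config)
        pat = dataset.patients
        self.pid_index = pd.Index(pat["patient_id"].to_numpy())
        self.positions = self.pid_index.get_indexer(self.members["patient_id"]).astype(np.int64)
        self.obs_end = pat["observable_end"].to_numpy(dtype=np.int64)[self.positions]
        self.index_day = self.members["index_date"].to_numpy(dtype=np.int64)
        if (self.obs_end < self.index_day).any():
            raise ValueError("observable period ends before the index date for some member")
        self.is_exposed = (self.members["group"] == "exposed").to_numpy()

        rx = dataset.prescriptions
        pema_mask = matches_any_prefix(rx["code"], config.pemafibrate_codes) if len(rx) else np.array([], dtype=bool)
        fib_mask = matches_any_prefix(rx["code"], config.fibrate_codes) if len(rx) else np.array([], dtype=bool)
        other_fib = fib_mask & ~pema_mask
        self._pema = rx[pema_mask] if len(rx) else rx
        pos_of = self.pid_index.get_indexer(rx.loc[other_fib, "patient_id"]) if len(rx) else np.array([], dtype=np.int64)
        self.other_fib_keys = pack_keys(
            pos_of,
            rx.loc[other_fib, "date"].to_numpy(dtype=np.int64) if len(rx) else np.array([], dtype=np.int64),
        )
        pos_any = self.pid_index.get_indexer(rx.loc[fib_mask, "patient_id"]) if len(rx) else np.array([], dtype=np.int64)
        self.any_fib_keys = pack_keys(
            pos_any,
            rx.loc[fib_mask, "date"].to_numpy(dtype=np.int64) if len(rx) else np.array([], dtype=np.int64),
        )
        # per-patient study-drug prescription arrays for episode construction
        self._pema_by_pid = {
            pid: grp for pid, grp in self._pema.groupby("patient_id")
        } if len(self._pema) else {}

    def _base_frame(self, analysis: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "member_id": self.members["member_id"].to_numpy(),
                "patient_id": self.members["patient_id"].to_numpy(),
                "group": self.members["group"].to_numpy(),
                "analysis": analysis,
                "start": self.index_day,
            }
        )

    def itt(self) -> pd.DataFrame:
        """ITT follow-up: index to event or end of the observable period;
        treatment changes during follow-up are ignored."""
        event_day = self.events.earliest_in_window(self.positions, self.index_day, self.obs_end)
        has_event = event_day >= 0
        end = np.where(has_event, event_day, self.obs_end)
        rec = self._base_frame("ITT")
        rec["end"] = end
        rec["event"] = has_event
        rec["event_date"] = np.where(has_event, event_day, -1)
        rec["censor_reason"] = np.where(has_event, "event", "end_observable")
        return rec

    def pp(self, gap_grace_days: int) -> pd.DataFrame:
        """Per-protocol follow-up for one gap/grace scenario.

        Exposed: censored at the first of event, end of observable period,
        first other-fibrate prescription, or exposure end (episode containing
        the index + grace).  Control: censored at the first of event, end of
        observable period, or first fibrate (incl. study-drug) prescription
        strictly within follow-up.
        """
        g = int(gap_grace_days)
        n = len(self.members)
        bound_exposure = np.full(n, np.iinfo(np.int64).max // 4)
        bound_fibrate = np.full(n, np.iinfo(np.int64).max // 4)

        exp_idx = np.nonzero(self.is_exposed)[0]
        for i in exp_idx:
            pid = self.members.at[i, "patient_id"]
            grp = self._pema_by_pid.get(pid)
            if grp is None:
                raise ValueError(f"exposed member {pid} has no study-drug prescriptions")
            end_ep = _episode_end_from_index(
                grp["date"].to_numpy(dtype=np.int64),
                grp["days_supply"].to_numpy(dtype=np.int64),
                int(self.index_day[i]),
                g,
            )
            bound_exposure[i] = end_ep + g
        # exposed: first other-fibrate on/after index
        of = first_on_or_after(self.other_fib_keys, self.positions[exp_idx], self.index_day[exp_idx])
        bound_fibrate[exp_idx] = np.where(of >= 0, of, bound_fibrate[exp_idx])
        # control: first fibrate of any kind after the index (none can exist
        # on/before it by construction)
        ctl_idx = np.nonzero(~self.is_exposed)[0]
        cf = first_on_or_after(self.any_fib_keys, self.positions[ctl_idx], self.index_day[ctl_idx])
        bound_fibrate[ctl_idx] = np.where(cf >= 0, cf, bound_fibrate[ctl_idx])

        end_no_event = np.minimum(self.obs_end, np.minimum(bound_exposure, bound_fibrate))
        event_day = self.events.earliest_in_window(self.positions, self.index_day, end_no_event)
        has_event = event_day >= 0
        end = np.where(has_event, event_day, end_no_event)

        reason = np.where(
            has_event,
            "event",
            np.where(
                bound_fibrate <= np.minimum(self.obs_end, bound_exposure),
                np.where(self.is_exposed, "other_fibrate", "pemafibrate_start"),
                np.where(bound_exposure <= self.obs_end, "exposure_end", "end_observable"),
            ),
        )
        rec = self._base_frame(f"PP-{g}")
        rec["end"] = end
        rec["event"] = has_event
        rec["event_date"] = np.where(has_event, event_day, -1)
        rec["censor_reason"] = reason
        return rec


def itt_followup(member, dataset, config) -> pd.Series:
    """ITT follow-up record for a single member."""
    builder = FollowUpBuilder(pd.DataFrame([member]), dataset, config)
    return builder.itt().iloc[0]


def pp_followup(member, dataset, config, gap_grace_days) -> pd.Series:
    """Per-protocol follow-up record for a single member."""
    builder = FollowUpBuilder(pd.DataFrame([member]), dataset, config)
    return builder.pp(gap_grace_days).iloc[0]


def person_time_and_events(followups: pd.DataFrame, weights=None) -> dict:
    """Event count, person-years and incidence per 100 person-years."""
    if not len(followups):
        raise ValueError("no follow-up records")
    days = (followups["end"] - followups["start"]).to_numpy(dtype=float)
    events = followups["event"].to_numpy(dtype=float)
    if weights is None:
        weights = np.ones(len(followups))
    weights = np.asarray(weights, dtype=float)
    person_years = float((days * weights).sum() / DAYS_PER_YEAR)
    n_events = float((events * weights).sum())
    return {
        "events": n_events,
        "person_years": person_years,
        "rate_per_100py": incidence_rate(n_events, person_years),
    }


def incidence_rate(events: float, person_years: float) -> float:
    """Events per 100 person-years."""
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    return 100.0 * events / person_years
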