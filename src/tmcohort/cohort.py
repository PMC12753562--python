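"""Cohort construction: inclusion, the eight exclusion criteria, and
time-matched 1:k control selection.

The design addresses immortal time bias: for an exposed patient whose first
study-drug prescription falls X days after their first dyslipidemia
diagnosis, each matched control's index date is set X days after the
control's own first diagnosis, so both groups enter follow-up at the same
"disease age".  A patient may appear in both groups at different index dates
(permitted by the design); within one matched set controls are sampled
without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._windows import count_in_window, first_on_or_after, pack_keys
from .claims import ClaimsDataset
from .config import StudyDesignConfig, matches_any_prefix
from .dates import age_in_years

logger = logging.getLogger(__name__)

EXCLUSION_LABELS = {
    1: "observable period shorter than the baseline window",
    2: "fibrate prescription during the baseline period",
    3: "VTE diagnosis during the baseline period",
    4: "study-drug prescription before first eligible diagnosis",
    5: "observable period ends before the index date",
    6: "age under minimum at the index date",
    7: "biliary atresia / gallstone diagnosis during the baseline period",
    8: "cyclosporine / rifampicin prescription during the baseline period",
}


@dataclass
class AttritionReport:
    """Ordered per-step remaining counts, per group."""

    steps: list = field(default_factory=list)  # (label, group, remaining)

    def add(self, label: str, group: str, remaining: int) -> None:
        self.steps.append((label, group, int(remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "group", "remaining"])


class CohortIndexes:
    """Precomputed per-patient record indexes used by every cohort query."""

    def __init__(self, dataset: ClaimsDataset, config: StudyDesignConfig):
        self.dataset = dataset
        self.config = config
        pat = dataset.patients
        self.n = len(pat)
        self.patient_ids = pat["patient_id"].to_numpy()
        self.pid_index = pd.Index(self.patient_ids)
        self.obs_start = pat["observable_start"].to_numpy(dtype=np.int64)
        self.obs_end = pat["observable_end"].to_numpy(dtype=np.int64)
        self.birth = pat["birth_date"].to_numpy(dtype=np.int64)

        dx, rx = dataset.diagnoses, dataset.prescriptions

        def keys(table, prefixes):
            if not len(table):
                return pack_keys(np.array([], dtype=np.int64), np.array([], dtype=np.int64))
            mask = matches_any_prefix(table["code"], prefixes)
            pos = self.pid_index.get_indexer(table.loc[mask, "patient_id"])
            return pack_keys(pos, table.loc[mask, "date"].to_numpy(dtype=np.int64))

        self.dysl_keys = keys(dx, config.dyslipidemia_codes)
        self.pema_keys = keys(rx, config.pemafibrate_codes)
        self.fibrate_keys = keys(rx, config.fibrate_codes)
        self.vte_keys = keys(dx, config.vte_codes)
        self.contra_dx_keys = keys(dx, config.contraindication_dx_codes)
        self.contra_rx_keys = keys(rx, config.contraindication_rx_codes)

        # first dyslipidemia diagnosis ever, per patient position
        all_pos = np.arange(self.n)
        self.first_dysl = first_on_or_after(self.dysl_keys, all_pos, 0)
        eligible = (self.first_dysl >= 0) & (self.first_dysl >= config.cutoff_day)
        self.first_eligible = np.where(eligible, self.first_dysl, -1)
        self.first_pema = first_on_or_after(self.pema_keys, all_pos, 0)

    def position(self, patient_id) -> int:
        pos = self.pid_index.get_loc(patient_id)
        return int(pos)


def first_eligible_diagnosis(patient_id, dataset: ClaimsDataset, config: StudyDesignConfig):
    """Earliest dyslipidemia diagnosis on/after the cutoff, provided the
    patient's overall first diagnosis does not precede the cutoff; None
    otherwise."""
    idx = CohortIndexes(dataset, config)
    day = idx.first_eligible[idx.position(patient_id)]
    return int(day) if day >= 0 else None


def _exclusions_bulk(
    idx: CohortIndexes, positions: np.ndarray, index_days: np.ndarray, role: str
) -> pd.DataFrame:
    """Boolean violation matrix (columns c1..c8) for candidate members."""
    cfg = idx.config
    b = cfg.baseline_days
    lo = index_days - b
    hi = index_days - 1
    out = pd.DataFrame(index=np.arange(len(positions)))
    out["c1"] = idx.obs_start[positions] > index_days - b
    out["c2"] = count_in_window(idx.fibrate_keys, positions, lo, hi) > 0
    out["c3"] = count_in_window(idx.vte_keys, positions, lo, hi) > 0
    if role == "exposed":
        first_elig = idx.first_eligible[positions]
        fp = idx.first_pema[positions]
        out["c4"] = (fp >= 0) & (fp < first_elig)
        out["c5"] = False
    else:
        out["c4"] = False
        out["c5"] = idx.obs_end[positions] < index_days
    out["c6"] = age_in_years(idx.birth[positions], index_days) < cfg.min_age
    out["c7"] = count_in_window(idx.contra_dx_keys, positions, lo, hi) > 0
    out["c8"] = count_in_window(idx.contra_rx_keys, positions, lo, hi) > 0
    return out


def check_exclusions(patient_id, index_date, role, dataset, config):
    """Evaluate all eight exclusion criteria for one candidate member.

    Returns (eligible, violated_labels); every violated criterion is
    reported, not only the first.
    """
    if role not in ("exposed", "control"):
        raise ValueError("role must be 'exposed' or 'control'")
    idx = CohortIndexes(dataset, config)
    pos = np.array([idx.position(patient_id)])
    if role == "exposed":
        at_index = count_in_window(
            idx.pema_keys, pos, np.array([index_date]), np.array([index_date])
        )
        if at_index[0] == 0:
            raise ValueError(
                "exposed role requires a study-drug prescription exactly at the index date"
            )
    row = _exclusions_bulk(idx, pos, np.array([int(index_date)]), role).iloc[0]
    violated = [EXCLUSION_LABELS[i] for i in range(1, 9) if row[f"c{i}"]]
    return len(violated) == 0, violated


def _exposed_members(idx: CohortIndexes, attrition: AttritionReport) -> pd.DataFrame:
    cfg = idx.config
    all_pos = np.arange(idx.n)
    has_elig = idx.first_eligible >= 0
    attrition.add("patients in the database", "exposed", idx.n)
    attrition.add("first dyslipidemia diagnosis on/after the cutoff", "exposed", has_elig.sum())

    # index = first study-drug prescription on/after the first eligible diagnosis
    cand = np.nonzero(has_elig & (idx.first_pema >= 0))[0]
    index_day = first_on_or_after(idx.pema_keys, cand, idx.first_eligible[cand])
    ok = index_day >= 0
    cand, index_day = cand[ok], index_day[ok]
    attrition.add("study-drug prescription on/after eligible diagnosis", "exposed", len(cand))

    viol = _exclusions_bulk(idx, cand, index_day, "exposed")
    remaining = np.ones(len(cand), dtype=bool)
    for i in range(1, 9):
        remaining &= ~viol[f"c{i}"].to_numpy()
        attrition.add(f"exclusion {i}: {EXCLUSION_LABELS[i]}", "exposed", remaining.sum())
    cand, index_day = cand[remaining], index_day[remaining]

    members = pd.DataFrame(
        {
            "patient_id": idx.patient_ids[cand],
            "position": cand,
            "group": "exposed",
            "index_date": index_day,
            "first_dyslipidemia_date": idx.first_eligible[cand],
            "offset_days_x": index_day - idx.first_eligible[cand],
        }
    )
    members = members.sort_values(["index_date", "patient_id"], kind="stable").reset_index(
        drop=True
    )
    members["matched_set_id"] = np.arange(len(members))
    return members


def build_exposed_cohort(dataset: ClaimsDataset, config: StudyDesignConfig):
    """Exposed members (one per qualifying patient) plus the attrition log."""
    idx = CohortIndexes(dataset, config)
    attrition = AttritionReport()
    members = _exposed_members(idx, attrition)
    return members.drop(columns="position"), attrition


def _control_ok(idx: CohortIndexes, positions: np.ndarray, index_days: np.ndarray) -> np.ndarray:
    """Vectorized control-role eligibility (lookback + all exclusions)."""
    cfg = idx.config
    b = cfg.baseline_days
    lo = index_days - b
    hi = index_days - 1
    ok = idx.first_eligible[positions] >= 0
    # study-drug-free lookback includes the index date itself
    ok &= count_in_window(idx.pema_keys, positions, lo, index_days) == 0
    ok &= idx.obs_start[positions] <= index_days - b
    ok &= count_in_window(idx.fibrate_keys, positions, lo, hi) == 0
    ok &= count_in_window(idx.vte_keys, positions, lo, hi) == 0
    ok &= idx.obs_end[positions] >= index_days
    ok &= age_in_years(idx.birth[positions], index_days) >= cfg.min_age
    ok &= count_in_window(idx.contra_dx_keys, positions, lo, hi) == 0
    ok &= count_in_window(idx.contra_rx_keys, positions, lo, hi) == 0
    return ok


class _ControlMatcher:
    """Candidate-pool computation shared across matched sets with equal X."""

    def __init__(self, idx: CohortIndexes):
        self.idx = idx
        self._cache: dict[int, np.ndarray] = {}
        self.eligible = np.nonzero(idx.first_eligible >= 0)[0]

    def pool(self, offset_x: int) -> np.ndarray:
        """Positions of every patient eligible as a control at X = offset_x."""
        if offset_x in self._cache:
            return self._cache[offset_x]
        elig = self.eligible
        cand_index = self.idx.first_eligible[elig] + offset_x
        pool = elig[_control_ok(self.idx, elig, cand_index)]
        self._cache[offset_x] = pool
        return pool


def match_controls(exposed_member, dataset, config, rng) -> pd.DataFrame:
    """Controls for one exposed member (standalone variant; see
    :func:`assemble_cohort` for the batched path)."""
    idx = CohortIndexes(dataset, config)
    matcher = _ControlMatcher(idx)
    return _draw_controls(idx, matcher, exposed_member, rng)


def _draw_controls(idx, matcher, member, rng) -> pd.DataFrame:
    cfg = idx.config
    x = int(member["offset_days_x"])
    pool = matcher.pool(x)
    self_pos = idx.pid_index.get_loc(member["patient_id"])
    pool = pool[pool != self_pos]
    if len(pool) <= cfg.match_ratio:
        chosen = pool
        if len(pool) < cfg.match_ratio:
            logger.warning(
                "matched set %s: control pool (%d) smaller than the match ratio (%d)",
                member["matched_set_id"],
                len(pool),
                cfg.match_ratio,
            )
    else:
        chosen = pool[rng.choice(len(pool), size=cfg.match_ratio, replace=False)]
    chosen = np.sort(chosen)
    return pd.DataFrame(
        {
            "patient_id": idx.patient_ids[chosen],
            "position": chosen,
            "group": "control",
            "index_date": idx.first_eligible[chosen] + x,
            "first_dyslipidemia_date": idx.first_eligible[chosen],
            "offset_days_x": x,
            "matched_set_id": member["matched_set_id"],
        }
    )


def _draw_controls_batch(idx: CohortIndexes, exposed: pd.DataFrame, rng) -> pd.DataFrame:
    """Controls for every exposed member, drawn by uniform rejection sampling.

    Sequentially accepting uniform proposals from the eligible-diagnosis set
    while skipping duplicates is distributionally identical to sampling the
    candidate pool uniformly without replacement, but avoids enumerating a
    pool per matched set.  Sets that fail to fill within the sampling rounds
    (near-empty pools) fall back to exact pool enumeration.
    """
    cfg = idx.config
    n_ex = len(exposed)
    if n_ex == 0:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "position",
                "group",
                "index_date",
                "first_dyslipidemia_date",
                "offset_days_x",
                "matched_set_id",
            ]
        )
    matcher = _ControlMatcher(idx)
    eligible = matcher.eligible
    ex_pos = exposed["position"].to_numpy()
    ex_x = exposed["offset_days_x"].to_numpy()
    chosen: list[set] = [set() for _ in range(n_ex)]
    pending = np.arange(n_ex)
    if len(eligible):
        for _ in range(12):
            if not len(pending):
                break
            need = np.array([cfg.match_ratio - len(chosen[i]) for i in pending])
            reps = need + 2
            draw_member = np.repeat(pending, reps)
            cand = eligible[rng.integers(0, len(eligible), size=len(draw_member))]
            cand_index = idx.first_eligible[cand] + ex_x[draw_member]
            ok = _control_ok(idx, cand, cand_index)
            ok &= cand != ex_pos[draw_member]
            for mem, pos, good in zip(draw_member, cand, ok):
                if good and len(chosen[mem]) < cfg.match_ratio:
                    chosen[mem].add(int(pos))
            pending = pending[
                np.array([len(chosen[i]) < cfg.match_ratio for i in pending])
            ]
    # exact enumeration for stubborn sets (tiny pools)
    for i in pending:
        pool = matcher.pool(int(ex_x[i]))
        pool = pool[pool != ex_pos[i]]
        remaining = np.setdiff1d(pool, np.fromiter(chosen[i], dtype=np.int64, count=len(chosen[i])))
        k = cfg.match_ratio - len(chosen[i])
        if len(remaining) <= k:
            chosen[i].update(int(p) for p in remaining)
            if len(chosen[i]) < cfg.match_ratio:
                logger.warning(
                    "matched set %s: control pool (%d) smaller than the match ratio (%d)",
                    exposed["matched_set_id"].iloc[i],
                    len(chosen[i]),
                    cfg.match_ratio,
                )
        else:
            extra = remaining[rng.choice(len(remaining), size=k, replace=False)]
            chosen[i].update(int(p) for p in extra)

    counts = np.array([len(c) for c in chosen])
    flat = np.fromiter(
        (p for c in chosen for p in sorted(c)), dtype=np.int64, count=int(counts.sum())
    )
    set_ids = np.repeat(exposed["matched_set_id"].to_numpy(), counts)
    offsets = np.repeat(ex_x, counts)
    return pd.DataFrame(
        {
            "patient_id": idx.patient_ids[flat],
            "position": flat,
            "group": "control",
            "index_date": idx.first_eligible[flat] + offsets,
            "first_dyslipidemia_date": idx.first_eligible[flat],
            "offset_days_x": offsets,
            "matched_set_id": set_ids,
        }
    )


def assemble_cohort(dataset: ClaimsDataset, config: StudyDesignConfig, rng=None):
    """Exposed cohort plus time-matched controls.

    Exposed members are processed in ascending index-date order (ties broken
    by patient id) so the result is reproducible under one seed.  Returns
    (members, attrition); members has one row per patient-index pairing, and
    a patient may legitimately occur in both groups at different index
    dates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = CohortIndexes(dataset, config)
    attrition = AttritionReport()
    exposed = _exposed_members(idx, attrition)
    controls = _draw_controls_batch(idx, exposed, rng)
    attrition.add("matched controls selected", "control", len(controls))
    members = pd.concat([exposed, controls], ignore_index=True)
    dual = members.groupby("patient_id")["group"].nunique()
    n_dual = int((dual > 1).sum())
    if n_dual:
        logger.info("%d patients appear in both groups at different index dates", n_dual)
    members.attrs["n_dual_group_patients"] = n_dual
    members = members.drop(columns="position")
    members["member_id"] = np.arange(len(members))
    return members, attrition
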