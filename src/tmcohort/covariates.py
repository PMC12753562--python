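"""Baseline covariate extraction for cohort members.

Each code-defined covariate flag is 1 iff any record with a matching code
prefix falls inside the member's baseline window ``[index - baseline_days,
index - 1]``.  BMI and smoking come from the latest measurement inside the
window (ties on the same date resolved by record order, later row wins);
age and sex come from the patients table.  BMI is additionally binned into
the six conventional categories (<18.5, 18.5-25, 25-30, 30-35, 35-40, >=40)
coded 0..5, the ordinal form used by the imputation and propensity models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._windows import DAY_SPAN, count_in_window, pack_keys
from .claims import ClaimsDataset
from .config import CodeDictionary, StudyDesignConfig, matches_any_prefix
from .dates import age_in_years

BMI_EDGES = (18.5, 25.0, 30.0, 35.0, 40.0)
BMI_LABELS = ("<18.5", "18.5-25", "25-30", "30-35", "35-40", ">=40")


def bmi_category(values) -> np.ndarray:
    """Ordinal BMI category codes 0..5 (NaN preserved)."""
    values = np.asarray(values, dtype=float)
    cat = np.digitize(values, BMI_EDGES).astype(float)
    cat[np.isnan(values)] = np.nan
    return cat


def _latest_measurement(measurements: pd.DataFrame, kind: str, pid_index, positions, lo, hi):
    """Latest in-window measurement value per member; NaN when absent."""
    sub = measurements[measurements["kind"] == kind]
    out = np.full(len(positions), np.nan)
    if not len(sub):
        return out
    pos = pid_index.get_indexer(sub["patient_id"])
    day = sub["date"].to_numpy(dtype=np.int64)
    # stable sort by (patient, date) keeps original record order within a
    # date, so the last entry on the winning date is the later record
    order = np.lexsort((np.arange(len(sub)), day, pos))
    keys = pos[order] * DAY_SPAN + day[order]
    vals = sub["value"].to_numpy(dtype=float)[order]
    hi_pos = np.searchsorted(keys, positions * DAY_SPAN + np.maximum(hi, -1), side="right") - 1
    valid = hi_pos >= 0
    kk = keys[np.maximum(hi_pos, 0)]
    hit = valid & (kk // DAY_SPAN == positions) & (kk % DAY_SPAN >= np.maximum(lo, 0))
    out[hit] = vals[hi_pos[hit]]
    return out


def extract_covariates_bulk(
    members: pd.DataFrame,
    dataset: ClaimsDataset,
    dictionary: CodeDictionary,
    config: StudyDesignConfig,
) -> pd.DataFrame:
    """Covariate vectors for all cohort members, one row per member."""
    pat = dataset.patients
    pid_index = pd.Index(pat["patient_id"].to_numpy())
    positions = pid_index.get_indexer(members["patient_id"]).astype(np.int64)
    index_day = members["index_date"].to_numpy(dtype=np.int64)
    lo = index_day - config.baseline_days
    hi = index_day - 1

    out = pd.DataFrame(index=members.index)
    out["member_id"] = members.get("member_id", pd.Series(np.arange(len(members)))).to_numpy()
    birth = pat["birth_date"].to_numpy(dtype=np.int64)[positions]
    out["age"] = age_in_years(birth, index_day)
    out["female"] = (pat["sex"].to_numpy()[positions] == "F").astype(np.int64)

    for cov in dictionary.covariates:
        if cov.kind != "binary-from-codes":
            continue
        table = dataset.diagnoses if cov.record == "dx" else dataset.prescriptions
        if len(table):
            mask = matches_any_prefix(table["code"], cov.prefixes)
            pos = pid_index.get_indexer(table.loc[mask, "patient_id"])
            keys = pack_keys(pos, table.loc[mask, "date"].to_numpy(dtype=np.int64))
        else:
            keys = pack_keys(np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        out[cov.name] = (count_in_window(keys, positions, lo, hi) > 0).astype(np.int64)

    kinds = {c.name: c.kind for c in dictionary.covariates}
    if kinds.get("bmi") == "continuous-measurement":
        bmi = _latest_measurement(dataset.measurements, "bmi", pid_index, positions, lo, hi)
        out["bmi"] = bmi
        out["bmi_category"] = bmi_category(bmi)
    elif "bmi" in kinds:
        raise ValueError(f"unknown covariate kind for 'bmi': {kinds['bmi']}")
    if kinds.get("smoking") == "categorical-measurement":
        out["smoking"] = _latest_measurement(
            dataset.measurements, "smoking", pid_index, positions, lo, hi
        )
    elif "smoking" in kinds:
        raise ValueError(f"unknown covariate kind for 'smoking': {kinds['smoking']}")
    for cov in dictionary.covariates:
        if cov.kind not in (
            "binary-from-codes",
            "continuous-measurement",
            "categorical-measurement",
        ):
            raise ValueError(f"unknown covariate kind for '{cov.name}': {cov.kind}")
    return out


def extract_covariates(member, dataset, dictionary, config) -> pd.Series:
    """Covariate vector for a single cohort member."""
    frame = extract_covariates_bulk(pd.DataFrame([member]), dataset, dictionary, config)
    return frame.iloc[0]
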