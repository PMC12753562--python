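"""Synthetic longitudinal claims generator with known ground truth.

The generator emulates the structure of a hospital claims database for a
dyslipidemia population:

* every patient has a first dyslipidemia diagnosis (``E78``-prefixed) inside
  their observable period, plus periodic follow-up visits;
* initiation of the study drug after that diagnosis follows a per-day hazard
  that depends on baseline covariates (confounding into exposure), and
  initiators leave realistic refill prescription sequences (discrete
  days-supply, short administrative gaps, occasional long interruptions,
  permanent discontinuation);
* outcome (VTE) events arrive from a piecewise-constant-hazard counting
  process whose rate depends on the same covariates (confounding into
  outcome), is multiplied by ``exp(true_log_hr)`` from drug initiation
  onwards, and carries a diagnosis-proximal detection surge during the first
  months after the dyslipidemia diagnosis;
* each detected event emits a VTE diagnosis record plus a same-day,
  same-facility anticoagulant/thrombolytic prescription (outpatient) or a
  same-hospitalization prescription (inpatient), so the downstream
  diagnosis-plus-treatment ascertainment algorithm can find it; a fraction of
  events are deliberately non-qualifying (diagnosis-only, or treatment at a
  different facility);
* BMI and smoking measurements are recorded at visits and then deleted per
  patient under a missing-at-random mechanism conditioned only on fully
  observed covariates (age, sex, diabetes), calibrated to a target missing
  proportion.

Fixed config + seed gives byte-identical output tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .claims import ClaimsDataset
from .config import OTHER_FIBRATE_CODE, PEMAFIBRATE_PREFIX, SimulationConfig
from .dates import DAYS_PER_YEAR, to_day

_VTE_DX_CODES = np.array(["I260", "I269", "I801", "I802", "I821", "I829"])
_ANTICOAG_CODES = np.array(["B01AF01", "B01AB01", "B01AD01"])
_ANTICOAG_PROBS = np.array([0.50, 0.35, 0.15])
_PEMA_CODE = PEMAFIBRATE_PREFIX + "01"


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + linear)) == target."""
    if target <= 0.0:
        return -np.inf
    return brentq(lambda c: expit(c + linear).mean() - target, -30.0, 30.0, xtol=1e-10)


def _visit_days(rng, start, end, lo, hi, max_visits=60):
    """Per-patient visit schedules: start + cumsum of U(lo, hi) gaps <= end.

    Returns (patient_row_index, day) flat arrays; the first visit is at
    ``start`` itself.
    """
    n = len(start)
    if n == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    span = np.maximum(end - start, 0)
    m = min(max_visits, int(np.ceil(span.max() / lo)) + 1)
    gaps = rng.integers(lo, hi + 1, size=(n, m))
    days = start[:, None] + np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(gaps, axis=1)[:, :-1]], axis=1
    )
    keep = days <= end[:, None]
    idx = np.nonzero(keep)
    return idx[0], days[keep]


def generate_claims(config: SimulationConfig) -> ClaimsDataset:
    """Generate a claims dataset under ``config``; deterministic in the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    s0, s1 = to_day(cfg.study_start), to_day(cfg.study_end)
    launch = to_day(cfg.drug_launch_date)

    # --- patients -----------------------------------------------------------
    obs_start = s0 + rng.integers(0, min(366, max(s1 - s0 - 700, 1)), n)
    obs_end = s1 - rng.integers(0, 401, n)
    obs_end = np.minimum(np.maximum(obs_end, obs_start + 700), s1)
    female = rng.random(n) < cfg.prob_female
    age0 = np.clip(rng.normal(cfg.mean_age, cfg.sd_age, n), cfg.min_age, cfg.max_age)
    birth_day = obs_start - np.round(age0 * DAYS_PER_YEAR).astype(np.int64)
    bmi = np.clip(rng.normal(cfg.mean_bmi, cfg.sd_bmi, n), 14.0, 55.0)
    smoking = (rng.random(n) < cfg.prob_smoking).astype(np.int64)
    specs = list(cfg.covariate_spec)
    if specs:
        flags = np.column_stack([rng.random(n) < s.prevalence for s in specs]).astype(np.int64)
    else:
        flags = np.zeros((n, 0), dtype=np.int64)

    # --- first dyslipidemia diagnosis and visit schedule --------------------
    lo_dx = obs_start + 180
    hi_dx = obs_end - 200
    span = np.maximum(hi_dx - lo_dx, 1)
    first_dx = lo_dx + rng.integers(0, 10_000, n) % span
    first_dx = np.minimum(first_dx, obs_end)

    dx_rows = [
        (np.arange(n), first_dx, np.full(n, "E780"), np.full(n, "F0")),
    ]
    # occasional records that predate the launch cutoff (makes the patient
    # ineligible: their overall first diagnosis precedes the cutoff)
    early_mask = rng.random(n) < cfg.frac_early_dx
    early_idx = np.nonzero(early_mask)[0]
    if early_idx.size:
        offset = rng.integers(0, 120, early_idx.size)
        early_day = np.minimum(obs_start[early_idx] + offset, first_dx[early_idx] - 1)
        ok = early_day >= obs_start[early_idx]
        dx_rows.append(
            (early_idx[ok], early_day[ok], np.full(ok.sum(), "E780"), np.full(ok.sum(), "F0"))
        )
    visit_idx, visit_day = _visit_days(rng, first_dx + 1, obs_end, 120, 240)
    dx_rows.append(
        (visit_idx, visit_day, np.full(visit_idx.size, "E785"), np.full(visit_idx.size, "F0"))
    )

    # --- treatment initiation ----------------------------------------------
    age_dx = (first_dx - birth_day) / DAYS_PER_YEAR
    lp_treat = (
        flags @ np.array([s.beta_treat for s in specs])
        + cfg.beta_treat_age_per_decade * (age_dx - 65.0) / 10.0
        + cfg.beta_treat_female * female
        + cfg.beta_treat_bmi * (bmi - cfg.mean_bmi)
        + cfg.beta_treat_smoking * smoking
    )
    from scipy.special import logit as _logit

    base_logodds = (
        _logit(cfg.ever_user_fraction) if 0.0 < cfg.ever_user_fraction < 1.0 else -np.inf
    )
    ever_user = rng.random(n) < expit(base_logodds + lp_treat)
    delay = rng.exponential(cfg.uptake_mean_days, n)
    init_day = first_dx + np.ceil(delay).astype(np.int64)
    initiator = (
        ever_user
        & (delay <= cfg.uptake_window_days)
        & (init_day <= obs_end - 1)
        & (init_day >= launch)
    )
    init_day = np.where(initiator, init_day, np.iinfo(np.int64).max // 4)

    # --- refill sequences for initiators ------------------------------------
    rs = cfg.refill_spec
    rx_pid, rx_day, rx_supply = [], [], []
    active = np.nonzero(initiator)[0]
    start = init_day[active].copy()
    while active.size:
        supply = rng.choice(np.array(rs.supply_days), size=active.size, p=np.array(rs.supply_probs))
        rx_pid.append(active.copy())
        rx_day.append(start.copy())
        rx_supply.append(supply)
        short = rng.random(active.size) < rs.short_gap_prob
        gap = np.where(
            short,
            rng.integers(0, rs.short_gap_max + 1, active.size),
            rng.integers(rs.long_gap_min, rs.long_gap_max + 1, active.size),
        )
        nxt = start + supply + gap
        cont = (rng.random(active.size) >= rs.stop_prob) & (nxt <= obs_end[active] - 1)
        active, start = active[cont], nxt[cont]
    pema_pid = np.concatenate(rx_pid) if rx_pid else np.array([], dtype=np.int64)
    pema_day = np.concatenate(rx_day) if rx_day else np.array([], dtype=np.int64)
    pema_supply = np.concatenate(rx_supply) if rx_supply else np.array([], dtype=np.int64)

    # stray study-drug prescriptions before the first diagnosis (trips the
    # prior-use exclusion)
    stray_mask = (rng.random(n) < cfg.frac_pema_before_dx) & ~early_mask
    stray_idx = np.nonzero(stray_mask)[0]
    stray_day = first_dx[stray_idx] - rng.integers(30, 181, stray_idx.size)
    ok = (stray_day >= np.maximum(obs_start[stray_idx], launch)) & (
        stray_day <= obs_end[stray_idx]
    )
    stray_idx, stray_day = stray_idx[ok], stray_day[ok]

    # other-fibrate users
    of_idx = np.nonzero(rng.random(n) < cfg.frac_other_fibrate_user)[0]
    of_day = obs_start[of_idx] + (
        rng.integers(0, 10_000, of_idx.size) % np.maximum(obs_end[of_idx] - obs_start[of_idx], 1)
    )

    # contraindication records
    cdx_idx = np.nonzero(rng.random(n) < cfg.frac_contra_dx)[0]
    cdx_day = obs_start[cdx_idx] + (
        rng.integers(0, 10_000, cdx_idx.size) % np.maximum(obs_end[cdx_idx] - obs_start[cdx_idx], 1)
    )
    cdx_code = rng.choice(np.array(["K800", "K831"]), cdx_idx.size, p=np.array([0.8, 0.2]))
    crx_idx = np.nonzero(rng.random(n) < cfg.frac_contra_rx)[0]
    crx_day = obs_start[crx_idx] + (
        rng.integers(0, 10_000, crx_idx.size) % np.maximum(obs_end[crx_idx] - obs_start[crx_idx], 1)
    )
    crx_code = rng.choice(np.array(["L04X001", "J04A101"]), crx_idx.size)

    # --- outcome events (piecewise-constant-rate counting process) ----------
    lp_out = (
        flags @ np.array([s.beta_outcome for s in specs])
        + cfg.beta_outcome_age_per_decade * (age_dx - 65.0) / 10.0
        + cfg.beta_outcome_female * female
        + cfg.beta_outcome_bmi * (bmi - cfg.mean_bmi)
        + cfg.beta_outcome_smoking * smoking
    )
    base_rate = cfg.baseline_hazard * np.exp(lp_out)
    brk = np.sort(
        np.column_stack(
            [first_dx, first_dx + cfg.early_window_days, np.minimum(init_day, obs_end + 1)]
        ),
        axis=1,
    )
    brk = np.clip(brk, obs_start[:, None], (obs_end + 1)[:, None])
    edges = np.column_stack([obs_start, brk, obs_end + 1])  # n x 5 -> 4 intervals
    lengths = np.maximum(np.diff(edges, axis=1), 0)
    t0 = edges[:, :-1]
    in_early = (t0 >= first_dx[:, None]) & (t0 < (first_dx + cfg.early_window_days)[:, None])
    exposed = t0 >= init_day[:, None]
    seg_rate = (
        base_rate[:, None]
        * np.where(in_early, cfg.early_hazard_ratio, 1.0)
        * np.exp(cfg.true_log_hr * exposed)
    )
    counts = rng.poisson(seg_rate * lengths)
    flat_counts = counts.ravel()
    rep = np.repeat(np.arange(counts.size), flat_counts)
    ev_pid = rep // counts.shape[1]
    seg = rep % counts.shape[1]
    lo = edges[ev_pid, seg]
    width = lengths[ev_pid, seg]
    ev_day = lo + np.floor(rng.random(ev_pid.size) * width).astype(np.int64)
    ev_day = np.minimum(ev_day, obs_end[ev_pid])
    # dedupe same patient-day events
    if ev_pid.size:
        order = np.lexsort((ev_day, ev_pid))
        ev_pid, ev_day = ev_pid[order], ev_day[order]
        keep = np.ones(ev_pid.size, dtype=bool)
        keep[1:] = (ev_pid[1:] != ev_pid[:-1]) | (ev_day[1:] != ev_day[:-1])
        ev_pid, ev_day = ev_pid[keep], ev_day[keep]

    k = ev_pid.size
    ev_dx_code = rng.choice(_VTE_DX_CODES, k)
    ev_rx_code = rng.choice(_ANTICOAG_CODES, k, p=_ANTICOAG_PROBS)
    ev_facility = np.char.add("F", rng.integers(1, 5, k).astype(str))
    dx_only = rng.random(k) < cfg.dx_only_event_fraction
    inpatient = (~dx_only) & (rng.random(k) < cfg.inpatient_fraction)
    outpatient = (~dx_only) & ~inpatient
    mismatch = outpatient & (rng.random(k) < cfg.facility_mismatch_fraction)

    # hospitalizations for inpatient events
    hosp_idx = np.nonzero(inpatient)[0]
    hosp_id = np.full(k, -1, dtype=np.int64)
    hosp_id[hosp_idx] = np.arange(1, hosp_idx.size + 1)
    adm = np.maximum(ev_day[hosp_idx] - 1, obs_start[ev_pid[hosp_idx]])
    dis = np.minimum(ev_day[hosp_idx] + 6, obs_end[ev_pid[hosp_idx]])
    in_rx_day = np.minimum(ev_day[hosp_idx] + rng.integers(0, 3, hosp_idx.size), dis)

    # --- covariate background records ---------------------------------------
    cov_dx_parts, cov_rx_parts = [], []
    for j, spec in enumerate(specs):
        idx = np.nonzero(flags[:, j])[0]
        vi, vd = _visit_days(rng, obs_start[idx] + rng.integers(0, 61, idx.size), obs_end[idx], 60, 150)
        part = (idx[vi], vd, np.full(vi.size, spec.code + "1"), np.full(vi.size, "F0"))
        (cov_dx_parts if spec.record == "dx" else cov_rx_parts).append(part)

    # --- measurements with MAR deletion -------------------------------------
    # lab visits start near the observable start and recur at most 170 days
    # apart, so any 180-day baseline window that satisfies the lookback
    # exclusion contains at least one measurement; missingness then comes
    # solely from the MAR deletion below
    mi, md = _visit_days(rng, obs_start + rng.integers(0, 11, n), obs_end, 100, 170)
    bmi_values = np.round(bmi[mi] + rng.normal(0.0, 0.5, mi.size), 1)
    smoke_values = smoking[mi].astype(float)

    ms = cfg.missing_spec
    cov_names = [s.name for s in specs]
    diabetes = (
        flags[:, cov_names.index("diabetes")] if "diabetes" in cov_names else np.zeros(n)
    )
    lin = (
        ms.beta_age_per_decade * (age0 - 65.0) / 10.0
        + ms.beta_female * female
        + ms.beta_diabetes * diabetes
    )
    intercept = _calibrate_intercept(lin, ms.target)
    p_missing = expit(intercept + lin) if np.isfinite(intercept) else np.zeros(n)
    drop_bmi = rng.random(n) < p_missing
    drop_smoke = rng.random(n) < p_missing

    meas_parts = []
    keep_b = ~drop_bmi[mi]
    meas_parts.append((mi[keep_b], md[keep_b], np.full(keep_b.sum(), "bmi"), bmi_values[keep_b]))
    keep_s = ~drop_smoke[mi]
    meas_parts.append(
        (mi[keep_s], md[keep_s], np.full(keep_s.sum(), "smoking"), smoke_values[keep_s])
    )

    # --- assemble tables -----------------------------------------------------
    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "sex": np.where(female, "F", "M"),
            "birth_date": birth_day,
            "observable_start": obs_start,
            "observable_end": obs_end,
        }
    )

    def _dx_frame(pid, day, code, facility, setting="outpatient", hosp=None):
        return pd.DataFrame(
            {
                "patient_id": np.asarray(pid, dtype=np.int64),
                "date": np.asarray(day, dtype=np.int64),
                "code": code,
                "facility_id": facility,
                "setting": setting,
                "hospitalization_id": pd.array(
                    hosp if hosp is not None else [pd.NA] * len(np.atleast_1d(pid)), dtype="Int64"
                ),
            }
        )

    dx_frames = [_dx_frame(*part) for part in dx_rows + cov_dx_parts]
    dx_frames.append(_dx_frame(cdx_idx, cdx_day, cdx_code, np.full(cdx_idx.size, "F0")))
    # VTE diagnoses: dx-only + outpatient + inpatient
    out_or_only = dx_only | outpatient
    dx_frames.append(
        _dx_frame(
            ev_pid[out_or_only],
            ev_day[out_or_only],
            ev_dx_code[out_or_only],
            ev_facility[out_or_only],
        )
    )
    dx_frames.append(
        _dx_frame(
            ev_pid[hosp_idx],
            ev_day[hosp_idx],
            ev_dx_code[hosp_idx],
            ev_facility[hosp_idx],
            "inpatient",
            hosp_id[hosp_idx],
        )
    )
    diagnoses = pd.concat(dx_frames, ignore_index=True)

    def _rx_frame(pid, day, code, supply, dose, facility, setting="outpatient", hosp=None):
        m = len(np.atleast_1d(pid))
        return pd.DataFrame(
            {
                "patient_id": np.asarray(pid, dtype=np.int64),
                "date": np.asarray(day, dtype=np.int64),
                "code": code,
                "days_supply": np.broadcast_to(np.asarray(supply, dtype=np.int64), (m,)),
                "daily_dose": np.broadcast_to(np.asarray(dose, dtype=float), (m,)),
                "facility_id": facility,
                "setting": setting,
                "hospitalization_id": pd.array(
                    hosp if hosp is not None else [pd.NA] * m, dtype="Int64"
                ),
            }
        )

    rx_frames = [
        _rx_frame(pema_pid, pema_day, _PEMA_CODE, pema_supply, 0.2, np.full(pema_pid.size, "F0")),
        _rx_frame(stray_idx, stray_day, _PEMA_CODE, 30, 0.2, np.full(stray_idx.size, "F0")),
        _rx_frame(of_idx, of_day, OTHER_FIBRATE_CODE, 30, 400.0, np.full(of_idx.size, "F0")),
        _rx_frame(crx_idx, crx_day, crx_code, 30, 1.0, np.full(crx_idx.size, "F0")),
    ]
    rx_frames += [
        _rx_frame(pid, day, np.char.add(code, ""), 30, 1.0, fac)
        for pid, day, code, fac in cov_rx_parts
    ]
    # outpatient event treatment: same day; same facility unless mismatched
    op = np.nonzero(outpatient)[0]
    op_fac = ev_facility[op].copy()
    mm = mismatch[op]
    op_fac[mm] = np.char.add("F", ((rng.integers(1, 4, mm.sum()) + 3) % 5 + 5).astype(str))
    rx_frames.append(_rx_frame(ev_pid[op], ev_day[op], ev_rx_code[op], 30, 1.0, op_fac))
    rx_frames.append(
        _rx_frame(
            ev_pid[hosp_idx],
            in_rx_day,
            ev_rx_code[hosp_idx],
            7,
            1.0,
            ev_facility[hosp_idx],
            "inpatient",
            hosp_id[hosp_idx],
        )
    )
    prescriptions = pd.concat(rx_frames, ignore_index=True)

    hospitalizations = pd.DataFrame(
        {
            "hospitalization_id": hosp_id[hosp_idx],
            "patient_id": ev_pid[hosp_idx],
            "admission_date": adm,
            "discharge_date": dis,
        }
    )

    measurements = pd.concat(
        [
            pd.DataFrame(
                {
                    "patient_id": np.asarray(pid, dtype=np.int64),
                    "date": np.asarray(day, dtype=np.int64),
                    "kind": kind,
                    "value": val,
                }
            )
            for pid, day, kind, val in meas_parts
        ],
        ignore_index=True,
    )

    diagnoses = diagnoses.sort_values(["patient_id", "date", "code"], kind="stable").reset_index(
        drop=True
    )
    prescriptions = prescriptions.sort_values(
        ["patient_id", "date", "code"], kind="stable"
    ).reset_index(drop=True)
    measurements = measurements.sort_values(
        ["patient_id", "date", "kind"], kind="stable"
    ).reset_index(drop=True)

    return ClaimsDataset(
        patients=patients,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        hospitalizations=hospitalizations,
        measurements=measurements,
    )
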