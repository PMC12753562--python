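"""Study configuration: simulation parameters, design constants and code lists.

Three configuration objects drive the pipeline:

* :class:`SimulationConfig` — the synthetic claims generator (sample size,
  confounding structure, true exposure effect, refill behaviour, MAR
  missingness).
* :class:`StudyDesignConfig` — the epidemiological design constants
  (inclusion cutoff, 180-day baseline, 1:5 time-matching, gap/grace
  scenarios, number of imputations) and the code lists used for inclusion,
  exclusion and outcome ascertainment.
* :class:`CodeDictionary` — covariate name -> code-prefix lists for baseline
  covariate extraction.

Code lists ship with a synthetic-compatible default dialect (ICD-10-like
diagnosis prefixes, ATC-like prescription prefixes); real-data vocabularies
are supplied as configuration, never hard-coded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .dates import to_day

# ---------------------------------------------------------------------------
# Synthetic code dialect
# ---------------------------------------------------------------------------

#: prescription prefix shared by all fibrates (class-level code)
FIBRATE_CLASS_PREFIX = "C10A2"
#: pemafibrate within the fibrate class
PEMAFIBRATE_PREFIX = "C10A2P"
#: a non-pemafibrate fibrate used by the generator (bezafibrate analog)
OTHER_FIBRATE_CODE = "C10A2B01"

VTE_DX_PREFIXES = ("I26", "I80", "I82")
ANTICOAGULANT_PREFIXES = ("B01AD", "B01AB", "B01AF")  # thrombolytic, parenteral, oral


@dataclass(frozen=True)
class CovariateSpec:
    """One generated baseline covariate and its structural coefficients.

    ``beta_treat`` is the log-odds-scale effect on the daily hazard of
    starting the study drug (confounding into exposure); ``beta_outcome`` is
    the log-hazard-ratio effect on the outcome.  ``record`` says whether the
    covariate leaves diagnosis ("dx") or prescription ("rx") records, with
    code prefix ``code``.
    """

    name: str
    code: str
    record: str  # "dx" | "rx"
    prevalence: float
    beta_treat: float = 0.0
    beta_outcome: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence for {self.name} outside [0, 1]")
        if self.record not in ("dx", "rx"):
            raise ValueError(f"record kind for {self.name} must be 'dx' or 'rx'")


def default_covariate_spec() -> tuple[CovariateSpec, ...]:
    """Default confounding structure of the generator.

    Prevalences follow the magnitudes typical of a dyslipidemia claims
    population (diabetes ~25%, cancer ~20%, hypertension ~14%, ...).  Signs
    are chosen so that drug initiators are younger, more often male, more
    metabolic (diabetes, statin, ezetimibe) and less oncologic than
    non-initiators, while the outcome hazard rises with age, cancer and
    cardiovascular comorbidity — i.e. genuine confounding in both
    directions.
    """
    return (
        CovariateSpec("diabetes", "E11", "dx", 0.25, 0.55, 0.30),
        CovariateSpec("hypertension", "I10", "dx", 0.14, 0.25, 0.25),
        CovariateSpec("chronic_kidney_disease", "N18", "dx", 0.08, 0.20, 0.20),
        CovariateSpec("liver_disease", "K76", "dx", 0.08, 0.60, 0.10),
        CovariateSpec("cancer", "C18", "dx", 0.20, -0.30, 0.80),
        CovariateSpec("heart_failure", "I50", "dx", 0.12, 0.00, 0.45),
        CovariateSpec("pneumonia", "J18", "dx", 0.15, -0.10, 0.30),
        CovariateSpec("statin", "C10AA", "rx", 0.25, 0.40, 0.00),
        CovariateSpec("ezetimibe", "C10AX", "rx", 0.033, 0.80, 0.00),
        CovariateSpec("oral_anticoagulant", "B01AF", "rx", 0.054, -0.20, 0.50),
        CovariateSpec("arb", "C09C", "rx", 0.12, 0.15, 0.10),
        CovariateSpec("insulin", "A10A", "rx", 0.05, 0.25, 0.20),
    )


@dataclass(frozen=True)
class RefillSpec:
    """Refill behaviour of the study drug.

    ``supply_days``/``supply_probs``: discrete days-supply distribution.
    Inter-refill gaps (uncovered days between one supply's end and the next
    prescription) are a mixture of short administrative gaps and long
    interruptions so that every gap/grace branch of the per-protocol
    follow-up algebra occurs in generated data.
    """

    supply_days: tuple[int, ...] = (30, 60, 90)
    supply_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    short_gap_prob: float = 0.75
    short_gap_max: int = 10
    long_gap_min: int = 40
    long_gap_max: int = 240
    stop_prob: float = 0.08  # per-refill probability of permanent discontinuation


@dataclass(frozen=True)
class MissingSpec:
    """MAR missingness for BMI and smoking measurements.

    All of a patient's BMI (resp. smoking) measurements are deleted with a
    logistic probability conditioned only on fully observed covariates (age,
    sex, diabetes); the intercept is calibrated at generation time so that
    the mean deletion probability equals ``target``.
    """

    target: float = 0.8
    beta_age_per_decade: float = 0.25
    beta_female: float = 0.10
    beta_diabetes: float = -0.40

    def __post_init__(self) -> None:
        if not 0.0 <= self.target < 1.0:
            raise ValueError("missing proportion target must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic claims generator."""

    n_patients: int = 20_000
    study_start: str = "2017-12-01"
    study_end: str = "2023-07-31"
    drug_launch_date: str = "2018-06-01"
    covariate_spec: tuple[CovariateSpec, ...] = field(default_factory=default_covariate_spec)
    true_log_hr: float = 0.0
    baseline_hazard: float = 3.6e-5  # outcome events per person-day (~1.3 per 100 PY)
    refill_spec: RefillSpec = field(default_factory=RefillSpec)
    missing_spec: MissingSpec = field(default_factory=MissingSpec)
    inpatient_fraction: float = 0.30
    seed: int = 0

    # demography / continuous covariates
    mean_age: float = 67.5
    sd_age: float = 14.3
    min_age: float = 16.0  # allows under-20 records so the age exclusion is exercised
    max_age: float = 99.0
    prob_female: float = 0.466
    mean_bmi: float = 24.0
    sd_bmi: float = 4.3
    prob_smoking: float = 0.40
    beta_treat_age_per_decade: float = -0.50
    beta_treat_female: float = -0.35
    beta_treat_bmi: float = 0.06  # per kg/m^2 above 24
    beta_treat_smoking: float = 0.30
    beta_outcome_age_per_decade: float = 0.35
    beta_outcome_female: float = -0.10
    beta_outcome_bmi: float = 0.03
    beta_outcome_smoking: float = 0.25

    # drug initiation: whether a patient ever starts the study drug is a
    # logistic function of the baseline covariates (the covariate_spec
    # beta_treat coefficients are log-odds on this indicator), with
    # ever_user_fraction the probability at covariate reference values.
    # Ever-users start after a front-loaded delay from the first diagnosis,
    # confined to an uptake window: uptake of a newly launched lipid drug
    # happens at or soon after the diagnostic work-up, so initiation hazard
    # drops to zero once the window closes.  Together these keep initiation
    # uncommon — mirroring the rarity of new-drug uptake in a national
    # claims universe — and keep late drop-in among matched controls (which
    # would dilute an ITT contrast) rare.
    ever_user_fraction: float = 0.10
    uptake_mean_days: float = 180.0
    uptake_window_days: int = 540

    # diagnosis-proximal detection surge: outcome hazard multiplied by
    # early_hazard_ratio within early_window_days after the first
    # dyslipidemia diagnosis (diagnostic work-up surfaces latent disease)
    early_hazard_ratio: float = 2.5
    early_window_days: int = 180

    # record realism
    dx_only_event_fraction: float = 0.10  # VTE dx without qualifying treatment
    facility_mismatch_fraction: float = 0.05  # outpatient rx at a different facility
    frac_pema_before_dx: float = 0.01
    frac_other_fibrate_user: float = 0.05
    frac_contra_dx: float = 0.03  # gallstone/biliary atresia codes in records
    frac_contra_rx: float = 0.01  # cyclosporine/rifampicin analog records
    frac_early_dx: float = 0.03  # extra dyslipidemia dx before the launch cutoff

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.inpatient_fraction <= 1.0:
            raise ValueError("inpatient_fraction outside [0, 1]")
        if not to_day(self.study_start) <= to_day(self.drug_launch_date) < to_day(self.study_end):
            raise ValueError("dates must satisfy study_start <= drug_launch_date < study_end")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesignConfig:
    """Design constants and code lists of the cohort study."""

    dyslipidemia_codes: tuple[str, ...] = ("E78",)
    fibrate_codes: tuple[str, ...] = (FIBRATE_CLASS_PREFIX,)
    pemafibrate_codes: tuple[str, ...] = (PEMAFIBRATE_PREFIX,)
    vte_codes: tuple[str, ...] = VTE_DX_PREFIXES
    contraindication_dx_codes: tuple[str, ...] = ("K831", "K80")
    contraindication_rx_codes: tuple[str, ...] = ("L04X0", "J04A1")
    thrombolytic_anticoagulant_codes: tuple[str, ...] = ANTICOAGULANT_PREFIXES
    cutoff_date: str = "2018-06-01"
    baseline_days: int = 180
    match_ratio: int = 5
    min_age: int = 20
    gap_grace_days: tuple[int, ...] = (0, 30, 90, 180)
    n_imputations: int = 20
    # whether an inpatient anticoagulant on the same day as the VTE diagnosis
    # qualifies as "after the record" (on-or-after reading)
    same_day_treatment_qualifies: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_days <= 0:
            raise ValueError("baseline_days must be positive")
        if self.match_ratio < 1:
            raise ValueError("match_ratio must be >= 1")
        if any(g < 0 for g in self.gap_grace_days):
            raise ValueError("gap_grace_days must be non-negative")
        for name in (
            "dyslipidemia_codes",
            "fibrate_codes",
            "pemafibrate_codes",
            "vte_codes",
            "thrombolytic_anticoagulant_codes",
        ):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    @property
    def cutoff_day(self) -> int:
        return to_day(self.cutoff_date)

    def replace(self, **kwargs) -> "StudyDesignConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Covariate code dictionary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateDef:
    name: str
    kind: str  # "binary-from-codes" | "continuous-measurement" | "categorical-measurement"
    prefixes: tuple[str, ...] = ()
    record: str = "dx"  # for binary-from-codes: which table to scan

    def __post_init__(self) -> None:
        if self.kind == "binary-from-codes" and not self.prefixes:
            raise ValueError(f"covariate {self.name} has an empty prefix list")


@dataclass(frozen=True)
class CodeDictionary:
    """Covariate name -> code prefixes used for baseline extraction."""

    covariates: tuple[CovariateDef, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(names) != len(set(names)):
            raise ValueError("covariate names must be unique")

    def binary_names(self) -> list[str]:
        return [c.name for c in self.covariates if c.kind == "binary-from-codes"]


def default_code_dictionary() -> CodeDictionary:
    """Synthetic-compatible default dictionary.

    Mirrors the generator's code dialect plus one structurally-zero
    covariate (``hiv``) whose code never occurs in generated data; it
    exercises the zero-variance-predictor handling of the imputation and
    propensity stages (the real study had the same situation with
    superficial vein thrombosis).
    """
    defs = [
        CovariateDef(spec.name, "binary-from-codes", (spec.code,), spec.record)
        for spec in default_covariate_spec()
    ]
    defs.append(CovariateDef("hiv", "binary-from-codes", ("B20",), "dx"))
    defs.append(CovariateDef("bmi", "continuous-measurement"))
    defs.append(CovariateDef("smoking", "categorical-measurement"))
    return CodeDictionary(tuple(defs))


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def save_config(path, simulation: SimulationConfig, design: StudyDesignConfig) -> None:
    payload = {"simulation": _as_plain(simulation), "design": _as_plain(design)}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _tupled(seq, cls=None):
    if cls is None:
        return tuple(seq)
    return tuple(cls(**item) for item in seq)


def load_config(path) -> tuple[SimulationConfig, StudyDesignConfig]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    sim_raw = dict(payload.get("simulation", {}))
    if "covariate_spec" in sim_raw:
        sim_raw["covariate_spec"] = _tupled(sim_raw["covariate_spec"], CovariateSpec)
    if "refill_spec" in sim_raw:
        rs = dict(sim_raw["refill_spec"])
        for key in ("supply_days", "supply_probs"):
            if key in rs:
                rs[key] = tuple(rs[key])
        sim_raw["refill_spec"] = RefillSpec(**rs)
    if "missing_spec" in sim_raw:
        sim_raw["missing_spec"] = MissingSpec(**sim_raw["missing_spec"])
    design_raw = dict(payload.get("design", {}))
    for key, val in list(design_raw.items()):
        if isinstance(val, list):
            design_raw[key] = tuple(val)
    return SimulationConfig(**sim_raw), StudyDesignConfig(**design_raw)


def matches_any_prefix(codes, prefixes: Sequence[str]):
    """Boolean mask: does each code start with any of the prefixes?

    Claims tables repeat a small code vocabulary millions of times, so the
    prefix test runs on the unique codes and is broadcast back.
    """
    import numpy as np
    import pandas as pd

    arr = np.asarray(codes, dtype=object)
    uniq, inverse = pd.factorize(arr, use_na_sentinel=True)
    # pd.factorize returns (codes, uniques)
    inverse, uniq = uniq, inverse
    uniq_mask = np.zeros(len(uniq), dtype=bool)
    for i, code in enumerate(uniq):
        if isinstance(code, str):
            uniq_mask[i] = any(code.startswith(p) for p in prefixes)
    out = np.zeros(len(arr), dtype=bool)
    valid = inverse >= 0
    out[valid] = uniq_mask[inverse[valid]]
    return out
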