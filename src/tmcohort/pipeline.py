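"""End-to-end study orchestration: simulate -> cohort -> covariates ->
imputation -> weighting -> follow-up -> survival analysis -> report.

Every stage writes plain delimited files under the output directory so any
stage can be inspected or re-entered, and a manifest records the config
snapshot, per-stage seeds, output hashes and warnings; replaying the same
config and master seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .claims import write_claims
from .cohort import assemble_cohort
from .config import (
    CodeDictionary,
    SimulationConfig,
    StudyDesignConfig,
    _as_plain,
    default_code_dictionary,
)
from .covariates import extract_covariates_bulk
from .followup import FollowUpBuilder, person_time_and_events
from .impute import FCSImputer
from .simulate import generate_claims
from .survival import (
    forest_table,
    km_discrepancy,
    pool_across_imputations,
    weighted_cox,
    weighted_km,
)
from .weighting import PropensityWeighter, balance_table

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_study(
    sim_config: SimulationConfig,
    design: StudyDesignConfig,
    out_dir,
    dictionary: CodeDictionary | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the full study and write all artifacts; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = dictionary or default_code_dictionary()
    master = int(seed if seed is not None else design.seed) % (2**31)
    # documented derivation rule: stage seeds are the master SeedSequence's
    # first spawned children, in stage order
    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ("simulate", "cohort", "impute"), np.random.SeedSequence(master).spawn(3)
        )
    }
    collector = _WarningCollector()
    logging.getLogger("tmcohort").addHandler(collector)
    written: list[Path] = []
    try:
        # 1. simulate
        dataset = generate_claims(sim_config.replace(seed=stage_seeds["simulate"]))
        written += write_claims(dataset, out / "claims")

        # 2. cohort
        rng = np.random.default_rng(stage_seeds["cohort"])
        members, attrition = assemble_cohort(dataset, design, rng)
        if not len(members):
            raise RuntimeError("stage build-cohort: no exposed patients qualified")
        cohort_path = out / "cohort.csv"
        members[
            ["member_id", "patient_id", "group", "index_date", "matched_set_id", "offset_days_x"]
        ].to_csv(cohort_path, index=False)
        attr_path = out / "attrition.csv"
        attrition.to_frame().to_csv(attr_path, index=False)
        written += [cohort_path, attr_path]
        exposed = (members["group"] == "exposed").to_numpy()

        # 3. covariates
        covariates = extract_covariates_bulk(members, dataset, dictionary, design)
        cov_path = out / "covariates.csv"
        covariates.to_csv(cov_path, index=False)
        written.append(cov_path)

        # 4. follow-up (ITT + every gap/grace scenario)
        builder = FollowUpBuilder(members, dataset, design)
        followups = {"ITT": builder.itt()}
        for g in design.gap_grace_days:
            followups[f"PP-{g}"] = builder.pp(g)
        fu_path = out / "followups.csv"
        pd.concat(followups.values(), ignore_index=True).to_csv(fu_path, index=False)
        written.append(fu_path)

        # 5. multiple imputation (predicts from covariates + ITT outcome/time)
        imputer = FCSImputer(
            m=design.n_imputations, seed=stage_seeds["impute"]
        )
        stack = imputer.fit_transform(covariates.drop(columns=["bmi"]), followups["ITT"])
        imp_dir = out / "imputations"
        imp_dir.mkdir(exist_ok=True)
        for i, table in enumerate(stack.tables, start=1):
            path = imp_dir / f"covariates_imp{i:02d}.csv"
            table.to_csv(path, index=False)
            written.append(path)

        # 6. propensity + SMRW per imputation
        weights = []
        weight_frame = pd.DataFrame({"member_id": members["member_id"].to_numpy()})
        for i, table in enumerate(stack.tables, start=1):
            weighter = PropensityWeighter().fit(table, exposed)
            weights.append(weighter.weights_)
            weight_frame[f"weight_imp{i:02d}"] = weighter.weights_
            weight_frame[f"propensity_imp{i:02d}"] = weighter.propensity_
        w_path = out / "weights.csv"
        weight_frame.to_csv(w_path, index=False)
        written.append(w_path)

        # 7. balance diagnostics
        bal = balance_table(covariates.drop(columns=["bmi"]), stack, weights, exposed)
        bal_path = out / "balance.csv"
        bal.to_csv(bal_path, index=False)
        written.append(bal_path)

        # 8. survival analysis per scenario, Rubin-pooled across imputations
        results = {}
        km_frames = []
        for label, fu in followups.items():
            fits = [
                weighted_cox(fu, exposed, weights=w, analysis=label) for w in weights
            ]
            pooled = pool_across_imputations(fits)
            pt_exp = person_time_and_events(fu[exposed])
            pt_ctl = person_time_and_events(fu[~exposed])
            results[label] = {
                "pooled": pooled,
                "events_exposed": pt_exp["events"],
                "events_control": pt_ctl["events"],
                "person_years_exposed": pt_exp["person_years"],
                "person_years_control": pt_ctl["person_years"],
                "rate_exposed_per_100py": pt_exp["rate_per_100py"],
                "rate_control_per_100py": pt_ctl["rate_per_100py"],
            }
            # KM from the first imputed dataset (report convention) plus a
            # cross-imputation consistency check
            curves = [weighted_km(fu, exposed, weights=w) for w in weights]
            km = curves[0].assign(analysis=label)
            km_frames.append(km)
            results[label]["km_max_discrepancy"] = km_discrepancy(curves)
        km_path = out / "km_curves.csv"
        pd.concat(km_frames, ignore_index=True).to_csv(km_path, index=False)
        written.append(km_path)
        forest = forest_table(results)
        res_path = out / "results.csv"
        forest.to_csv(res_path, index=False)
        written.append(res_path)
    except Exception as exc:  # re-raise with stage context
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        logging.getLogger("tmcohort").removeHandler(collector)

    manifest = {
        "config": {
            "simulation": _as_plain(sim_config),
            "design": _as_plain(design),
        },
        "master_seed": master,
        "stage_seeds": stage_seeds,
        "n_members": int(len(members)),
        "n_exposed": int(exposed.sum()),
        "n_controls": int((~exposed).sum()),
        "realized_match_ratio": float((~exposed).sum() / max(exposed.sum(), 1)),
        "n_dual_group_patients": int(members.attrs.get("n_dual_group_patients", 0)),
        "dropped_imputation_predictors": stack.dropped_predictors,
        "km_max_discrepancy": {k: v["km_max_discrepancy"] for k, v in results.items()},
        "warnings": collector.messages,
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
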