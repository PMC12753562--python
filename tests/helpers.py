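"""Test-only comparators.

The naive cohort deliberately reintroduces immortal time bias: exposed
follow-up starts at treatment initiation while control follow-up starts at
the first diagnosis, so the two groups sit at different disease ages when
the diagnosis-proximal hazard surge is active.  It exists purely to
demonstrate the bias the time-matched design removes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tmcohort.cohort import AttritionReport, CohortIndexes, _control_ok, _exposed_members
from tmcohort.followup import FollowUpBuilder
from tmcohort.survival import weighted_cox


def naive_crude_fit(dataset, design, rng):
    """Crude Cox fit on the naive (diagnosis-anchored controls) cohort."""
    idx = CohortIndexes(dataset, design)
    exposed = _exposed_members(idx, AttritionReport())
    elig = np.nonzero(idx.first_eligible >= 0)[0]
    # controls anchored at their own first diagnosis (offset zero), with the
    # same record-based exclusions applied at that anchor
    ok = _control_ok(idx, elig, idx.first_eligible[elig])
    pool = np.setdiff1d(elig[ok], exposed["position"].to_numpy())
    k = min(len(pool), design.match_ratio * len(exposed))
    chosen = pool[rng.choice(len(pool), size=k, replace=False)]
    controls = pd.DataFrame(
        {
            "patient_id": idx.patient_ids[chosen],
            "group": "control",
            "index_date": idx.first_eligible[chosen],
            "matched_set_id": -1,
            "offset_days_x": 0,
        }
    )
    members = pd.concat(
        [exposed.drop(columns="position"), controls], ignore_index=True
    )
    members["member_id"] = np.arange(len(members))
    builder = FollowUpBuilder(members, dataset, design)
    fu = builder.itt()
    return weighted_cox(fu, (members["group"] == "exposed").to_numpy())
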