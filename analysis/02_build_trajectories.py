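#!/usr/bin/env python
"""Rebuild treatment trajectories from the raw cohort files.

Applies the dose-plausibility filter (drop below half the minimal or above
five times the maximal therapeutic dose), merges same-class prescriptions
whose gaps are at most 30 days into trajectories, keeps each patient's first
trajectory, derives continuation and duration outcomes, aggregates sentiment
events, imputes missing GAF by predictive mean matching, and binarizes
everything into the 23-column case table.  Writes trajectories.csv,
case_table.csv, switch_flows.csv and a Table-1-style cohort summary.
"""

from pathlib import Path

from adtraj import (DoseTable, aggregate_sentiment, assemble_trajectories,
                    attach_patient_data, binarize, derive_outcomes,
                    filter_doses, impute_gaf, summarize_cohort,
                    switch_flow_table)
from adtraj.synthetic import read_cohort

OUT = Path("results")
IMPUTE_SEED = 14


def main() -> None:
    cohort = read_cohort(OUT / "cohort")
    dose_table = DoseTable.default()

    records = filter_doses(cohort.prescriptions, dose_table)
    print(f"dose filter: {len(cohort.prescriptions)} records in, "
          f"{len(records)} out "
          f"({len(cohort.prescriptions) - len(records)} implausible)")

    trajectories = assemble_trajectories(records, dose_table)
    by_patient: dict[str, list] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    for t in trajectories:
        derive_outcomes(t, by_patient[t.patient_id], dose_table)
    trajectories = attach_patient_data(trajectories, cohort.patients,
                                       cohort.gaf)
    for t in trajectories:
        aggregate_sentiment(cohort.sentiment_events, t)
    n_switch = sum(not t.continued for t in trajectories)
    print(f"{len(trajectories)} first trajectories; "
          f"{n_switch} switched ({n_switch / len(trajectories):.1%})")

    flows = switch_flow_table(trajectories, records, dose_table)
    flows.to_csv(OUT / "switch_flows.csv")

    n_missing = sum(t.gaf is None for t in trajectories)
    trajectories = impute_gaf(trajectories, seed=IMPUTE_SEED)
    print(f"imputed {n_missing} missing GAF scores")

    case_table = binarize(trajectories)
    case_table.to_csv(OUT / "case_table.csv", index=False)
    summary = summarize_cohort(trajectories)
    summary.to_csv(OUT / "cohort_summary.csv")
    print(summary.to_string())


if __name__ == "__main__":
    main()
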