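#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds the default ground-truth network (one six-level antidepressant-class
node plus seventeen binary patient/treatment/outcome variables, base rates
anchored at the reference cohort's Table-1-style proportions), samples 4,808
cases from it, and renders them into raw EHR-style files under
results/cohort/ — prescriptions with day-indexed intervals and doses,
demographics with DSM flags, GAF scores with 15% missingness, per-theme
sentiment events, and 2% deliberately implausible doses for the filter to
catch.  The ground truth itself is written as DOT + CPT JSON so later steps
can be scored against it.
"""

from pathlib import Path

from adtraj import ehr_ground_truth, render_ehr, sample_cases
from adtraj.synthetic import write_ground_truth

OUT = Path("results")
N_CASES = 4808
CPT_SEED, SAMPLE_SEED, RENDER_SEED = 11, 12, 13


def main() -> None:
    truth = ehr_ground_truth(cpt_seed=CPT_SEED, n_cases=N_CASES)
    print(f"ground truth: {len(truth.nodes)} nodes, "
          f"{len(truth.dag.arcs)} arcs")
    cases = sample_cases(truth, N_CASES, seed=SAMPLE_SEED)
    print(f"sampled {len(cases)} cases; "
          f"continuation rate {cases['continued'].mean():.3f}")
    raw = render_ehr(cases, seed=RENDER_SEED, corruption_rate=0.02,
                     gaf_missing_rate=0.15)
    OUT.mkdir(exist_ok=True)
    write_ground_truth(truth, OUT)
    raw.write(OUT / "cohort")
    cases.to_csv(OUT / "true_cases.csv", index=False)
    print(f"wrote {len(raw.prescriptions)} prescriptions, "
          f"{len(raw.sentiment_events)} sentiment events, "
          f"{raw.gaf['gaf'].isna().sum()} missing GAF scores "
          f"-> {OUT / 'cohort'}")


if __name__ == "__main__":
    main()
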