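# Methods

This note documents what the package computes, the assumptions and defaults
behind each stage, what the synthetic cohort does and does not emulate, and
the design decisions taken where more than one reasonable choice existed.

## Units of analysis: treatment trajectories

The analysis unit is a patient's **first antidepressant treatment
trajectory**: consecutive prescriptions of one antidepressant class
(SSRI, nSSRI, TriCA, TetraCA, MAOI, other), where a new same-class
prescription starting within **30 days** of the running episode's end
extends it (inclusive: a 30-day gap merges, 31 splits). Boundary and
tie-break choices:

- **Dose plausibility.** Records dosed below half the drug's minimal or
  above five times its maximal therapeutic dose are treated as data-entry
  faults and dropped *before* any other step. The rule is "less than" /
  "exceeding", so doses exactly at 0.5·min or 5·max survive. The packaged
  dose table (`data/synthetic_dose_table.csv`) is a **synthetic**,
  configurable stand-in with plausible per-drug bounds; swap in a real
  reference via `DoseTable.from_csv`.
- **Duration** is `end − start` in days (a same-day script has duration 0);
  the effective-duration outcome is `duration ≥ 35` days (five weeks, the
  minimum for an expected clinical effect).
- **First trajectory.** If two classes start the same day, class-name order
  breaks the tie (deterministic and auditable).
- **Continuation.** A trajectory is *continued* when its class equals the
  class of the patient's final antidepressant prescription in follow-up;
  pauses within the same class are therefore not switches, and a
  switch-and-return counts as continued. Co-prescription at the final time
  point counts as continued if the initial class is among the final classes.
- **Co-medication flags** (benzodiazepine, lithium, antipsychotics,
  disulfiram) require ≥ 1 day of interval overlap with the trajectory.

## Outcomes from note-derived sentiment

Sentiment events (theme ∈ {core complaints, social functioning, well-being,
experience}, polarity ±1) are pre-extracted inputs; the NLP detection model
that produces them is out of scope. Per trajectory and theme the mean
polarity of in-window events is taken; an event-free theme scores 0, which
the ≥ 0 binarization reads as non-negative — a deliberate convention, since
downstream variables must be complete and binary (no missing category), and
it is flagged per trajectory for audit.

## Imputation and binarization

GAF is the only incomplete variable. Missing scores are filled by **single
predictive-mean-matching** imputation: GAF is regressed (OLS) on the
complete covariates over observed rows; each missing row receives the
observed GAF of one of its five nearest neighbours in predicted mean, drawn
with a seeded generator. Imputed values are thus always members of the
observed support. Single rather than pooled multiple imputation is used
because one completed dataset feeds one structure-learning run; repeating
with different seeds is the supported sensitivity check.

Binarization cut points (all configurable, ties to the upper class): age at
48 and GAF at 50 (reference-cohort medians), duration at 35 days, sentiment
at 0. The case table has 23 binary columns in a fixed, documented order;
the six class indicators are one-hot.

## Structure learning

Both learners are implemented from scratch on a shared counting core.

- **G² test**: `2·Σ O ln(O/E)` summed over conditioning strata, referred to
  χ² with df = Σ over non-empty strata of (non-zero rows − 1)(non-zero
  columns − 1). Tests whose tables average fewer than 5 expected counts per
  cell are flagged degenerate and treated as non-rejections — conservative,
  and it caps conditioning-set growth automatically. Measured type-I error
  at α = 0.05 is ~0.05 (the acceptance suite checks [0.03, 0.07]).
- **PC-stable**: neighbour sets are frozen at the start of each
  conditioning-set-size level, making the skeleton phase order-independent
  (asserted under column permutation). V-structures come from separating
  sets; Meek rules R1–R3 close the orientation (R4 is only needed with
  background knowledge). Conflicting orientations fall back to undirected
  edges, and any directed cycle left by conflicting v-structures on finite
  data is demoted edge-by-edge until the CPDAG is valid.
- **BIC**: log-likelihood − (log n)/2 × free parameters, decomposable per
  node; larger is better. Local terms are memoised by (node, parent set).
- **Tabu search**: starts from the empty graph; single-arc moves scored by
  local BIC deltas; when nothing improves, the best non-tabu move is taken;
  the *inverse* of every accepted move is tabu for `tabu_length = 10`
  moves (with aspiration: a tabu move beating the best score is allowed).
  The search stops after `max_no_improve = 10` consecutive accepted moves
  that fail to improve the best score seen, and returns the best DAG
  visited. Stopping on best-score stagnation (rather than on locally
  non-improving moves) is what guarantees termination when the search
  oscillates around an optimum. Ties are broken by a seeded draw.

Neither α nor the search hyperparameters are reported for the original
analysis; the defaults above are documented assumptions, all configurable.

## Bootstrap averaging

`R = 100` nonparametric resamples (n rows with replacement at full n);
strength = fraction of resamples containing an edge in either orientation;
direction = fraction of edge-containing resamples orienting it each way,
undirected CPDAG edges counting ½ each. The averaged network keeps edges
with strength **strictly greater than 0.85**, orients by direction
majority, and leaves exact 50/50 ties undirected. Averaging is monotone in
the threshold. Before fitting, any undirected averaged edge is oriented by
its direction majority, falling back to the acyclicity-preserving
orientation (logged).

## Inference

CPTs are maximum-likelihood (conditional relative frequencies); parent
configurations never observed get a uniform row and are flagged.
`exact_query` answers P(target | evidence) by variable elimination
(cheapest-variable-first ordering) and is the oracle for
`logic_sampling_query`, which forward-samples full assignments in
topological order, rejects those contradicting the evidence, and reports
the estimate with its Monte-Carlo standard error; zero accepted samples
raise an explicit error rather than returning 0. Probability deltas between
two evidence scenarios are reported in percentage points. No causal
(do-operator) semantics are claimed anywhere: queries are observational
conditionals on the fitted joint.

## The synthetic cohort

The generator exists so the whole pipeline can be verified without access
to clinical data. A ground-truth network over the analysis variables is
built, cases are ancestrally sampled from it, and each case is rendered
*backwards* into raw records that the pipeline must reconstruct; with
corruption disabled and fixed seeds the round trip is exact on every
trajectory-derived variable.

- **Class node.** The six antidepressant classes are mutually exclusive, so
  the ground truth carries one categorical six-level class node (expanded to
  six one-hot indicators in the case table). A set of independent binary
  class flags could not generate valid cohorts, and the exclusivity
  dependence among indicators is represented as an undirected clique when
  the truth is compared with learned networks.
- **Defaults are the study conditions.** 4,808 trajectories; root-node base
  rates and child-node anchors follow the reference cohort's characteristics
  table (e.g. continuation 0.663, female 0.577, benzodiazepine 0.643,
  depression diagnosis 0.401); sentiment event counts are Poisson with
  per-theme means 4.06 / 1.65 / 4.04 / 5.69; GAF is missing completely at
  random at rate 0.15; ages uniform 18–85 and GAF uniform 20–70 around the
  binarization cuts (no generative model for either is stated anywhere, so
  these are the simplest choices consistent with the cut points); 2% of
  patients carry one implausibly dosed record to exercise the filter.
  Dates live on a per-patient day axis starting at 0; calendar formats are
  an I/O concern only.
- **Detectable effects.** Child CPTs are additive in their parents with
  per-parent contrasts guaranteed ≥ `effect_floor` (default 0.25): every
  arc is statistically detectable by design. Rows are kept a 0.1 margin
  away from 0 and 1 — near-deterministic strata would dilute marginal
  associations and silently defeat the floor — and the base rate is aimed
  at the anchor in the *marginal* by subtracting the expected parent-offset
  contribution (parents approximated as independent).
- **What it does not emulate.** Free-text notes (events are pre-extracted),
  site-specific referral and follow-up patterns, dose titration within an
  episode, calendar seasonality, and real sentiment magnitudes (only the
  per-trajectory sign class is controlled). Passing tests therefore show
  the *pipeline machinery* is correct under known generating conditions,
  not that any clinical conclusion transfers to real data.

## Benchmark experiment design

Scales were chosen so each stated tolerance is a multi-sigma bound rather
than a coin flip, and the whole suite runs in minutes on one CPU:

- **Exhaustive oracle.** Tabu results on 4-node data (n = 200, 20 truths)
  are compared against brute-force enumeration of all 543 labelled DAGs
  under a shared score cache.
- **CPDAG recovery.** PC is only uniformly consistent under
  strong-faithfulness-type conditions, and random CPTs routinely violate
  them (e.g. sibling pairs whose marginal dependence is second-order in the
  effects and undetectable at n = 20,000). Recovery benchmarks therefore
  draw 5-node sparse truths screened by exact joint enumeration: adjacent
  pairs must stay dependent (≥ 0.03) under every conditioning set, and
  spouse/unshielded-triple pairs under every non-separating set; distant
  pairs are unconstrained because their weak dependence plays no role in
  identifiability. The residual failure mode is the irreducible one — a
  single persistent α-level spurious edge — putting per-seed perfect
  recovery at ~0.90–0.92 at α = 0.05.
- **Parameter recovery** uses a layered truth (balanced roots, children fed
  only by roots) so every CPT cell sees thousands of rows and the 0.02
  entry tolerance sits beyond 4σ.
- **Inference oracle.** Logic sampling (10⁵ draws) versus variable
  elimination on 20 random 6-node networks, with single-variable
  modal-value evidence so the acceptance rate keeps the 0.01 band at > 4σ;
  delta signs are checked against full joint enumeration.
- **Cohort-scale averaging stability** samples n = 4,800 from 23-node
  truths (effect floor 0.2, ≤ 3 parents — matching the expectation that no
  variable has more than about five predictors) and requires all true arcs
  above and all non-adjacent pairs below the 0.85 strength threshold; run
  with the tabu learner, which is ~3× faster than PC here with the same
  stability.

## Known limitations

- The pipeline is observational and exploratory end to end; no causal
  claims are supported, and selection bias or hidden confounding in real
  cohorts is outside what the synthetic validation can detect.
- The G² χ² reference is asymptotic; very sparse strata are handled by df
  adjustment and the degenerate-test guard, not by exact tests.
- `exact_query`'s elimination ordering is greedy (cheapest-first); fine for
  the sparse averaged networks produced here, not for dense graphs.
- The marginal-anchoring of child base rates treats parents as independent;
  anchors on nodes with strongly dependent parents are approximate (the
  effect contrasts, which drive learning, are exact).
- Multi-level nodes are supported as roots only — sufficient for the class
  node, which has no parents in the default truth.
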