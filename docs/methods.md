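# Methods

`oncocea` re-implements, as a tested library and CLI, a US-payer
cost-effectiveness and budget-impact analysis of first-line atezolizumab,
pembrolizumab and platinum-based chemotherapy in stage IV NSCLC, stratified
by PD-L1 expression. This note documents the model, the assumptions baked
into each stage, the synthetic-data design, and the numerical choices.

## Pseudo-IPD reconstruction

Published trials report KM curves and numbers-at-risk tables, not
individual data. `km_reconstruct.reconstruct_ipd` implements the standard
iterative reconstruction: within each at-risk interval the number of
censored subjects is estimated, censor times are spread uniformly over the
interval (the conventional assumption when exact censor marks are
unavailable), events are allocated at the coordinate drop times by tracking
the product-limit identity, and the censor count is adjusted until the
implied number at risk matches the published count at the next boundary
(up to 100 sweeps per interval; the best allocation seen is kept and a
warning is logged if the match is not exact). Remaining survivors are
administratively censored at the last coordinate. If a total event count is
supplied, allocated events are rescaled by largest-remainder apportionment,
earliest time first. Without a risk table the degenerate mode assumes no
censoring before the last coordinate, and is flagged in the log.

Empty at-risk intervals (risk-table rows whose span contains no curve
coordinate, common in sparse curve tails) are skipped outright; they carry
no information and, if processed naively, would leak censor mass into the
preceding coordinate.

Preprocessing makes digitized input well-posed: points sorted by time,
survival clamped to [0, 1], monotone non-increase enforced by a running
minimum, duplicate times collapsed to the lower value, and a (0, 1) anchor
prepended.

Fidelity is quantified by `reconstruction_error`: the max and mean absolute
difference between the input survival and the KM estimate of the
reconstruction at the input coordinates. On clean synthetic curves
(n = 200/arm, Weibull event times, 20 %/yr dropout) the max deviation is
well below 0.02.

### A note on digitization granularity

The synthetic digitizer offers two modes. `digitize(ipd, grid, risk_times)`
samples the KM curve on a fixed grid (default monthly, risk table every
3 months — the typical figure layout). Grid sampling of a step function,
however, assigns each event to the first grid time at or after its true
step, shifting event times late by up to one grid interval; at a monthly
grid this inflates downstream fitted Weibull shapes by roughly 8 %.
`digitize_steps(ipd, risk_times)` records a coordinate at every visible
step — which is what a careful human digitizer traces — and removes the
artefact. The pipeline uses step-accurate curves; the grid mode remains for
emulating coarse extractions.

## Parametric survival fitting

Five families (exponential, Weibull, log-normal, log-logistic, gamma) are
fitted to the reconstructed IPD by maximising the right-censored
log-likelihood Σ_events ln f(t) + Σ_censored ln S(t), with densities and
survival functions from `scipy.stats`. Optimisation runs on log-transformed
parameters (Nelder–Mead, then a BFGS polish); start values come from a
least-squares Weibull plot (ln(−ln S_KM) vs ln t) where applicable, and
method-of-moments otherwise. Event times are floored at 10⁻⁸ months so
families with f(0) = 0 stay finite. The `converged` flag reports the
optimiser verdict honestly; a non-convergent family is excluded from
selection with a warning, and only the failure of all five raises.

Model selection minimises AIC = 2k − 2 ln L. Ties within 10⁻⁶ go to the
family with fewer parameters, then to a fixed family order — float equality
is meaningless at the precision the optimiser delivers. All times are in
months throughout fitting; cycle conversion happens in the cohort engine.

## Cohort model

The three health states — progression-free (PFS), progressed disease (PD),
death — are mutually exclusive; the engine is a partitioned-survival model:
occupancy is read directly off the fitted curves at each cycle start,

    pfs_k  = min(S_PFS(t_k), S_OS(t_k))
    dead_k = 1 − S_OS(t_k)
    pd_k   = 1 − pfs_k − dead_k ,

with t_k = k·(21/30.4375) months. This is the standard construction when
PFS and OS are fitted independently, and reproduces both curves by design;
no transition matrix is derived. Defaults: 3-week cycles, 3 %/yr
discounting with factor (1+r)^(−t/365.25 d), $200,000/QALY willingness to
pay, and a 20-year horizon operationalising "lifetime" (configurable; a
warning fires if more than 1 % of the cohort is alive at horizon). A month
is 365.25/12 days everywhere, for consistency with the annual discount
exponent. Half-cycle correction (averaging adjacent cycle boundaries) is
available but off by default, matching plain cycle-start evaluation.

Costs per cycle: first-line drug acquisition while progression-free (capped
at 4 cycles for chemotherapy — configurable to 6 — and at 35 cycles/2 years
for pembrolizumab per trial protocol; atezolizumab runs until progression),
routine disease-management costs per state, second-line therapy for a fixed
number of PD cycles followed by best supportive care, a one-time end-of-life
cost on death, and a one-time expected adverse-event management cost at
entry (Σ incidence × unit cost over grade ≥3 events, the usual convention
for trial-window toxicities). Utilities weight PFS/PD occupancy into QALYs.

Doses resolve from a reference patient (BSA 1.82 m², 70 kg; carboplatin by
the Calvert formula, dose = AUC × (CrCl + 25), with CrCl defaulting to
70 mL/min — an assumption, since no source value exists). Partial billing
units are rounded up (whole-vial billing).

Because the model has no explicit second-line state, the fraction of PD
occupancy on second-line therapy at cycle k is approximated as the
progression inflow of the last L cycles (L = 4 by default), capped by the
PD occupancy itself; the remainder receives best supportive care. This
slightly overstates second-line exposure when death is fast relative to L,
and is the main structural approximation of the engine.

## Incremental analysis and uncertainty

`econ_eval.compare` reports Δcost, ΔQALY and the ICER when both share a
sign; cheaper-and-better is labelled dominant, dearer-and-worse dominated,
and pure cost differences carry no ratio. ICERs are kept unrounded
internally; CSV output rounds money to cents. An optional frontier routine
applies strict and extended dominance; the base tables are pairwise only.

One-way DSA re-evaluates the ICER at each parameter's published range
(±20 % of base where no range exists) with everything else held at base,
and ranks parameters by spread. The PSA draws all parameters jointly and
independently — costs and quantities from Gamma, utilities from Beta, both
moment-matched to (base, s) with s = (max − min)/3.92, reading published
ranges as 95 % intervals; that single bridging assumption is isolated in
one function, and an infeasible Beta standard deviation is shrunk to the
support boundary with a warning. Fixed-tagged rows never vary. Survival
parameters are not varied in the base PSA (the parameter table carries no
survival rows); each of the 1,000 iterations re-runs the full accrual on
one joint draw, and the CEAC reports, per willingness-to-pay value, the
fraction of iterations in which each strategy attains the maximal net
monetary benefit λ·QALY − cost. One seeded RNG stream drives the whole run;
identical seeds give byte-identical CEAC files.

## Budget impact

Incident stage-IV NSCLC cases decline 2 %/yr from 1,312 in 2015; the 2020
model-entry count is truncated to whole patients (1,185) and multiplied by
the 22 % high-PD-L1 proportion (260.7 eligible patients, kept fractional
for expenditure arithmetic). Later cohorts decay by the exact geometric
factor rather than re-truncating each year, so adjacent cohorts' first-year
expenditures scale by exactly 0.98 — re-truncation would break that
identity while changing totals by well under 0.1 %. Each cohort contributes
its per-patient undiscounted annual cost difference (ICI − chemotherapy,
from the cohort model's yearly cost profile) for its years since diagnosis;
the net row of the cohort-year × calendar-year matrix is the column sum —
the cumulative incremental impact over all active cohorts in that year.

## Synthetic data

No trial data are redistributable, so the packaged scenario is synthetic: a
three-arm trial emulating a high-PD-L1 first-line population with Weibull
event times back-derived from typical published medians (OS ≈ 13 months on
chemotherapy and ≈ 20 on either ICI; PFS ≈ 5 vs 7–8 months), n = 300/arm,
5 %/yr exponential dropout and 30 months of administrative censoring.
Progression and death times are drawn independently per subject with PFS
time = min(progression, death), guaranteeing PFS ≤ OS — the only coupling
the downstream model requires. All randomness flows from one integer seed
via per-arm child streams.

What the generator does *not* emulate: treatment switching, cure fractions
or plateauing ICI tails, informative censoring, correlated PFS/OS beyond
the min-coupling, or digitization noise. Passing tests therefore
demonstrate the correctness of the machinery on data satisfying the
parametric assumptions, not fidelity of any specific published estimate:
the trial survival parameters, adverse-event incidences and second-line
composition behind the published totals were never printed, so absolute
costs/QALYs from the synthetic scenario are illustrative. The published
tables are instead validated through their internal arithmetic (incremental
consistency of totals, column-sum and geometric-decay identities of the
budget matrix), which the same code paths reproduce.

## Problem sizes and defaults used in the shipped checks

Reconstruction fidelity runs at n = 200/arm with 20 %/yr dropout; parameter
recovery at n = 300/arm (mean over three replicates); AIC selection
consistency at n = 1,000 over 50 replicates; the PSA at 1,000 iterations.
The packaged end-to-end scenario (n = 300/arm, all stages including the
PSA) completes in well under a minute on one CPU.

## Known limitations

- The second-line/BSC split inside PD is an approximation (above).
- Independent parameter draws: no correlation structure in the PSA.
- The partitioned-survival construction cannot distinguish death from PFS
  vs from PD; end-of-life costs attach to total mortality increments.
- AIC selection is per-endpoint/arm; no joint selection across arms is
  attempted, and only the five classical families are offered (no splines
  or cure models).
- Adverse events enter as costs only, with no utility decrement.
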