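# Methods

`cycleconn` implements two analyses of dense-sampling hormone-imaging
studies — a variance decomposition of whole-connectome similarity and a
cross-validated, network-based predictive model of contraceptive use
and ovarian-hormone levels — together with a synthetic-study generator
that provides a ground-truth test surface for both.

## The data model

A *study* is a session table plus one functional connectome per
session. Each session carries a subject id, a dataset id, a binary
hormonal-contraceptive (HC) flag, the menstrual-cycle day, estradiol
([E2]) and progesterone ([P4]) concentrations, and mean framewise
displacement (FD, mm). A connectome is a symmetric region × region
matrix of Pearson correlations between regional BOLD signals; edges are
indexed by the strict upper triangle in row-major order, a fixed total
order used everywhere in the package. The HC flag is constant within a
(subject, dataset) pair — a subject who changes contraceptive status is
represented as two dataset periods, as in the emulated design. Cycle
day is carried as metadata but never used as a model input (self-report
quality makes it unreliable; it only drives the sensitivity analysis
that drops ovulatory-window sessions).

## Connectome estimation

`timeseries_to_connectome` residualizes each region's parcellated BOLD
series against a confound design (OLS with intercept), standardizes the
residuals, and correlates regions pairwise. The default confound set is
the six rigid motion parameters, CSF and white-matter signals, and
their temporal derivatives (16 columns; grey matter excluded). A
temporal derivative is a first-order backward difference with 0 at the
first timepoint. Exactly collinear confound columns are dropped with a
warning. Multiple rest runs are residualized separately and their
residual series concatenated before the single correlation step, which
preserves per-run confound fits. An optional censor vector drops
flagged high-motion volumes before regression; it defaults to off since
the emulated studies report mean FD < 0.2 mm. The resulting matrix is
symmetrized by averaging with its transpose; residuals are orthogonal
to every confound column to numerical precision.

## Analysis 1: similarity decomposition

Similarity between two sessions is the Pearson correlation of their
edge vectors, Fisher-transformed (arctanh) with |r| clipped at
1 − 1e−7 so identical connectomes remain finite. Session pairs fall
into four categories: same *individual*; different subjects in the same
*dataset*; different subjects with the same *HC use* status; and all
different-subject pairs (*group*). The categories overlap by
definition, so each pair carries one membership flag per category and
summaries evaluate each category over all pairs meeting its own
definition; a mutually exclusive labeling (individual > dataset >
hc_use > group) is also provided for plotting. Category means are
compared with Welch two-sample t tests at α < 0.01 (Welch because
category sizes and variances differ by orders of magnitude). Pairwise z
values sharing a session are not independent; the t tests deliberately
ignore this, matching the analysis being reimplemented, and the
limitation is noted here rather than corrected. Subtracting two
category mean z values gives the *normalized effect magnitude* of one
factor relative to another.

## Analysis 2: network-based prediction

For an outcome y (HC use, [E2], or [P4]; hormone outcomes min-max
scaled to [0, 1] within each dataset), each discovery iteration
reshuffles sessions into `n_folds` folds (default 5). Within each
training fold:

1. every edge — and, for hormone outcomes, the outcome — is
   residualized against the nuisance covariates (FD; plus HC use for
   hormone models) with coefficients fitted on training rows only;
2. a connection-wise F test (`F = r²(n−2)/(1−r²)`, which equals the
   two-group one-way ANOVA F for a binary outcome) scores every edge,
   and edges with p < 0.05 survive;
3. the surviving edges are reduced to their largest connected
   component (most edges; ties broken toward the component containing
   the smallest region index);
4. component edges, standardized on training rows, enter an
   L2-penalized model — logistic regression for HC use, ridge
   regression for hormones — with the penalty α chosen from a
   log-spaced grid of 20 values in [1e−4, 10] by inner 3-fold
   cross-validation (accuracy / negative MSE; first best in grid order,
   so the choice is deterministic);
5. the model is scored on the held-out fold: classification accuracy
   for HC use, Spearman ρ between actual and predicted levels for
   hormones (Spearman rather than Pearson to tolerate non-normal
   hormone distributions). An empty component records chance-level
   performance (0.5 / 0) and selects nothing rather than aborting.

The iteration's performance is the mean across its folds. The edges an
iteration contributes to the weighted network are those present in the
component of **every** fold of that iteration — a stability-selection
rule. This is a deliberate design choice for the weighted-average
definition: because a 5% edge-level threshold admits chance edges in
every fold, a per-fold union makes nearly every edge's weight nonzero
over hundreds of fold draws, and a threshold defined as a fraction of
the *nonzero* edges then cannot isolate a planted component. The
intersection rule keeps never-reliably-selected edges at exactly zero
while leaving consistently selected edges with weights near the mean
performance. The union rule remains available
(`CVConfig.fold_aggregation="any"`). Edge weight = Σ (iteration mean
performance × stable-selection indicator) / n_iterations.

The weighted network is thresholded by retaining the top
⌈fraction × n⌉ of its n positive-weight edges (default 50%, ties by
edge index; the same rule is applied to the HC network, which the
emulated analysis thresholds without stating a number). The retained
edges are refit on the full discovery study (same residualization,
standardization and α-tuning machinery, now on all rows) and the
resulting model — edge subset, β, intercept, α, residualization
coefficients and feature statistics — is stored as JSON for transfer.

**Transfer.** On an external study with the same region set, edges are
residualized with the *stored* coefficients (nothing refit),
standardized with the stored statistics, and passed through the model.
For hormone outcomes the removed covariate contribution is added back
so predictions live on the outcome scale, and actual outcomes are
min-max scaled within the external dataset (cross-assay units make raw
concentrations incomparable). Reported: accuracy or Spearman ρ, plus
MSE (predicted probability vs. 0/1 label for HC).

No test-set leakage anywhere: residualization, F tests, component
selection, standardization and α selection see training rows only;
this is asserted by tests that perturb held-out rows and check fitted
parameters and selections are unchanged.

## The synthetic generator

Session edge weights are built as
`tanh(backbone + dataset offset + subject offset + planted effects +
noise)`: a sparse group backbone (density 0.25, weights N(0, 0.35²)),
per-dataset and per-subject Gaussian edge offsets (SD 0.08 / 0.15),
planted connected components of 15 edges for HC, [E2] and [P4] effects
(10 for motion) whose edge weights shift linearly with the (0-1
scaled) predictor, and i.i.d. Gaussian edge noise (SD 0.12). All
group-level structure (backbone, masks, coefficients, offsets) derives
from the ground-truth seed alone, so independently generated studies
can share planted effects — which is what makes synthetic transfer
experiments meaningful. Per-session noise, hormones and FD derive from
the design seed.

Hormone trajectories are sums of Gaussian bumps on the cycle-day axis:
estradiol has an ovulatory peak near 0.46·L (L = cycle length, valid
range 21–35 d) and a smaller mid-luteal shoulder, progesterone a
mid-luteal peak near 0.75·L over a low follicular baseline, with
amplitudes giving ~8-fold ([E2]) and ~80-fold ([P4]) dynamic range over
a full cycle; contraceptive users get flat suppressed levels (< 2-fold
range). A 2% (5% for HC users) multiplicative log-normal jitter
emulates assay noise. The default design mirrors the emulated studies:
one subject scanned daily for 30 naturally-cycling and 30
contraceptive-period sessions (two dataset periods), plus a weekly
study of three subjects — one naturally cycling, two HC users — with
10 total sessions.

What the generator does *not* emulate: BOLD-level temporal structure
(it operates at the connectome level; noise is i.i.d. per edge per
session with no autocorrelation), realistic assay error models, cycle
irregularity, or realistic effect sizes — the emulated studies report
no within-subject hormone–connectivity effect sizes, so planted
magnitudes are chosen for test power. Passing recovery tests therefore
demonstrates the pipeline's correctness and calibration, not that such
effects are detectable at real-world effect sizes.

## Numerical choices and degenerate inputs

- arctanh clipping at |r| ≤ 1 − 1e−7 (z ≈ 8.4 for perfect matches).
- Welch t on two identical constant samples is defined as t = 0, p = 1
  (scipy returns NaN for the 0/0 case).
- Constant edges in the F test get F = 0, p = 1; a constant outcome is
  rejected; a single-class training fold records chance performance.
- Constant covariates on training rows are dropped with a warning;
  constant features survive standardization via an SD floor of 1.
- Zero-variance edge vectors make a session's similarity pairs
  undefined; they are flagged and excluded from summaries.
- All randomness flows through seeded `numpy` generators (string tokens
  hashed via CRC-32 into `SeedSequence` entropy); identical seeds give
  bit-identical studies, weighted networks and models.

## Default experiment sizes

Tests and the acceptance script run at 50 regions (1,225 edges), 60
discovery sessions, 10 external sessions and 100 discovery iterations —
a deliberately scaled-down version of the emulated 268-region /
1,000-iteration analyses that preserves every pipeline stage while
keeping a full run in minutes on one CPU. The full-scale settings are
plain configuration (`n_regions`, `CVConfig.n_iterations`).

## Known limitations

- The pair-level t tests inherit the non-independence caveat above; no
  permutation or mixed-model correction is provided (a non-goal).
- Family-wise error inference for the classical network-based statistic
  (permutation NBS) is out of scope; component selection here serves
  prediction, not inference.
- Min-max outcome scaling within small external datasets (10 sessions)
  makes transfer MSE sensitive to the external range.
- With one densely sampled subject, contraceptive status is perfectly
  confounded with acquisition period (dataset), exactly as in the
  emulated design; the generator's dataset offsets let users study that
  confound explicitly.
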