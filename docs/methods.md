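# Methods

## The intrinsic ignition framework

The package quantifies how broadly spontaneous activity in one brain region
propagates through the rest of a parcellated network, from resting-state
BOLD time series alone.

Per subject, each regional signal is band-pass filtered (default
0.01–0.09 Hz, zero-phase Butterworth of order 2 applied forward and
backward), z-scored over time (population sd, so the transform is
idempotent), and reduced to a point process: a *driving event* occurs at TR
*t* when z_it > θ and z_i,t−1 ≤ θ. For every driving event, the set of
regions that themselves emit an event inside the window [t, t+w−1]
(default w = 4 TRs, trigger included) defines a binary co-activation
matrix — a clique on the active set. *Integration* is the size of the
largest connected subcomponent of that matrix divided by the number of
regions; isolated nodes count as singletons, so integration lies in
[1/N, 1]. A region's *ignition* is the mean and its *node-metastability*
the standard deviation of its per-event integrations.

Group structure is summarised three ways: (i) pairwise Monte-Carlo
permutation tests on per-subject whole-brain mean metastability, with
Benjamini–Hochberg FDR across the family and Cohen's d effect sizes;
(ii) the cortical *hierarchy* — regions ranked by cohort-mean
metastability, descending — and the *Hierarchy Disruption Factor*
HDF(a, b) = √Σ_r (a_r − b_r)², computed rank-against-rank on the sorted
values; (iii) linear mixed-effects models linking regional metastability to
amyloid-β and tau SUVR, and an mRMR + kNN classifier of diagnostic stage.

### Numerical and convention choices

- **θ = 1 z-unit (default).** The canonical choice for point-process
  reductions of BOLD signals; exposed in the configuration.
- **Window anchoring.** The 4-TR window starts at the trigger TR. Events
  whose window would overrun the scan are dropped, not truncated.
- **Population (n-denominator) sd** for node-metastability; at realistic
  event counts the difference from the n−1 convention is negligible, and the
  per-region record counts are reported so either can be reconstructed.
- **Co-activity is defined on threshold crossings** inside the window, not
  on above-threshold occupancy.
- **Every crossing of every region is a driving event**; overlapping windows
  from different drivers produce independent records.
- **Regions with fewer than two events** carry NaN metastability (NaN
  ignition when they have no events); cohort means use the available values.
- **HDF takes the square root** of the summed squared rank-aligned
  differences (an l2 norm). With the published uniform HC–AD group-mean gap
  of 0.024 over 379 regions this gives 0.024·√379 ≈ 0.467, matching the
  published HC-vs-AD disruption value at two decimals, whereas the
  un-rooted sum does not.
- **Permutation p-values are add-one corrected**,
  p = (1 + #{|Δ_perm| ≥ |Δ_obs|})/(n_perm + 1), so they are never 0; the test
  statistic is the two-sided difference of group means.
- **Cohen's d** uses the Bessel-corrected pooled sd.
- **Minimum detectable effect** uses the two-sample normal approximation
  d = (z_{1−α/2} + z_{power})·√(1/n_a + 1/n_b), with an optional
  Wilcoxon asymptotic-relative-efficiency adjustment (÷√0.955). For groups
  of 17 and 10 at α = 0.05 and power 0.8 this gives 1.12 (1.14 adjusted).

## Mixed-effects burden models

The whole-brain model is `metastability ~ abeta * tau` with a random
intercept per subject, fit by REML (statsmodels MixedLM); Wald
normal-approximation p-values. The RSN-level model adds the three-way fixed
interaction with the 7 network labels and a random intercept plus RSN
variance components within subject; subcortical regions are excluded.
Per-network burden effects are obtained by contrast (base term plus its
interaction with that network's level). The nested random structure is
fragile at ~36 subjects: the fit cycles optimisers (lbfgs, bfgs, powell, cg)
and, if the random-slope structure still fails to converge, falls back to
the random-intercept-only model and records the downgrade in the result.
MMSE is deliberately not a covariate.

## Staging classifier

Features are ignition, node-metastability, amyloid-β and tau SUVR per
cortical region (four measures × regions). mRMR greedily selects 10
features (configurable), scoring relevance minus mean redundancy with
plug-in mutual information on 4 equal-frequency bins per feature (the MID
scheme); constant features are excluded with a warning and ties resolve to
the earlier column, so selection is deterministic. The kNN classifier uses
Euclidean distance on features standardised by training-fold statistics;
scores are neighbour vote fractions, thresholded at 0.5 with ties broken
toward the smaller class label.

Evaluation is nested: leave-one-out in the outer loop; per fold, feature
selection and k-tuning see training data only. The inner loop scores
k ∈ {2, 3, 4, 5} on 20 repeated stratified 75/25 train/validation splits
and keeps the best mean validation accuracy (ties → smaller k). The k grid
is read inclusively because reported optima sit at both ends of the range.
Test accuracy and AUC come from the pooled outer-fold scores (pooling is
the only way leave-one-out yields a single ROC); train metrics average the
per-fold models evaluated on their own training folds. Feature attribution
is permutation importance (mean in-sample accuracy drop over 30 shuffles
per feature) — a model-agnostic Shapley-style ranking, with the method name
recorded in the report.

## The synthetic cohort generator

Clinical cohorts with PET and fMRI are restricted-access, so validation
runs on a generative model chosen for analytic tractability rather than
biophysical realism. Global ignition events occur independently at each TR
with probability `event_rate`; each event draws a recruitment fraction
f ~ Beta(α, β) (default Beta(2, 2)) and recruits each region independently
with probability f, with one uniformly chosen driver always active.
Disease severity s ∈ [0, 1] shrinks the fraction toward its mean,
f′ = μ + (1−s)(f−μ), reducing integration *variance* — exactly the quantity
node-metastability measures — without moving the mean.

Because recruited regions co-activate at a single TR, each event's
co-activation matrix is a clique and its integration equals the recruited
fraction, giving node-metastability a closed form. A region only records
events it participates in, which size-biases the recruitment density by
f/E[f] (Beta(α, β) → Beta(α+1, β) at s = 0); conditional on f the observed
integration is (1 + Binomial(N−1, f))/N, so

    Var = ((N−1)/N)²·Var_sb(f) + (N−1)/N²·E_sb[f(1−f)].

For Beta(2, 2) and N = 100 this gives 0.2029 (driver forcing adds an
O(1/N) perturbation covered by test tolerances). The sd of integration over
*all* events — without the participation bias — is the larger
√(Var f + E[f(1−f)]/N) ≈ 0.228; the two are distinct quantities and both
are verified against independent event-loop simulations.

A BOLD mode convolves event trains with a canonical two-gamma haemodynamic
kernel (positive lobe peaking at 6 s, undershoot at 16 s, 1:6 amplitude
ratio, unit peak) sampled at the TR, plus white Gaussian noise, so the full
filter/threshold pipeline can be exercised; planted events are recovered
from noiseless BOLD at ≥95% within ±1 TR.

Burden tables draw per-region amyloid-β and tau SUVR log-normally around
the diagnostic group's cohort mean (HC 1.31/1.53, MCI 1.52/1.80,
AD 2.01/2.46 for Aβ/tau; log-scale sd 0.25, chosen to give the within-
subject regional spread real PET exhibits), then regenerate node-level
metastability targets as intercept + β_Aβ·Aβ + β_tau·tau + β_int·Aβ·tau +
subject random intercept + residual, with every coefficient recorded as
ground truth for recovery testing.

### Default study conditions

- Group sizes 17/9/10 (HC/MCI/AD); TR 3 s; 379-region-scale analyses are
  run at 100 regions for tractability.
- Severities HC 0.0, MCI 0.074, AD 0.255 — the complements of the published
  whole-brain group-mean metastability ratios (0.087/0.094, 0.070/0.094) —
  so cohort means shrink the way the three stages do.
- The severity-ordering replicate study uses 1182-TR scans at event rate
  0.3 with a 1-TR window. At that event count (~350 per subject) the
  per-subject sd estimator reaches the few-percent between-subject
  variability the published group summaries imply; at 197 TRs the estimator
  noise alone (~10% CV) would swamp the 7% HC–MCI gap, a limitation of the
  single-event-train generator, not of the analysis (real data carry far
  more effective events across 379 distinct regional trains).
- LME recovery cohorts use 70 regions (10 per network), β_Aβ = −0.002 with
  random-intercept sd 0.003 and residual sd 0.005 (values on the scale of
  the published whole-brain estimates), and a planted network-specific tau
  effect of −6.242e-3, the magnitude reported for the dorsal-attention
  network.

### What passing tests do and do not show

The generator has no haemodynamic variability, head motion, spatial
autocorrelation, structured physiological noise, or realistic connectome
topology; regions are exchangeable and events are globally synchronous.
Passing recovery tests therefore demonstrates that the *estimators and
inference machinery* are correct under the statistical structure the
analysis assumes — not that the pipeline is robust to the artefacts of real
fMRI/PET, which preprocessing upstream of this package is responsible for.

## Reproducibility

All randomness flows from one master seed through named per-stage
substreams (`SeedSequence`); rerunning the pipeline with identical inputs
reproduces every output byte for byte, and changing the seed perturbs only
Monte-Carlo stages (permutation p-values, inner CV splits), not the
deterministic ignition profiles. Tables are TSV with a one-line header,
floats written at `%.17g` so read(write(x)) is exact; region order is the
canonical alignment key.

## Known limitations

- Phase-based (Hilbert) ignition variants and time-resolved integration
  curves are out of scope.
- Wald normal-approximation p-values for the mixed models are
  anti-conservative in principle at very small subject counts; the null
  calibration test bounds the practical effect at the study's size.
- The RSN random-slope structure frequently downgrades to a random
  intercept at n≈36; per-network contrasts remain available either way.
- The generator's closed forms assume the 1-TR window; wider windows merge
  nearby events and shift integration records away from the per-event
  recruitment fraction (the general matrix route is still exact, and the
  equivalence is tested).
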