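# Methods

## Forward model

The package models forced-oscillation respiratory input impedance as a
two-element fractional-order network,
`Z(jω) = FrL·(jω)^α + 1/(FrC·(jω)^β)`, evaluated on the principal branch
`(jω)^x = ω^x·e^{jxπ/2}` so that resistance and reactance have closed
forms. Angular frequency is `ω = 2πf` with `f` in Hz — the standard FOT
convention. Impedance is carried in cmH₂O·s/L throughout; `FrL` and
`FrC` take whatever units make their term an impedance (fractional
exponents preclude SI-clean units), and `α`, `β` are dimensionless.

Parameter domain: `FrL, FrC > 0`, `β ∈ [0, 1]` (constant-phase tissue
element), and `α ∈ (0, 1]`. The upper bound on `α` is a design choice:
reported values cluster around 0.5–0.7 and an exponent above 1 has no
physiologic reading for this element. `α` or `β` within 10⁻⁶ of zero is
treated as degenerate — the element collapses to a real constant, `H → 0`
and η is undefined — and is rejected explicitly (`DegenerateParameterError`)
rather than returned as ±Inf.

The tissue compartment is summarised by damping `G = cos(πβ/2)/FrC`,
elastance `H = sin(πβ/2)/FrC` and hysteresivity `η = G/H = cot(πβ/2)`.
Two identities are used as invariants everywhere: η depends on β only,
and `G² + H² = 1/FrC²`.

## Parameter estimation

`fit_spectrum` minimises the stacked residual
`[Zr_meas − Zr_model; Zx_meas − Zx_model]` (equal weight on both
components) with scipy's bounded trust-region reflective least squares
and an analytic Jacobian. Defaults: bounds `FrL, FrC ∈ [10⁻⁴, 10]`,
`α, β ∈ [10⁻⁶, 1]`; relative cost/step/gradient tolerances 10⁻¹⁰; at most
1000 residual evaluations per start. The cost surface can be multimodal,
so the fit restarts from a deterministic coarse lattice (two log-spaced
amplitudes per element crossed with exponent levels 0.4/0.8, eight starts)
plus one data-driven start that reads `FrL` off the highest-frequency
reactance and `FrC` off the lowest-frequency reactance with α = β = 0.6;
the lowest-MSEt solution wins. Fit quality is reported as
`MSEr`/`MSEx` — *mean* squared residual per component, so the metric is
grid-size independent — and `MSEt = √(MSEr + MSEx)`.

The default measurement grid is 4–32 Hz in 2-Hz steps (15 points), the
conventional adult FOT range; at least six frequencies are required for
a four-parameter fit. Noise-free spectra are recovered to ~10⁻¹⁵
relative error; under the default simulated noise the batch drivers use
a reduced two-start configuration (heuristic + lattice corners), which
the grid-search cross-check shows lands in the same basin as the full
multistart at a fraction of the cost.

## Synthetic cohorts

The generator emulates a three-group observational design: healthy
controls (n = 23) and two patient groups with normal (n = 21) and
abnormal (n = 24) spirometry, labels 0/1/1. Per-subject truth parameters
are drawn from independent truncated normals. Group means are anchored
so that the mean control subject sits on the control side of every
published single-parameter cutoff (FrL 0.137, β 0.623, η 0.599, G 14.098,
H 25.06) and the patient means on the patient side, with severity
increasing from the normal-exam to the abnormal-exam group:

| group        | FrL  | α    | FrC   | β    |
|--------------|------|------|-------|------|
| control      | 0.09 | 0.70 | 0.034 | 0.70 |
| normal exam  | 0.18 | 0.55 | 0.042 | 0.58 |
| abnormal exam| 0.28 | 0.50 | 0.048 | 0.50 |

Amplitude parameters get coefficients of variation of 15–18%. The
dimensionless exponents get tighter spreads — α ≈ 10% CV and β an
absolute sd of 0.045 in every group — because constant-phase exponents
have a narrow physiologic within-group range, and because the β→η→AUC
geometry demands it: with a β spread of 15% CV the control/patient
distributions would overlap so heavily (standardised separation ≈ 0.9)
that no analysis stage could reach the high-accuracy regime the cohort
is meant to exercise. These defaults are cutoff-consistent stand-ins,
**not** a reconstruction of any study's empirical distributions, which
were never published as numbers.

Spectra are produced by evaluating the model on the default grid and
adding independent Gaussian noise (sd 0.15 cmH₂O·s/L per component,
typical FOT scatter against impedance magnitudes of 2–5). Clinical
covariates are attached by a Gaussian copula: the anchor feature is
rank-transformed to Blom normal scores z, the covariate's latent value
is `r·z + √(1−r²)·ε`, mapped to a normal marginal and clipped at
physiologic limits (SpO₂ ≤ 100, percent-predicted > 5, Raw ≥ 0.2). The
five defaults reproduce the headline feature–exam correlations
(FrL↔FEF% −0.62, FrL↔DLCOa% −0.71, η↔final SpO₂ −0.57, β↔Pe% +0.50,
FrL↔Raw +0.60). Rank-based anchoring plus truncation attenuates the raw
Pearson correlation by a few hundredths; the realised mean at n = 68 is
within ±0.05 of target.

What the generator does *not* emulate: within-subject covariance between
the four parameters (draws are independent given the group), breathing
artifacts or non-Gaussian device noise, frequency-dependent noise
weights, and any covariate–covariate correlation beyond what the shared
anchors induce. Tests passing on these cohorts therefore demonstrate
correctness of the pipeline machinery and the qualitative group
geometry, not performance on real patients.

Generation is driven by one `numpy` Generator; the same spec and seed
regenerate a bit-identical cohort, including downstream CSV bytes.

## Statistical protocol

Group comparisons are gated per feature by Shapiro–Wilk in every group
(α = 0.05): all normal → one-way ANOVA with Tukey HSD pairwise p-values
vs control; otherwise Kruskal–Wallis with pairwise two-sided
Mann–Whitney U vs control, reported uncorrected. Stars follow
* p<0.05, ** p<0.01, *** p<0.001. A zero-variance group is degenerate
for Shapiro–Wilk and routes to the nonparametric branch; literally
identical pooled samples short-circuit to "no difference".

Correlations use Pearson when *both* variables pass Shapiro–Wilk and
Spearman otherwise, are classed as small/no (|R| ≤ 0.25), reasonable
(≤ 0.50), moderate-to-good (≤ 0.75) or very-good-to-excellent (> 0.75)
with boundary ties to the lower class, and are tested at the
modified-Bonferroni level 0.05 divided by the effective number of
independent correlations — two FOT variable families × four exam
families = 8, i.e. 0.00625, displayed as 0.0063 (half-away-from-zero to
four decimals).

## ROC conventions

AUC is the Mann–Whitney pair-counting probability with ties credited ½.
Orientation (is disease the high or the low side?) is chosen so the AUC
is ≥ 0.5 and reported in the criterion string ("> x" vs "<= x"); the
reversed-orientation AUC is recomputed by counting on negated scores
rather than as 1 − AUC so that a strictly decreasing transform of the
scores (β vs η) yields the bit-identical AUC. Cutoffs are placed at
observed score values only, maximising Youden J = Se + Sp − 1; J-ties
break toward the more specific threshold. Accuracy classes: low
(0.5–0.7], moderate (0.7–0.9], high (0.9–1.0], upper-inclusive; AUC ≥
0.75 counts as adequate for clinical use.

Correlated AUCs on the same subjects are compared with DeLong's
placement-value z-test (two-sided); each score is auto-oriented before
comparison, and a zero-variance difference (rank-identical scores)
reports Δ with p = 1.

Cross-validated single-parameter accuracy uses leave-one-out threshold
learning: each fold learns orientation and Youden cutoff on n−1
subjects and emits the held-out subject's signed distance to that
cutoff (patient side positive); the final ROC of those scores is
computed with the orientation *fixed* to "higher", since the signed
distance already encodes the disease direction — re-learning it from
the held-out scores would be leakage. Known limitation: because
removing a subject changes the training class counts, the learned
cutoff is weakly anti-correlated with the held-out label, and on
weak-signal data at n ≈ 40–70 the LOOCV AUC can exceed the plain AUC by
up to ~0.1 on a single cohort. It does not inflate on average, and in
the strong-signal regime the two estimates agree closely; the test
suite asserts exactly that.

Sample-size planning follows Hanley–McNeil: smallest equal group size n
such that `z_{α/2}·SE₀ + z_β·SE₁ ≤ A − A₀`, with the exponential-model
variance (Q₁ = A/(2−A), Q₂ = 2A²/(1+A)) evaluated under both hypotheses.
The two-sided type-I convention is used (the usual choice of ROC
sample-size calculators); for A = 0.75 vs 0.5 at 10%/10% errors it gives
21 per group. The one-sided variant would give 16; the convention is
deliberately documented because published roundings of "about 20" do not
pin it down.

## Classifier stage

Six families: linear SVM (C = 1), RBF SVM (C = 1, γ from the median
pairwise-distance heuristic on the training fold), AdaBoost with 50
depth-1 stumps, 1-nearest-neighbour, random forest (100 trees — AUC
estimates at these cohort sizes are stable well below that, and it
keeps the subset search economical), and a Parzen-window classifier
(shared-bandwidth Gaussian product kernels per class,
training-prevalence priors, bandwidth maximising the pooled
leave-one-out log-likelihood over a 12-point log grid from 0.05 to 3 on
standardised features).

Evaluation is leave-one-out: per fold, features are z-scored with
training-fold statistics only, the classifier trains on n−1 subjects,
and a continuous class-1 score is recorded for the held-out subject —
margins for the SVMs and AdaBoost, vote fraction for the forest,
posterior for Parzen, relative class distance d₀/(d₀+d₁) for 1-NN (a
continuous surrogate that agrees with the 1-NN decision). AUC comes
from the held-out scores on the fixed class-1 orientation; Se/Sp are
read at their Youden point. All stochastic kinds take an explicit seed,
making every table seed-reproducible. `loocv_evaluate` accepts a
separate `test_features` copy so fold hygiene (no held-out leakage into
scaling or training) can be audited directly.

The exhaustive search LOOCV-evaluates every nonempty subset of the
candidate features (127 subsets for the seven model features; a guard
rejects more than 12 candidates), enumerating by size then
lexicographic order and keeping the first maximum — so ties resolve to
the smallest, alphabetically-first subset. Cross-product expansion
appends all C(k,2) pairwise products as named columns (`a*b`).

## Problem sizes

The test suite and the acceptance script size their simulations to keep
a full run in the low minutes on one CPU: 100 noise-free round-trip
fits, 10 spectra against a 20⁴-point grid-search oracle, 50 cohorts for
the stochastic high-accuracy rate, 100 cohorts for correlation
recovery, 200 brute-force ROC instances, and the 127-subset search with
the kernel/instance classifiers. The ensemble kinds (AdaBoost, random
forest) are evaluated on all features in the scripted runs; their
subset search is available through the CLI when a longer run is
acceptable.

## Known limitations

- Single fractional-order topology: no Newtonian-resistance variant, no
  integer-order RIC/eRIC alternatives, no frequency-dependent G(ω), H(ω).
- No confidence intervals on fitted parameters (a bootstrap would be a
  natural extension).
- The synthetic cohorts are cutoff-consistent stand-ins; none of the
  published patient-data tables can be reproduced numerically from them.
- LOOCV threshold learning has the small-n coupling described above.
- Parzen bandwidth is shared across classes and dimensions; strongly
  anisotropic features rely on the per-fold standardisation to make that
  reasonable.
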