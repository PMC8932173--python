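# Methods

This note documents the models, conventions and numerical choices behind
`cervipose`, and what the synthetic-data pipeline does and does not
establish about real fluoroscopic data.

## Coordinate and sign conventions

All geometry lives in the sagittal plane in millimetres, x
anterior-positive, y cranial-positive. Pixel-space landmark files are
converted at read time with a caller-supplied mm-per-pixel scale; nothing
downstream sees pixels. A line's orientation is defined modulo 180° and
represented in (−90°, +90°]; the wrap `((a + 90) mod 180) − 90`, with the
−90° boundary mapped to +90°, fixes the representative. The signed joint
angle is orientation(lower) − orientation(upper), wrapped the same way; a
positive angle denotes extension (posterior closing). Physiological
intervertebral angles are far from the ±90° boundary, so the wrap only
matters as a contract, which is tested explicitly at the boundary.

## Midplane construction

For a four-corner vertebral body the midplane line joins the midpoint of
the two anterior corners to the midpoint of the two posterior corners
(Frobin's bisecting scheme); its orientation is the arctangent of the
midpoint-to-midpoint slope. The alternative — a fitted rectangle axis —
was deliberately not used: the midpoint-line slope is deterministic,
closed-form, and exactly equivariant under rigid motions, and it is
invariant to relabeling the superior/inferior corner within the anterior
or posterior pair (tested). C0 (occiput) and C1 (atlas) carry no
rectangular body; they enter as explicit two-point reference axes
(anterior point, posterior point of a conventional reference line), which
keeps the seven-joint output without inventing corner landmarks that do
not exist anatomically. The landmark file schema fixes the corner order
(AS, PS, PI, AI); the reader validates quadrilateral simplicity (via
shapely) instead of attempting to re-sort ambiguous input.

## Error definitions

Constant error is upright1 − upright2 within condition, unwrapped: the
inputs are already-wrapped physiological angles and reposition
differences are small by construction, so a second wrap could only
corrupt the sign convention. Absolute error is |CE|, enforced row-wise as
a table invariant. The pooled "average cervical joint" summaries are
computed over all subject × joint observations (not over per-joint
means): with balanced data the two pooled means coincide, but only the
observation-level SD is of the magnitude (≈2°) such studies report.
Counting convention: the study-size tally counts CE and AE separately at
each of the two upright recordings each error compares — four tallied
values per subject × joint × condition row, hence 1680 for a 30-subject
study.

## Statistical models

**RM-ANOVA.** Two within factors, Joint (7 levels) and Time (2 levels),
one observation per subject × cell. The univariate decomposition assigns
each effect its own error stratum: F(Time) = MS_Time / MS_Time×Subject
with df (1, S−1); F(Joint) and F(Joint×Time) use their respective
subject-interaction mean squares with df (6, 6(S−1)). Total SS equals the
sum of the seven component SS (tested to 1e−8 relative). Greenhouse–
Geisser ε is computed from the orthonormal-contrast covariance of the
relevant margin (time-averaged subject × joint matrix for Joint; the
between-time difference matrix for the interaction); ε for a 2-level
factor is 1. Following common practice with this software lineage, ε-
corrected df are *applied* only when Mauchly's test on the Joint factor
rejects at α = 0.05, but both uncorrected and corrected p are always
reported. Mauchly's W uses the orthonormal-contrast covariance and the
first-order chi-square approximation with df k(k−1)/2 − 1; the
second-order Box term (which pingouin adds) changes p only in the third
decimal and is omitted. With fewer subjects than joint levels the
contrast covariance is singular; the sphericity test is then reported as
undefined and the uncorrected p is used.

**Normality.** The Kolmogorov–Smirnov statistic is computed against a
normal with plug-in sample moments. Because plug-in estimation makes the
plain KS null anticonservative, the p-value comes from a seeded
Monte-Carlo Lilliefors null: 10,000 standard-normal samples of the same
n, each standardised by its own sample moments, with the add-one rank
estimator. The null is cached per (n, replicates, seed), so repeated
tests at one sample size cost one simulation. The test's size is
verified: under normal data the 5%-level rejection rate over 1000
replicates lies in [3%, 7%].

**Post hoc.** Paired t per joint (pain vs control across subjects) on AE,
Bonferroni-adjusted with family size m = 7 — one comparison per joint,
the natural family for following up a Joint × Time interaction. A joint
whose paired differences are all exactly zero is flagged and assigned
adjusted p = 1. CE is not post-hoc tested by default (signed errors are
expected null); the function accepts either kind.

**Reliability.** ICC(3,1): two-way mixed, consistency, single measures,
(MSR − MSE)/(MSR + (k−1)MSE) from the explicit two-way decomposition of
the image-joint × repetition matrix. The pooled intra-rater measurement
error is the mean ± SD of signed *successive* repetition differences
(rep r+1 − rep r) pooled over images and joints; successive (rather than
all-pairs) differencing is what makes a constant inter-repetition offset
appear as (offset, 0).

**Power.** Two-tailed paired t via the noncentral t distribution:
power(n) = P(|T| > t_crit) with T ~ nct(n−1, d_z√n), and the required
sample size is the smallest n reaching the target. At d_z = 0.7,
α = 0.05, power 0.9 this gives n = 24 (verified against an independent
brute-force power curve); published sample-size statements for comparable
designs sometimes quote larger n (e.g. 27) from unstated test-family
choices in G*Power, and no attempt is made to reconcile them — the
contract here is the noncentral-t computation.

## Synthetic study generator

The generator emulates the data structure of a two-condition
repositioning study: S subjects × {control, pain} × {upright1, upright2},
each image a complete C0–C7 landmark set.

* **Template.** Rectangular bodies 15 mm (depth) × 11 mm (height) for
  C2–C7, stacked 16 mm apart with a mild lordotic orientation profile;
  20 mm two-point axes for C0/C1. Dimensions are typical adult cervical
  scale; only orientations matter to the angles.
* **Posture variation.** Per subject, each level's neutral tilt is
  perturbed by N(0, 2°) (default), shared between conditions. This
  varies the baseline angles without touching the reposition errors,
  which are differences within condition.
* **Reposition kinematics.** For each condition, upright2 is upright1
  with each joint k rotated by δ_k ~ N(μ_ck, σ_ck), applied as a rigid
  rotation of all vertebrae above the joint (processed caudally to
  cranially about the current joint centre). Under this rigid-chain
  model the joint angles are independently and exactly controllable:
  the recovered CE at joint k equals δ_k to ≤1e−6° (round-trip tested),
  and a perturbation at one joint changes no other joint's angle.
  Configurations whose |μ| + 6σ reaches 45° are rejected as wrap-unsafe,
  and drawn perturbations are re-checked.
* **Marking noise.** Independent isotropic Gaussian noise (default SD
  0.1 mm) on every landmark coordinate of every image, emulating manual
  annotation. First-order propagation through the midpoint construction
  gives an angle-level repeat-difference SD of ≈0.7° at 0.1 mm — the
  same order as the few-tenths-of-a-degree intra-rater errors reported
  for careful manual marking — and the simulation matches that closed
  form within 10% (tested at 500 images).
* **Calibration defaults.** Per-joint CE means are flat at the pooled
  values (0.18° control, 0.23° pain). Control SDs are flat at 2.18°; the
  during-pain per-joint SD profile is shaped (1.5, 1.5, 1.7, 2.4, 3.2,
  2.4, 1.7 before normalisation) — elevated at C4/C5 and, attenuated, at
  its neighbours — then rescaled so the pooled SD is exactly 2.22°.
  The shape is an illustrative modelling choice: published studies of
  segment-level repositioning print only pooled summaries, so any
  per-joint decomposition is a choice, made once here. Note that the
  pooled AE implied by a normal CE distribution is its folded-normal
  mean (≈1.74° for N(0.18, 2.18)); generators calibrated on CE therefore
  cannot simultaneously match independently reported pooled AE values
  that are inconsistent with that mapping, and AE is checked against the
  folded-normal closed form, not against external AE figures.

**What the synthetic data does not show.** The generator produces exactly
normal, between-subject-independent perturbations, stationary marking
noise and distortion-free geometry. Passing tests demonstrate that the
pipeline's algebra and inference behave correctly under the model the
statistics assume — not that real fluoroscopic studies satisfy those
assumptions (out-of-plane distortion, rater drift, non-normal error
tails, and correlated joint perturbations are all real-data features the
model omits).

## Problem sizes and determinism

Parameter-recovery checks use 5000-subject cohorts (35,000 observations
per condition), acceptance tolerance 3 Monte-Carlo standard errors with
the SD's standard error taken from the empirical fourth moment.
Size-calibration checks use 1000 replicates of 30-subject studies run
through the full landmark pipeline. All randomness flows through
explicit `numpy.random.default_rng` seeds; identical seeds give
bit-identical studies, and the analysis itself is deterministic.
Hypothesis-based property tests run derandomised.

## Known limitations

* Strictly sagittal, 2-D: no out-of-plane correction or 3-D kinematics.
* Starts at landmark coordinates; no image processing or automatic
  landmark extraction.
* Only CE and AE are implemented — variable error (VE) and RMSE variants
  from the wider proprioception literature are out of scope.
* The two-point C0/C1 axes are a pragmatic accommodation; different
  choices of skull-base/atlas reference lines will shift those two
  joints' absolute angles (but not their reposition errors, which are
  within-image differences).
* No mixed-effects or multivariate alternatives to the univariate
  RM-ANOVA, and no non-parametric fallbacks.
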