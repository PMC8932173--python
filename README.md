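# cervipose

Landmark-based analysis of **cervical joint reposition errors** — a
fluoroscopic measure of neck proprioception — from vertebral corner
landmarks to within-subject inference, with a synthetic study generator
for fully reproducible end-to-end testing.

## The problem

Joint position sense of the neck is commonly quantified with a
repositioning task: a seated subject holds a neutral upright head posture
(*upright 1*), performs a full cervical flexion, and returns as precisely
as possible to the initial posture (*upright 2*). Sagittal fluoroscopic
images of both postures are annotated with vertebral landmarks, and the
angular difference between the two postures at each motion segment is the
**reposition error** of that joint. Treating the cervical spine as seven
joints (C0/C1 … C6/C7) rather than a single unit lets the error be
localised — for example around a painful segment.

`cervipose` implements the full computational pipeline of such a study,
for a two-condition within-subject design (e.g. before vs during
experimentally induced muscle pain):

1. **Geometry** — for each vertebra C2–C7, the four body corners
   (anterior-superior, posterior-superior, posterior-inferior,
   anterior-inferior) define the *midplane line*: the line through the
   midpoint of the anterior corners and the midpoint of the posterior
   corners (Frobin's bisecting scheme). C0 and C1, which have no
   rectangular body, are carried as two-point reference axes. The signed
   intervertebral angle of joint *k* is
   θ<sub>k</sub> = φ<sub>k+1</sub> − φ<sub>k</sub>, the orientation
   difference of the adjacent midplane lines, wrapped into (−90°, +90°].
2. **Errors** — per joint and condition, the **constant error**
   CE = θ<sup>(upright1)</sup> − θ<sup>(upright2)</sup> (signed, direction
   of under/overshoot) and the **absolute error** AE = |CE|. A complete
   study of S subjects yields an S × 7 × 2 long-format table.
3. **Statistics** — Lilliefors-corrected Kolmogorov–Smirnov normality
   (seeded Monte-Carlo null), Mauchly's sphericity test, two-way
   repeated-measures ANOVA (factors Joint × Time, each effect tested
   against its own subject-interaction stratum, Greenhouse–Geisser
   epsilon), per-joint paired-*t* post hoc with Bonferroni correction
   (m = 7), ICC(3,1) and pooled measurement error for intra-rater
   reliability, and paired-*t* sample-size/power via the noncentral *t*.
4. **Synthetic data** — a rigid-chain spine model in which a drawn
   perturbation δ<sub>k</sub> ~ N(μ, σ) at joint *k* rotates every
   vertebra above the joint, so the pipeline's recovered CE at joint *k*
   equals δ<sub>k</sub> exactly in the noise-free limit; optional
   isotropic landmark marking noise emulates manual annotation.

## Worked example

```bash
python examples/03_full_study_analysis.py
```

generates a 30-subject study (pooled CE calibrated to 0.18° ± 2.18° in
the control condition and 0.23° ± 2.22° during pain, with the during-pain
variance concentrated at C4/C5) and prints, among more:

```
Subjects: 30  images: 120  error rows: 420  tallied error values: 1680
Pooled CE (control): +0.12 deg +/- 2.27 deg
Pooled AE (control): +1.83 deg +/- 1.34 deg
Mauchly (Joint): W=0.363, chi2(20)=27.15, p=0.1311
RM-ANOVA CE Time: F(1,29)=0.379, p=0.5432 (GG eps=1.000, p_GG=0.5432)
RM-ANOVA AE Joint x Time: F(6,174)=2.432, p=0.0277 (GG eps=0.817, p_GG=0.0388)
Post hoc (AE, pain vs control, Bonferroni m=7):
  C4/C5: diff=+0.667 deg, t=1.718, p_adj=0.6755
```

420 rows are the 30 × 7 × 2 subject-joint-condition errors; the tally of
1680 counts CE and AE separately at each of the two upright recordings.
The Time and Joint × Time lines ask whether errors grew during pain and
whether the growth localises to specific joints; signed CE effects stay
null because under- and overshoot average out. The other example scripts
cover single-image geometry, error tables, and reliability/power.

A thin CLI wraps the same stages:

```bash
cervipose simulate --subjects 30 --seed 1 --out study.csv
cervipose report --landmarks study.csv --out report.json --text
```

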