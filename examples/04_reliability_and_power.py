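"""Intra-rater marking reliability and design power.

Repeats the marking of upright-position images three times with 0.1 mm
landmark noise, then reports the pooled measurement error (mean +/- SD of
successive repetition differences) and ICC(3,1) of the joint angles; finally
computes the paired-t sample size for a target effect.
"""

import numpy as np

import cervipose as cp

cfg = cp.calibrated_config(n_subjects=10, seed=6, marking_noise_sd_mm=0.0)
landmarks, _ = cp.generate_study(cfg)

cube = []
for i, (_, image) in enumerate(landmarks.groupby(["subject_id", "condition", "position"])):
    reps = cp.generate_marking_repeats(image, noise_sd_mm=0.1, repeats=3, seed=i)
    cube.append([cp.angle_table(rep).to_numpy()[0] for rep in reps])
cube = np.asarray(cube)  # (images, 3 repeats, 7 joints)

mean, sd = cp.intra_rater_error(cube)
icc = cp.marking_reliability(cube)
print(f"Intra-rater measurement error over {cube.shape[0]} images x 3 markings: "
      f"{mean:+.2f} +/- {sd:.2f} deg")
print(f"ICC(3,1) of repeated joint-angle measurements: {icc.icc:.3f} "
      f"(n={icc.n} image-joint targets, k={icc.k} occasions)")

req = cp.PowerRequest(effect_size=0.7, alpha=0.05, power=0.9)
n = cp.required_sample_size(req)
print(f"\nPaired t test, two-tailed, d_z={req.effect_size}, alpha={req.alpha}, "
      f"power {req.power}: minimum n = {n} subjects")
print("(With 0.1 mm marking noise the angle-level repeat error stays under a")
print("degree, and repeated markings remain highly reliable.)")
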