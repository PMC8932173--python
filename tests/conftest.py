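import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cervipose as cp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return cp.default_template()


@pytest.fixture(scope="session")
def small_study():
    """A 4-subject study with marking noise, plus its error table."""
    cfg = cp.calibrated_config(n_subjects=4, seed=11, marking_noise_sd_mm=0.05)
    df, meta = cp.generate_study(cfg)
    table = cp.build_error_table(cp.angle_table(df))
    return df, meta, table


@pytest.fixture(scope="session")
def calibrated_run():
    """Large seeded cohort calibrated to the pooled constant-error parameters.

    S = 5000 subjects, perturbations N(0.18, 2.18) deg per joint before pain
    and pooled-SD 2.22 deg (mean 0.23) during pain, no marking noise; used by
    the parameter-recovery and folded-normal consistency checks.
    """
    cfg = cp.calibrated_config(n_subjects=5000, seed=42, marking_noise_sd_mm=0.0)
    df, meta = cp.generate_study(cfg)
    table = cp.build_error_table(cp.angle_table(df))
    return cfg, meta, table


def make_image_from_tilts(template, tilts, image_id="img"):
    """Build a full C0..C7 image whose per-level orientations are `tilts`."""
    import cervipose.synthetic as syn

    pts = syn._pose_points(template, np.asarray(tilts, dtype=float)[None, :])
    landmarks = []
    for i, lvl in enumerate(cp.LEVELS):
        p = pts[i][0]
        if lvl in ("C0", "C1"):
            landmarks.append(cp.VertebraLandmarks.from_axis(lvl, tuple(p[0]), tuple(p[1])))
        else:
            landmarks.append(
                cp.VertebraLandmarks.from_corners(lvl, *(tuple(q) for q in p))
            )
    return landmarks
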