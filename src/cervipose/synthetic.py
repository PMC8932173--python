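"""Synthetic fluoroscopic-study generator.

Emits complete landmark-level studies with the statistical structure the
analysis assumes: S subjects x 2 conditions (control / pain) x 2 upright
positions, each image holding the landmark set of C0..C7.  For every
subject and condition, upright1 is a neutral template spine with small
per-subject posture variation; upright2 re-poses the spine by rotating, at
each joint k, the whole chain of vertebrae above the joint by a
perturbation drawn from a configurable per-joint normal distribution
(rigid-chain kinematics).  Under this model the constant error recovered
by the analysis pipeline at joint k equals the drawn perturbation exactly
(before marking noise), which makes every downstream stage testable
against known ground truth.

Independent isotropic Gaussian "marking noise" can be added to every
landmark coordinate to emulate the manual marking of fluoroscopic frames.
All randomness flows from a single recorded seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CONDITIONS, POSITIONS
from .geometry import (
    AXIS_ORDER,
    CORNER_ORDER,
    JOINTS,
    LEVELS,
    TWO_POINT_LEVELS,
    Point2D,
    VertebraLandmarks,
)

#: hard wrap-safety bound on joint perturbations, degrees
MAX_SAFE_PERTURBATION_DEG = 45.0


class ConfigError(ValueError):
    """Invalid or wrap-unsafe synthetic-study configuration."""


# ---------------------------------------------------------------------------
# spine template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpineTemplate:
    """Neutral upright spine used as the anatomical scaffold.

    C2..C7 are rectangular vertebral bodies (`body_depth_mm` anterior-posterior
    by `body_height_mm` cranio-caudal) centred on a vertical stack;
    C0 and C1 carry two-point reference axes of half-length
    `axis_half_length_mm`.  `orientations_deg` gives each level's neutral
    sagittal tilt (a mild lordotic profile); `centers_mm` the body centres.
    """

    orientations_deg: tuple[float, ...]
    centers_mm: tuple[tuple[float, float], ...]
    body_depth_mm: float = 15.0
    body_height_mm: float = 11.0
    axis_half_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if len(self.orientations_deg) != len(LEVELS) or len(self.centers_mm) != len(LEVELS):
            raise ConfigError("template needs one orientation and one centre per level C0..C7")

    def local_points(self, level: str) -> np.ndarray:
        """Landmark offsets from the body centre in the unrotated frame."""
        if level in TWO_POINT_LEVELS:
            h = self.axis_half_length_mm
            return np.array([[h, 0.0], [-h, 0.0]])  # ANT, POST
        dx, dy = self.body_depth_mm / 2.0, self.body_height_mm / 2.0
        return np.array([[dx, dy], [-dx, dy], [-dx, -dy], [dx, -dy]])  # AS PS PI AI

    def neutral_landmark_points(self) -> list[np.ndarray]:
        """Per-level landmark coordinates (mm) of the neutral pose."""
        out = []
        for i, lvl in enumerate(LEVELS):
            rot = _rotation_matrix(self.orientations_deg[i])
            out.append(np.asarray(self.centers_mm[i]) + self.local_points(lvl) @ rot.T)
        return out

    def landmarks(self, level: str) -> VertebraLandmarks:
        pts = self.neutral_landmark_points()[LEVELS.index(level)]
        if level in TWO_POINT_LEVELS:
            return VertebraLandmarks.from_axis(level, Point2D(*pts[0]), Point2D(*pts[1]))
        return VertebraLandmarks.from_corners(level, *(Point2D(*p) for p in pts))


def default_template() -> SpineTemplate:
    """Neutral cervical spine: ~15 x 11 mm bodies stacked 16 mm apart with mild lordosis."""
    orientations = (9.0, 6.0, 4.0, 2.5, 1.0, -0.5, -2.0, -3.5)
    centers = tuple((0.0, 16.0 * (len(LEVELS) - 1 - i)) for i in range(len(LEVELS)))
    return SpineTemplate(orientations_deg=orientations, centers_mm=centers)


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _scale_sd_profile(relative: Sequence[float], pooled_sd: float) -> tuple[float, ...]:
    """Rescale a per-joint SD shape so the pooled (mixture) SD equals `pooled_sd`.

    With equal per-joint means, the pooled variance over joints is the mean
    of the per-joint variances.
    """
    rel = np.asarray(relative, dtype=float)
    if rel.shape != (len(JOINTS),) or np.any(rel < 0):
        raise ConfigError("SD profile needs 7 non-negative entries")
    scale = pooled_sd / np.sqrt(np.mean(rel**2))
    return tuple(float(v) for v in rel * scale)


#: during-pain SD shape: elevated at the pain-level joint C4/C5 and, attenuated,
#: at its neighbours C3/C4 and C5/C6 (illustrative modelling choice; the shape
#: is normalized so the pooled SD matches the configured pooled value)
PAIN_SD_SHAPE: tuple[float, ...] = (1.5, 1.5, 1.7, 2.4, 3.2, 2.4, 1.7)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-generation parameters.

    `ce_mean_deg` / `ce_sd_deg` map each condition to 7 per-joint normal
    parameters (degrees) of the reposition perturbation; `marking_noise_sd_mm`
    is the isotropic per-coordinate landmark marking noise; `posture_sd_deg`
    the per-subject per-level neutral-tilt variation.  Defaults calibrate the
    pooled constant-error distribution to 0.18 +/- 2.18 deg before pain and
    0.23 +/- 2.22 deg during pain, with the during-pain variance concentrated
    around the C4/C5 pain level.
    """

    n_subjects: int = 30
    ce_mean_deg: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {"control": (0.18,) * 7, "pain": (0.23,) * 7}
    )
    ce_sd_deg: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "control": (2.18,) * 7,
            "pain": _scale_sd_profile(PAIN_SD_SHAPE, 2.22),
        }
    )
    marking_noise_sd_mm: float = 0.1
    posture_sd_deg: float = 2.0
    mm_per_pixel: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("need at least one subject")
        if self.marking_noise_sd_mm < 0 or self.posture_sd_deg < 0:
            raise ConfigError("noise SDs must be non-negative")
        for cond in CONDITIONS:
            mu = np.asarray(self.ce_mean_deg[cond], dtype=float)
            sd = np.asarray(self.ce_sd_deg[cond], dtype=float)
            if mu.shape != (len(JOINTS),) or sd.shape != (len(JOINTS),):
                raise ConfigError(f"{cond}: need 7 per-joint mean and SD values")
            if np.any(sd < 0):
                raise ConfigError(f"{cond}: negative perturbation SD")
            if np.any(np.abs(mu) + 6.0 * sd >= MAX_SAFE_PERTURBATION_DEG):
                raise ConfigError(
                    f"{cond}: perturbation distribution reaches the wrap-unsafe "
                    f"range (|angle| >= {MAX_SAFE_PERTURBATION_DEG} deg)"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ce_mean_deg"] = {c: list(v) for c, v in self.ce_mean_deg.items()}
        d["ce_sd_deg"] = {c: list(v) for c, v in self.ce_sd_deg.items()}
        return d


def calibrated_config(
    n_subjects: int = 30,
    seed: int = 0,
    marking_noise_sd_mm: float = 0.1,
    control_pooled: tuple[float, float] = (0.18, 2.18),
    pain_pooled: tuple[float, float] = (0.23, 2.22),
    pain_sd_shape: Sequence[float] = PAIN_SD_SHAPE,
) -> SyntheticConfig:
    """Config whose pooled CE distribution matches given per-condition (mean, SD)."""
    return SyntheticConfig(
        n_subjects=n_subjects,
        ce_mean_deg={"control": (control_pooled[0],) * 7, "pain": (pain_pooled[0],) * 7},
        ce_sd_deg={
            "control": (control_pooled[1],) * 7,
            "pain": _scale_sd_profile(pain_sd_shape, pain_pooled[1]),
        },
        marking_noise_sd_mm=marking_noise_sd_mm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _landmark_labels() -> list[tuple[str, str]]:
    labels = []
    for lvl in LEVELS:
        for lm in (AXIS_ORDER if lvl in TWO_POINT_LEVELS else CORNER_ORDER):
            labels.append((lvl, lm))
    return labels


_LABELS = _landmark_labels()            # 2*2 + 6*4 = 28 landmarks per image
_ROWS_PER_IMAGE = len(_LABELS)
_N_PTS = {lvl: (2 if lvl in TWO_POINT_LEVELS else 4) for lvl in LEVELS}


def _pose_points(template: SpineTemplate, tilt_deg: np.ndarray) -> list[np.ndarray]:
    """Per-level landmark arrays for S subjects: level i -> (S, n_pts_i, 2).

    Each vertebra is rotated about its own centre by the subject's per-level
    tilt (neutral orientation + posture offset).
    """
    s = tilt_deg.shape[0]
    out = []
    for i, lvl in enumerate(LEVELS):
        local = template.local_points(lvl)                       # (P, 2)
        a = np.deg2rad(tilt_deg[:, i])                           # (S,)
        c, sn = np.cos(a), np.sin(a)
        rot = np.empty((s, 2, 2))
        rot[:, 0, 0], rot[:, 0, 1] = c, -sn
        rot[:, 1, 0], rot[:, 1, 1] = sn, c
        pts = np.einsum("sij,pj->spi", rot, local) + np.asarray(template.centers_mm[i])
        out.append(pts)
    return out


def _apply_chain_rotations(points: list[np.ndarray], delta_deg: np.ndarray) -> list[np.ndarray]:
    """Rotate, for each joint k, all vertebrae above the joint by +delta[:, k].

    Processed caudally-to-cranially with the pivot at the current midpoint of
    the two adjacent vertebral centres, so the chain stays rigidly connected.
    Only orientations matter to the joint angles; the pivots keep the
    anatomy plausible.
    """
    pts = [p.copy() for p in points]
    s = delta_deg.shape[0]
    for k in range(len(JOINTS) - 1, -1, -1):       # joint k couples levels k (upper) and k+1
        a = np.deg2rad(delta_deg[:, k])
        c, sn = np.cos(a), np.sin(a)
        rot = np.empty((s, 2, 2))
        rot[:, 0, 0], rot[:, 0, 1] = c, -sn
        rot[:, 1, 0], rot[:, 1, 1] = sn, c
        pivot = (pts[k].mean(axis=1) + pts[k + 1].mean(axis=1)) / 2.0   # (S, 2)
        for i in range(k + 1):
            rel = pts[i] - pivot[:, None, :]
            pts[i] = np.einsum("sij,spj->spi", rot, rel) + pivot[:, None, :]
    return pts


def _frame_from_points(per_position: dict[tuple[str, str], list[np.ndarray]],
                       subject_ids: list[str]) -> pd.DataFrame:
    """Stack per-(condition, position) point arrays into the long landmark schema."""
    s = len(subject_ids)
    chunks = []
    for (cond, pos), pts in per_position.items():
        coords = np.concatenate([p.reshape(s, -1, 2) for p in pts], axis=1)  # (S, 28, 2)
        chunks.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subject_ids, _ROWS_PER_IMAGE),
                    "condition": cond,
                    "position": pos,
                    "level": np.tile([lvl for lvl, _ in _LABELS], s),
                    "landmark": np.tile([lm for _, lm in _LABELS], s),
                    "x_mm": coords[:, :, 0].ravel(),
                    "y_mm": coords[:, :, 1].ravel(),
                }
            )
        )
    df = pd.concat(chunks, ignore_index=True)
    return df.sort_values(["subject_id", "condition", "position"],
                          kind="stable", ignore_index=True)


def generate_study(
    config: SyntheticConfig, template: SpineTemplate | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate a complete synthetic study in the landmark CSV schema.

    Returns (landmark table, metadata).  The table holds S x 4 images (2
    conditions x 2 upright positions); metadata echoes the config and seed.
    Fully reproducible from the seed.
    """
    template = template or default_template()
    rng = np.random.default_rng(config.seed)
    s = config.n_subjects
    subject_ids = [f"S{i + 1:04d}" for i in range(s)]

    posture = rng.normal(0.0, config.posture_sd_deg, size=(s, len(LEVELS)))
    tilt = np.asarray(template.orientations_deg) + posture

    per_position: dict[tuple[str, str], list[np.ndarray]] = {}
    true_ce: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        mu = np.asarray(config.ce_mean_deg[cond], dtype=float)
        sd = np.asarray(config.ce_sd_deg[cond], dtype=float)
        delta = rng.normal(mu, sd, size=(s, len(JOINTS)))
        if np.any(np.abs(delta) >= MAX_SAFE_PERTURBATION_DEG):
            raise ConfigError("drawn perturbation exceeds the wrap-safe range (|angle| >= 45 deg)")
        upright1 = _pose_points(template, tilt)
        # CE = upright1 - upright2 angle; rotating the chain above joint k by
        # +delta_k lowers the recovered joint angle by delta_k, so CE = +delta_k.
        upright2 = _apply_chain_rotations(upright1, delta)
        per_position[(cond, "upright1")] = upright1
        per_position[(cond, "upright2")] = upright2
        true_ce[cond] = delta

    if config.marking_noise_sd_mm > 0:
        for key, pts in per_position.items():
            per_position[key] = [
                p + rng.normal(0.0, config.marking_noise_sd_mm, size=p.shape) for p in pts
            ]

    df = _frame_from_points(per_position, subject_ids)
    meta = {
        "generator": "cervipose.synthetic.generate_study",
        "config": config.to_dict(),
        "subject_ids": subject_ids,
        # ground-truth joint perturbations (the CE the pipeline should recover
        # before marking noise), per condition: S x 7 nested lists
        "true_ce_deg": {cond: delta.tolist() for cond, delta in true_ce.items()},
    }
    return df, meta


def generate_marking_repeats(
    image: pd.DataFrame, noise_sd_mm: float, repeats: int, seed: int
) -> list[pd.DataFrame]:
    """R independent noisy markings of one image's landmark rows.

    `image` is a landmark-schema frame for a single image; each repeat adds
    fresh isotropic Gaussian noise of SD `noise_sd_mm` to every coordinate.
    """
    if repeats < 2:
        raise ValueError("need at least 2 marking repetitions")
    if noise_sd_mm < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        rep = image.copy()
        rep[["x_mm", "y_mm"]] = rep[["x_mm", "y_mm"]].to_numpy() + rng.normal(
            0.0, noise_sd_mm, size=(len(rep), 2)
        )
        out.append(rep)
    return out
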