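"""Study input/output and the end-to-end analysis driver.

The on-disk landmark format is a long CSV with header columns
``subject_id, condition, position, level, landmark, x_mm, y_mm``; one image
is one (subject_id, condition, position) group holding the 28 landmarks of
C0..C7 (two axis points for C0/C1, four corners for C2..C7).  Pixel-space
files are converted with a caller-supplied mm-per-pixel scale at read time;
everything downstream works in millimetres.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import errors as err
from . import geometry as geom
from . import stats as st

log = logging.getLogger("cervipose")

SCHEMA_COLUMNS = ["subject_id", "condition", "position", "level", "landmark", "x_mm", "y_mm"]


class ValidationError(ValueError):
    """Landmark file violates the study schema."""


@dataclass
class StudyBundle:
    """Validated landmark records of a complete study, in millimetres."""

    landmarks: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_images(self) -> int:
        return len(self.landmarks.groupby(geom.IMAGE_KEY, sort=False))

    @property
    def subjects(self) -> list:
        return sorted(self.landmarks["subject_id"].unique())


def _validate_frame(df: pd.DataFrame) -> None:
    if list(df.columns) != SCHEMA_COLUMNS:
        raise ValidationError(f"header must be exactly {SCHEMA_COLUMNS}, got {list(df.columns)}")
    bad_level = ~df["level"].isin(geom.LEVELS)
    if bad_level.any():
        rows = (df.index[bad_level] + 2).tolist()[:5]
        raise ValidationError(f"unknown level labels at file rows {rows}")
    valid_lm = set(geom.CORNER_ORDER) | set(geom.AXIS_ORDER)
    bad_lm = ~df["landmark"].isin(valid_lm)
    if bad_lm.any():
        rows = (df.index[bad_lm] + 2).tolist()[:5]
        raise ValidationError(f"unknown landmark labels at file rows {rows}")
    coords = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        rows = (df.index[~np.isfinite(coords).all(axis=1)] + 2).tolist()[:5]
        raise ValidationError(f"non-finite coordinates at file rows {rows}")
    dup = df.duplicated(subset=["subject_id", "condition", "position", "level", "landmark"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValidationError(f"duplicate landmark rows at file rows {rows}")
    # per-image completeness and per-vertebra geometric validity
    for key, image in df.groupby(geom.IMAGE_KEY, sort=False):
        subject, condition, position = key
        levels = set(image["level"])
        if levels != set(geom.LEVELS):
            missing = sorted(set(geom.LEVELS) - levels)
            raise ValidationError(
                f"subject {subject!r} condition {condition!r} position {position!r}: "
                f"missing level(s) {missing}"
            )
        try:
            geom.landmarks_to_objects(image)
        except (geom.SchemaError, geom.GeometryError) as exc:
            raise ValidationError(
                f"subject {subject!r} condition {condition!r} position {position!r}: {exc}"
            ) from exc
    counts = df.groupby("subject_id")[["condition"]].nunique()
    images = df.groupby("subject_id").apply(
        lambda g: g.groupby(["condition", "position"]).ngroups, include_groups=False
    )
    incomplete = images[images != 4]
    if len(incomplete):
        raise ValidationError(
            f"subjects without the full 2 conditions x 2 positions: {list(incomplete.index)}"
        )
    del counts


def read_landmarks(path, mm_per_pixel: float = 1.0) -> StudyBundle:
    """Read and validate a landmark CSV; scale coordinates to millimetres."""
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _validate_frame(df)
    df = df.copy()
    df[["x_mm", "y_mm"]] = df[["x_mm", "y_mm"]].astype(float) * mm_per_pixel
    log.info("read %d landmark rows (%d images) from %s", len(df),
             df.groupby(geom.IMAGE_KEY).ngroups, path)
    return StudyBundle(landmarks=df, meta={"source": str(path), "mm_per_pixel": mm_per_pixel})


def write_landmarks(landmarks: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a landmark table as CSV; optional sidecar metadata JSON at <path>.meta.json."""
    path = Path(path)
    landmarks.to_csv(path, index=False)
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2))
    log.info("wrote %d landmark rows to %s", len(landmarks), path)


def bundle_from_frame(df: pd.DataFrame, meta: dict | None = None) -> StudyBundle:
    """Wrap an in-memory landmark frame (already in mm) as a validated bundle."""
    _validate_frame(df.reset_index(drop=True))
    return StudyBundle(landmarks=df.reset_index(drop=True), meta=meta or {})


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_full_analysis(bundle: StudyBundle, ks_seed: int = 834_721) -> dict:
    """Run geometry -> errors -> stats on a study and return the combined report.

    Stages: per-image joint angles; CE/AE error table with pooled and
    per-joint summaries; K-S normality per condition and error kind;
    Mauchly sphericity of the Joint factor; RM-ANOVA of CE and of AE;
    Bonferroni post hoc on AE.  Deterministic given the input and seeds.
    """
    angles = geom.angle_table(bundle.landmarks)
    log.info("geometry: %d images -> %d joint angles", len(angles), angles.size)

    table = err.build_error_table(angles)
    log.info("errors: %d rows (%d tallied error values)", table.n_rows, table.n_error_values)

    pooled = {
        cond: {kind: dict(zip(("mean", "sd"), err.pooled_summary(table, cond, kind)))
               for kind in err.ERROR_KINDS}
        for cond in err.CONDITIONS
    }
    normality = {
        cond: {
            kind: _asdict(st.ks_normality(
                table.data.loc[table.data["condition"] == cond, err._KIND_COL[kind]].to_numpy(),
                seed=ks_seed,
            ))
            for kind in err.ERROR_KINDS
        }
        for cond in err.CONDITIONS
    }
    anovas = {kind: st.rm_anova(table, kind) for kind in err.ERROR_KINDS}
    posthoc = st.bonferroni_posthoc(table, "AE")
    log.info("stats: RM-ANOVA on CE and AE; %d post hoc comparisons", posthoc.m)

    report = {
        "provenance": dict(bundle.meta),
        "counts": {
            "subjects": table.n_subjects,
            "images": bundle.n_images,
            "error_rows": table.n_rows,
            "error_values": table.n_error_values,
        },
        "pooled": pooled,
        "per_joint": err.per_joint_summary(table).to_dict(orient="records"),
        "normality": normality,
        "mauchly_joint": _asdict(anovas["AE"].mauchly_joint),
        "rm_anova": {kind: _asdict(res.effects) for kind, res in anovas.items()},
        "rm_anova_selected_p": {
            kind: {name: res.selected_p(name) for name in res.effects}
            for kind, res in anovas.items()
        },
        "posthoc_AE": _asdict(list(posthoc.rows)),
        "error_table": table.data.to_dict(orient="list"),
    }
    return _asdict(report)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def format_report(report: dict) -> str:
    """Human-readable summary of a full-analysis report."""
    lines = []
    c = report["counts"]
    lines.append(f"Subjects: {c['subjects']}  images: {c['images']}  "
                 f"error rows: {c['error_rows']}  tallied error values: {c['error_values']}")
    for cond, kinds in report["pooled"].items():
        for kind, ms in kinds.items():
            lines.append(f"Pooled {kind} ({cond}): {ms['mean']:+.2f} deg +/- {ms['sd']:.2f} deg")
    mau = report["mauchly_joint"]
    lines.append(f"Mauchly (Joint): W={mau['w']:.3f}, chi2({mau['df']})={mau['chi2']:.2f}, p={mau['p']:.4f}")
    for kind, effects in report["rm_anova"].items():
        for name, e in effects.items():
            lines.append(
                f"RM-ANOVA {kind} {name}: F({e['df']},{e['df_error']})={e['f']:.3f}, "
                f"p={e['p']:.4f} (GG eps={e['gg_epsilon']:.3f}, p_GG={e['p_gg']:.4f})"
            )
    lines.append("Post hoc (AE, pain vs control, Bonferroni m=7):")
    for row in report["posthoc_AE"]:
        lines.append(
            f"  {row['joint']}: diff={row['mean_diff']:+.3f} deg, t={row['t']:.3f}, "
            f"p_adj={row['p_bonferroni']:.4f}"
        )
    return "\n".join(lines)
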