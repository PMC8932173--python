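"""Reposition errors: constant error (CE) and absolute error (AE).

The repositioning task records each subject twice per condition in the
upright posture (upright1 = initial target, upright2 = re-assumed position
after full cervical flexion).  For each joint the *constant error* is the
signed angle difference upright1 - upright2 — direction of under/overshoot —
and the *absolute error* is its magnitude.  Both are tabulated per
subject x joint x condition, giving S*7*2 rows and, counting CE and AE
separately, S*7*2*2 error values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import IMAGE_KEY, JOINTS, SchemaError

CONDITIONS: tuple[str, ...] = ("control", "pain")
POSITIONS: tuple[str, ...] = ("upright1", "upright2")
ERROR_KINDS: tuple[str, ...] = ("CE", "AE")
_KIND_COL = {"CE": "ce_deg", "AE": "ae_deg"}


class CompletenessError(ValueError):
    """A subject is missing an image or a joint angle."""


def constant_error(angle_upright1: float, angle_upright2: float) -> float:
    """Signed reposition error in degrees: upright1 - upright2.

    No wrapping is applied: inputs are pre-wrapped physiological joint
    angles and reposition differences are small by construction.
    """
    if not (math.isfinite(angle_upright1) and math.isfinite(angle_upright2)):
        raise ValueError("joint angles must be finite")
    return angle_upright1 - angle_upright2


def absolute_error(ce: float) -> float:
    """Unsigned reposition error |CE| in degrees."""
    if not math.isfinite(ce):
        raise ValueError("constant error must be finite")
    return abs(ce)


@dataclass(frozen=True)
class RepositionErrorTable:
    """Long-format table of reposition errors.

    `data` has columns subject_id, condition, joint, ce_deg, ae_deg and one
    row per subject x joint x condition, sorted by (subject, condition,
    joint).  The study's error-value tally counts CE and AE separately,
    i.e. 2x the row count.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        expected_cols = ["subject_id", "condition", "joint", "ce_deg", "ae_deg"]
        if list(df.columns) != expected_cols:
            raise SchemaError(f"error table must have columns {expected_cols}")
        keys = df[["subject_id", "condition", "joint"]]
        if keys.duplicated().any():
            raise SchemaError("duplicate (subject, condition, joint) rows in error table")
        n_subj = df["subject_id"].nunique()
        if len(df) != n_subj * len(JOINTS) * len(CONDITIONS):
            raise CompletenessError(
                f"expected {n_subj}x{len(JOINTS)}x{len(CONDITIONS)} rows, got {len(df)}"
            )
        if not np.allclose(df["ae_deg"], df["ce_deg"].abs()):
            raise ValueError("ae_deg must equal |ce_deg| for every row")

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_error_values(self) -> int:
        """Tallied joint reposition error values (study-size bookkeeping).

        Counts, for every subject x joint x condition, the constant and the
        absolute error separately at each of the two upright-position
        recordings the error compares: 4 tallied values per table row
        (1680 for a complete 30-subject study).
        """
        return 4 * len(self.data)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def build_error_table(angles: pd.DataFrame) -> RepositionErrorTable:
    """Build the CE/AE table from a per-image joint-angle table.

    `angles` is indexed by (subject_id, condition, position) with the seven
    joint columns (the output of :func:`cervipose.geometry.angle_table`).
    Every subject must contribute the full 2 conditions x 2 positions; CE is
    computed within condition as upright1 - upright2.
    """
    if list(angles.columns) != list(JOINTS):
        raise SchemaError(f"angle table must have the joint columns {list(JOINTS)}")
    if angles.index.names != IMAGE_KEY:
        raise SchemaError(f"angle table must be indexed by {IMAGE_KEY}")
    if not np.isfinite(angles.to_numpy()).all():
        raise CompletenessError("angle table contains missing joint angles")

    subjects = sorted(angles.index.get_level_values("subject_id").unique())
    expected = pd.MultiIndex.from_product(
        [subjects, CONDITIONS], names=["subject_id", "condition"]
    )
    by_position = {}
    for position in POSITIONS:
        try:
            sub = angles.xs(position, level="position")
        except KeyError:
            raise CompletenessError(f"no {position} images in the angle table") from None
        missing = expected.difference(sub.index)
        if len(missing):
            subject, condition = missing[0]
            raise CompletenessError(
                f"subject {subject!r}, condition {condition!r}: missing {position} image"
            )
        by_position[position] = sub.reindex(expected)

    ce_wide = by_position["upright1"] - by_position["upright2"]
    long = ce_wide.stack()
    long.index.names = ["subject_id", "condition", "joint"]
    table = long.rename("ce_deg").reset_index()
    table["ae_deg"] = table["ce_deg"].abs()
    table["joint"] = pd.Categorical(table["joint"], categories=JOINTS, ordered=True)
    table = table.sort_values(["subject_id", "condition", "joint"], ignore_index=True)
    table["joint"] = table["joint"].astype(str)
    return RepositionErrorTable(data=table[["subject_id", "condition", "joint", "ce_deg", "ae_deg"]])


def angle_sets_to_table(angle_sets: Mapping[tuple, "JointAngleSet"]) -> pd.DataFrame:
    """Arrange per-image JointAngleSet objects into the angle-table layout.

    Keys are (subject_id, condition, position) tuples; the result feeds
    :func:`build_error_table`.
    """
    from .geometry import JointAngleSet  # local import to avoid cycle at module load

    rows = {key: [aset.angles[j] for j in JOINTS] for key, aset in angle_sets.items()}
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=IMAGE_KEY)
    return pd.DataFrame(list(rows.values()), index=idx, columns=list(JOINTS)).sort_index()


def pooled_summary(table: RepositionErrorTable, condition: str, error_kind: str) -> tuple[float, float]:
    """Pooled mean and sample SD over all subject-joint observations.

    Pools the S x 7 values of one condition and error kind (observation-level
    SD, not SD of per-joint means).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if error_kind not in ERROR_KINDS:
        raise ValueError(f"error_kind must be one of {ERROR_KINDS}")
    values = table.data.loc[table.data["condition"] == condition, _KIND_COL[error_kind]]
    if values.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    return float(values.mean()), float(values.std(ddof=1))


def per_joint_summary(table: RepositionErrorTable) -> pd.DataFrame:
    """Mean and sample SD of CE and AE per condition x joint."""
    g = table.data.groupby(["condition", "joint"], sort=False)[["ce_deg", "ae_deg"]]
    out = g.agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ Normal(mu, sigma): the expected AE implied by a CE distribution."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return abs(mu)
    return sigma * math.sqrt(2.0 / math.pi) * math.exp(-(mu**2) / (2 * sigma**2)) + mu * (
        1.0 - 2.0 * norm.cdf(-mu / sigma)
    )
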