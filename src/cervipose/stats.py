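"""Within-subject inference for reposition-error studies.

Implements, from first principles, the inferential toolkit of a two-factor
fully within-subject design (factors: Joint with 7 levels, Time with 2
levels; one observation per subject x cell):

* Lilliefors-corrected Kolmogorov-Smirnov normality test (Monte-Carlo null
  with plug-in moments, cached per sample size),
* Mauchly's sphericity test with the chi-square approximation,
* two-way repeated-measures ANOVA with Greenhouse-Geisser epsilon,
* per-joint paired-t post hoc tests with Bonferroni correction,
* ICC(3,1) — two-way mixed model, consistency, single measures — for
  intra-rater marking reliability,
* pooled intra-rater measurement error from repeated markings,
* paired-t sample-size computation via the noncentral t distribution.

Mean squares, F ratios and epsilons follow the standard univariate
within-subject decomposition: each within effect is tested against its own
subject-interaction stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps

from .errors import CONDITIONS, RepositionErrorTable, _KIND_COL
from .geometry import JOINTS

__all__ = [
    "NormalityResult",
    "MauchlyResult",
    "RmAnovaEffect",
    "RmAnovaResult",
    "PosthocRow",
    "PosthocResult",
    "IccResult",
    "PowerRequest",
    "ks_normality",
    "mauchly",
    "gg_epsilon",
    "rm_anova",
    "bonferroni_posthoc",
    "icc_3_1",
    "intra_rater_error",
    "required_sample_size",
]


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityResult:
    d: float
    p: float
    n: int


def _ks_statistic(z_sorted: np.ndarray) -> np.ndarray:
    """Two-sided KS distance of rows of sorted standardised samples vs N(0,1)."""
    n = z_sorted.shape[-1]
    u = sps.norm.cdf(z_sorted)
    i = np.arange(1, n + 1)
    d_plus = (i / n - u).max(axis=-1)
    d_minus = (u - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_sims: int, seed: int) -> np.ndarray:
    """Simulated null distribution of the KS statistic with estimated moments.

    Standard-normal samples of size n are standardised by their own sample
    mean and SD (ddof=1) — the same plug-in used on the data — so the null
    accounts for parameter estimation (Lilliefors correction).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n))
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    return np.sort(_ks_statistic(z))


def ks_normality(values, n_sims: int = 10_000, seed: int = 834_721) -> NormalityResult:
    """One-sample KS test of normality with estimated mean and SD.

    The p-value comes from a seeded Monte-Carlo Lilliefors null (plug-in
    parameter estimation replicated under the null), cached per sample
    size, using the add-one estimator (D ranked among n_sims simulated
    statistics).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D sample with n >= 4")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance sample: normality test is degenerate")
    z = np.sort((x - x.mean()) / sd)
    d = float(_ks_statistic(z))
    null = _lilliefors_null(x.size, n_sims, seed)
    p = (np.count_nonzero(null >= d) + 1) / (n_sims + 1)
    return NormalityResult(d=d, p=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MauchlyResult:
    w: float
    chi2: float
    df: int
    p: float


def _contrast_cov(wide: np.ndarray) -> np.ndarray:
    """Covariance of the data projected onto orthonormal contrasts of the levels."""
    k = wide.shape[1]
    c = linalg.helmert(k)  # (k-1, k), orthonormal rows orthogonal to 1
    s = np.cov(wide, rowvar=False, ddof=1)
    return c @ s @ c.T


def mauchly(wide) -> MauchlyResult:
    """Mauchly's test of sphericity for an n x k subjects-by-levels matrix.

    W = det(S_c) / (tr(S_c)/(k-1))^(k-1) with S_c the orthonormal-contrast
    covariance; the chi-square approximation has df = k(k-1)/2 - 1.  With
    k = 2 sphericity is vacuous (single contrast): W = 1, p = 1.
    """
    x = np.asarray(wide, dtype=float)
    if x.ndim != 2:
        raise ValueError("need an n x k matrix")
    n, k = x.shape
    if k < 2 or n <= k:
        raise ValueError("need n > k >= 2 subjects x levels")
    if k == 2:
        return MauchlyResult(w=1.0, chi2=0.0, df=0, p=1.0)
    s_c = _contrast_cov(x)
    det = linalg.det(s_c)
    if not np.isfinite(det) or det <= 0.0:
        raise ValueError("singular contrast covariance: Mauchly's W undefined")
    w = det / (np.trace(s_c) / (k - 1)) ** (k - 1)
    d = k - 1
    f_corr = 1.0 - (2 * d**2 + d + 2) / (6 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * math.log(w)
    df = k * (k - 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return MauchlyResult(w=float(w), chi2=float(chi2), df=df, p=p)


def gg_epsilon(wide) -> float:
    """Greenhouse-Geisser epsilon of an n x k within-factor matrix (1/(k-1) <= eps <= 1)."""
    x = np.asarray(wide, dtype=float)
    k = x.shape[1]
    if k == 2:
        return 1.0
    s_c = _contrast_cov(x)
    denom = (k - 1) * np.trace(s_c @ s_c)
    if denom == 0.0:  # no within-factor variance at all
        return 1.0
    eps = np.trace(s_c) ** 2 / denom
    return float(min(eps, 1.0))


# ---------------------------------------------------------------------------
# RM-ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmAnovaEffect:
    """One within-subject effect with its own error stratum."""

    name: str
    ss: float
    df: int
    ms: float
    ss_error: float
    df_error: int
    ms_error: float
    f: float
    p: float
    gg_epsilon: float
    p_gg: float


@dataclass(frozen=True)
class RmAnovaResult:
    effects: dict[str, RmAnovaEffect]
    ss_subject: float
    ss_total: float
    mauchly_joint: MauchlyResult
    sphericity_alpha: float = 0.05

    def selected_p(self, effect: str) -> float:
        """GG-corrected p if the Joint-factor sphericity test rejects, else uncorrected."""
        e = self.effects[effect]
        if e.gg_epsilon < 1.0 and self.mauchly_joint.p < self.sphericity_alpha:
            return e.p_gg
        return e.p


def _anova_from_cube(y: np.ndarray) -> tuple[dict[str, RmAnovaEffect], float, float, MauchlyResult]:
    """Within-subject two-way decomposition of y[subject, factorA, factorB]."""
    s, j, t = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_j = y.mean(axis=(0, 2))
    m_t = y.mean(axis=(0, 1))
    m_sj = y.mean(axis=2)
    m_st = y.mean(axis=1)
    m_jt = y.mean(axis=0)

    ss_subject = j * t * np.sum((m_s - grand) ** 2)
    ss_j = s * t * np.sum((m_j - grand) ** 2)
    ss_t = s * j * np.sum((m_t - grand) ** 2)
    ss_js = t * np.sum((m_sj - m_s[:, None] - m_j[None, :] + grand) ** 2)
    ss_ts = j * np.sum((m_st - m_s[:, None] - m_t[None, :] + grand) ** 2)
    ss_jt = s * np.sum((m_jt - m_j[:, None] - m_t[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_jts = ss_total - (ss_subject + ss_j + ss_t + ss_js + ss_ts + ss_jt)
    ss_jts = max(ss_jts, 0.0)

    # GG epsilons from the effect-specific contrast matrices
    eps_j = gg_epsilon(m_sj)                      # Joint: subjects x joints, time-averaged
    eps_t = 1.0                                   # two-level factor
    eps_jt = gg_epsilon(y[:, :, 0] - y[:, :, 1]) if t == 2 else gg_epsilon(
        (y * linalg.helmert(t)[0][None, None, :]).sum(axis=2)
    )

    def effect(name, ss, df, ss_err, df_err, eps) -> RmAnovaEffect:
        ms = ss / df
        ms_err = ss_err / df_err
        f = ms / ms_err if ms_err > 0 else math.inf
        p = float(sps.f.sf(f, df, df_err)) if math.isfinite(f) else 0.0
        p_gg = float(sps.f.sf(f, df * eps, df_err * eps)) if math.isfinite(f) else 0.0
        return RmAnovaEffect(name, float(ss), df, float(ms), float(ss_err), df_err,
                             float(ms_err), float(f), p, float(eps), p_gg)

    effects = {
        "Joint": effect("Joint", ss_j, j - 1, ss_js, (j - 1) * (s - 1), eps_j),
        "Time": effect("Time", ss_t, t - 1, ss_ts, (t - 1) * (s - 1), eps_t),
        "Joint x Time": effect("Joint x Time", ss_jt, (j - 1) * (t - 1),
                               ss_jts, (j - 1) * (t - 1) * (s - 1), eps_jt),
    }
    try:
        mau = mauchly(m_sj)
    except ValueError:
        # too few subjects (n <= k) or singular covariance: sphericity cannot
        # be tested; selected_p then falls back to the uncorrected p
        mau = MauchlyResult(w=math.nan, chi2=math.nan, df=j * (j - 1) // 2 - 1, p=math.nan)
    return effects, float(ss_subject), float(ss_total), mau


def rm_anova(table: RepositionErrorTable, error_kind: str) -> RmAnovaResult:
    """Two-way RM-ANOVA of CE or AE with within factors Joint (7) and Time (2).

    Each effect is tested against its subject-interaction mean square:
    F(Time) = MS_Time / MS_TimexSubject, etc.  Greenhouse-Geisser epsilon
    is reported for the multi-level effects; Mauchly's test is applied to
    the Joint factor (the only within factor with more than 2 levels), and
    `selected_p` applies the corrected df only when that test rejects.
    """
    if error_kind not in _KIND_COL:
        raise ValueError(f"error_kind must be one of {tuple(_KIND_COL)}")
    df = table.data
    wide = df.pivot_table(index="subject_id", columns=["joint", "condition"],
                          values=_KIND_COL[error_kind], aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("missing cells: RM-ANOVA requires a complete balanced table")
    s = len(wide)
    y = np.empty((s, len(JOINTS), len(CONDITIONS)))
    for a, joint in enumerate(JOINTS):
        for b, cond in enumerate(CONDITIONS):
            y[:, a, b] = wide[(joint, cond)].to_numpy()
    effects, ss_subject, ss_total, mau = _anova_from_cube(y)
    return RmAnovaResult(effects=effects, ss_subject=ss_subject, ss_total=ss_total,
                         mauchly_joint=mau)


# ---------------------------------------------------------------------------
# post hoc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosthocRow:
    joint: str
    mean_diff: float     # pain - control
    t: float
    p_raw: float
    p_bonferroni: float
    zero_variance: bool = False


@dataclass(frozen=True)
class PosthocResult:
    rows: tuple[PosthocRow, ...]
    m: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def bonferroni_posthoc(table: RepositionErrorTable, error_kind: str = "AE") -> PosthocResult:
    """Per-joint paired t tests (pain vs control) with Bonferroni correction.

    The family is the 7 joints (m = 7); adjusted p = min(1, 7 * raw p).
    A joint whose paired differences are all exactly zero is degenerate:
    t = 0, adjusted p = 1, flagged.
    """
    if table.n_subjects < 3:
        raise ValueError("post hoc needs at least 3 subjects")
    col = _KIND_COL[error_kind]
    df = table.data
    m = len(JOINTS)
    rows: list[PosthocRow] = []
    for joint in JOINTS:
        sub = df[df["joint"] == joint].pivot_table(index="subject_id", columns="condition",
                                                   values=col, aggfunc="first")
        diff = (sub["pain"] - sub["control"]).to_numpy()
        if np.all(diff == 0.0):
            rows.append(PosthocRow(joint, 0.0, 0.0, 1.0, 1.0, zero_variance=True))
            continue
        t, p = sps.ttest_rel(sub["pain"], sub["control"])
        rows.append(PosthocRow(joint, float(diff.mean()), float(t), float(p),
                               float(min(1.0, m * p))))
    return PosthocResult(rows=tuple(rows), m=m)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IccResult:
    icc: float
    ms_targets: float
    ms_error: float
    k: int
    n: int


def icc_3_1(ratings) -> IccResult:
    """ICC(3,1): two-way mixed model, consistency, single measures.

    `ratings` is an n-targets x k-occasions matrix.  ICC = (MSR - MSE) /
    (MSR + (k-1) MSE) with MSR the between-target and MSE the residual mean
    square of the two-way (target x occasion) decomposition.  Consistency:
    invariant to adding a constant to an occasion's column.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 targets and k >= 2 occasions")
    if np.isnan(x).any():
        raise ValueError("ratings must be complete")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    if ss_rows == 0.0:
        raise ValueError("zero between-target variance: ICC undefined")
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse)
    return IccResult(icc=float(icc), ms_targets=float(msr), ms_error=float(mse), k=k, n=n)


def intra_rater_error(repeat_angles) -> tuple[float, float]:
    """Pooled intra-rater measurement error from repeated markings.

    `repeat_angles` is an array of shape (n_images, R, n_joints) of joint
    angles obtained by marking each image R >= 2 times.  Signed successive
    repetition differences (rep r+1 - rep r) are pooled over images and
    joints; returns their mean and sample SD in degrees.
    """
    a = np.asarray(repeat_angles, dtype=float)
    if a.ndim == 2:  # single image
        a = a[None, :, :]
    if a.ndim != 3 or a.shape[1] < 2:
        raise ValueError("need (n_images, R>=2, n_joints) repeated angle measurements")
    diffs = np.diff(a, axis=1).ravel()
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return float(diffs.mean()), sd


def marking_reliability(repeat_angles) -> IccResult:
    """ICC(3,1) of repeated markings: targets are image x joint angles, occasions are repeats."""
    a = np.asarray(repeat_angles, dtype=float)
    if a.ndim == 2:
        a = a[None, :, :]
    n_img, r, n_joint = a.shape
    ratings = a.transpose(0, 2, 1).reshape(n_img * n_joint, r)
    return icc_3_1(ratings)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerRequest:
    """Design request for a two-tailed paired t test: Cohen's d_z, alpha, target power."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must be in (0, 1)")
        if self.effect_size <= 0.0:
            raise ValueError("effect size d_z must be positive")


def paired_t_power(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Power of the two-tailed paired t test at sample size n, via the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect_size * math.sqrt(n)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def required_sample_size(req: PowerRequest, n_max: int = 100_000) -> int:
    """Smallest n whose two-tailed paired t test reaches the requested power."""
    for n in range(2, n_max + 1):
        if paired_t_power(n, req.effect_size, req.alpha) >= req.power:
            return n
    raise ValueError(f"power {req.power} unreachable with n <= {n_max} at d_z={req.effect_size}")
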