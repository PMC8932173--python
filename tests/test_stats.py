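"""Inferential suite: normality, sphericity, RM-ANOVA, post hoc, ICC, power.

Where an established implementation exists (pingouin), it serves as an
independent oracle; the package's own from-first-principles results are
checked against it and against hand-computed decompositions.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cervipose as cp
from cervipose.stats import gg_epsilon, paired_t_power

warnings.filterwarnings("ignore", module="pingouin")
pg = pytest.importorskip("pingouin")


def table_from_cube(y: np.ndarray) -> cp.RepositionErrorTable:
    """Wrap y[subject, joint, time] as an error table (values injected as CE)."""
    s, j, t = y.shape
    assert j == 7 and t == 2
    rows = []
    for si in range(s):
        for ti, cond in enumerate(("control", "pain")):
            for ji, joint in enumerate(cp.JOINTS):
                rows.append((f"s{si:03d}", cond, joint, y[si, ji, ti], abs(y[si, ji, ti])))
    df = pd.DataFrame(rows, columns=["subject_id", "condition", "joint", "ce_deg", "ae_deg"])
    return cp.RepositionErrorTable(data=df)


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

class TestKsNormality:
    def test_normal_quantile_grid_not_rejected(self):
        x = sps.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        res = cp.ks_normality(x)
        assert res.n == 100
        assert res.p > 0.05

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(1).exponential(size=200)
        assert cp.ks_normality(x).p < 0.05

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            cp.ks_normality([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            cp.ks_normality([1.0, 2.0, 3.0])

    def test_plain_ks_would_be_anticonservative(self):
        """The Lilliefors null is stochastically smaller than the plain KS null:
        the Monte-Carlo p is below the uncorrected kstest p on fitted data."""
        x = np.random.default_rng(7).normal(3.0, 2.0, size=80)
        res = cp.ks_normality(x)
        plain_p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue
        assert res.p < plain_p


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

class TestMauchly:
    def test_two_levels_is_vacuous(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        res = cp.mauchly(x)
        assert res.w == 1.0 and res.p == 1.0 and res.df == 0

    def test_matches_pingouin(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 4)) @ np.diag([1.0, 1.5, 0.7, 2.0])
        res = cp.mauchly(x)
        spher = pg.sphericity(pd.DataFrame(x))
        assert res.w == pytest.approx(float(spher.W), rel=1e-8)
        assert res.chi2 == pytest.approx(float(spher.chi2), rel=1e-8)
        assert res.df == int(spher.dof)
        # pingouin adds a second-order term to the Box chi-square approximation;
        # the first-order p agrees closely but not exactly
        assert res.p == pytest.approx(float(spher.pval), rel=0.05)

    def test_compound_symmetry_rarely_rejected(self):
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            subj = rng.normal(0, 1.0, size=(30, 1))
            x = subj + rng.normal(0, 1.0, size=(30, 7))
            if cp.mauchly(x).p < 0.05:
                hits += 1
        assert hits / reps <= 0.10

    def test_heterogeneous_variances_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 7)) * np.array([0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 5.0])
        assert cp.mauchly(x).p < 0.01

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(25, 7))
        eps = gg_epsilon(x)
        assert 1.0 / 6.0 <= eps <= 1.0
        assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0


# ---------------------------------------------------------------------------
# RM-ANOVA
# ---------------------------------------------------------------------------

# 3 subjects x 2 joints x 2 times; decomposition computed by hand from
# marginal means (cell-mean algebra) before the implementation was written.
TOY = np.array(
    [
        [[3.0, 5.0], [4.0, 9.0]],
        [[2.0, 4.0], [6.0, 8.0]],
        [[1.0, 6.0], [5.0, 10.0]],
    ]
)
TOY_EXPECTED = {
    "ss_subject": 0.5,
    "Joint": (36.75, 1, 1.5, 2, 49.0),
    "Time": (36.75, 1, 4.5, 2, 49.0 / 3),
    "Joint x Time": (0.75, 1, 1.5, 2, 1.0),
    "ss_total": 82.25,
}


class TestRmAnova:
    def test_toy_table_matches_hand_decomposition(self):
        from cervipose.stats import _anova_from_cube

        effects, ss_subject, ss_total, _ = _anova_from_cube(TOY)
        assert ss_subject == pytest.approx(TOY_EXPECTED["ss_subject"], abs=1e-8)
        assert ss_total == pytest.approx(TOY_EXPECTED["ss_total"], abs=1e-8)
        for name in ("Joint", "Time", "Joint x Time"):
            ss, df, ss_err, df_err, f = TOY_EXPECTED[name]
            e = effects[name]
            assert e.ss == pytest.approx(ss, abs=1e-8)
            assert e.df == df
            assert e.ss_error == pytest.approx(ss_err, abs=1e-8)
            assert e.df_error == df_err
            assert e.f == pytest.approx(f, abs=1e-8)

    def test_subject_means_only_data_has_zero_effect_ss(self):
        rng = np.random.default_rng(2)
        y = np.broadcast_to(rng.normal(size=(12, 1, 1)), (12, 7, 2)).copy()
        res = cp.rm_anova(table_from_cube(y), "CE")
        for e in res.effects.values():
            assert e.ss == pytest.approx(0.0, abs=1e-10)

    def test_degrees_of_freedom_for_thirty_subjects(self):
        rng = np.random.default_rng(6)
        res = cp.rm_anova(table_from_cube(rng.normal(size=(30, 7, 2))), "CE")
        assert (res.effects["Time"].df, res.effects["Time"].df_error) == (1, 29)
        assert (res.effects["Joint"].df, res.effects["Joint"].df_error) == (6, 174)
        assert (res.effects["Joint x Time"].df, res.effects["Joint x Time"].df_error) == (6, 174)

    def test_time_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(15, 7, 2)) + np.array([0.0, 0.4])
        res = cp.rm_anova(table_from_cube(y), "CE")
        d1 = y[:, :, 0].mean(axis=1)
        d2 = y[:, :, 1].mean(axis=1)
        t, p = sps.ttest_rel(d1, d2)
        assert res.effects["Time"].f == pytest.approx(t**2, rel=1e-10)
        assert res.effects["Time"].p == pytest.approx(p, rel=1e-10)

    def test_total_ss_is_sum_of_components(self):
        from cervipose.stats import _anova_from_cube

        rng = np.random.default_rng(10)
        y = rng.normal(size=(20, 7, 2))
        effects, ss_subject, ss_total, _ = _anova_from_cube(y)
        parts = ss_subject + sum(e.ss + e.ss_error for e in effects.values())
        assert parts == pytest.approx(ss_total, rel=1e-8)

    def test_matches_pingouin_two_way(self):
        rng = np.random.default_rng(21)
        y = rng.normal(size=(18, 7, 2)) + np.linspace(0, 1, 7)[None, :, None]
        table = table_from_cube(y)
        res = cp.rm_anova(table, "CE")
        long = table.data.rename(columns={"condition": "time"})
        aov = pg.rm_anova(
            data=long, dv="ce_deg", within=["joint", "time"], subject="subject_id", detailed=True
        ).set_index("Source")
        for ours, theirs in [("Joint", "joint"), ("Time", "time"), ("Joint x Time", "joint * time")]:
            e = res.effects[ours]
            assert e.ss == pytest.approx(float(aov.loc[theirs, "SS"]), rel=1e-8)
            assert e.f == pytest.approx(float(aov.loc[theirs, "F"]), rel=1e-8)
            assert e.p == pytest.approx(float(aov.loc[theirs, "p_unc"]), rel=1e-8)
        assert res.effects["Joint"].gg_epsilon == pytest.approx(
            float(aov.loc["joint", "eps"]), rel=1e-8
        )

    def test_missing_cells_rejected(self):
        rng = np.random.default_rng(11)
        table = table_from_cube(rng.normal(size=(6, 7, 2)))
        broken = cp.RepositionErrorTable.__new__(cp.RepositionErrorTable)
        object.__setattr__(broken, "data", table.data.iloc[:-1])
        with pytest.raises(ValueError):
            cp.rm_anova(broken, "CE")


# ---------------------------------------------------------------------------
# post hoc
# ---------------------------------------------------------------------------

class TestPosthoc:
    def test_adjustment_is_sevenfold_and_capped(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=(12, 7, 2))
        y[:, :, 1] += 0.8  # make some raw p small, some large
        res = cp.bonferroni_posthoc(table_from_cube(np.abs(y)), "AE")
        assert res.m == 7 and len(res.rows) == 7
        for row in res.rows:
            assert row.p_bonferroni == pytest.approx(min(1.0, 7 * row.p_raw))
            assert row.p_bonferroni >= row.p_raw

    def test_raw_p_0005_becomes_0035(self):
        assert min(1.0, 7 * 0.005) == pytest.approx(0.035)
        # and the same arithmetic emerges from the implementation:
        rng = np.random.default_rng(14)
        y = rng.normal(size=(10, 7, 2))
        res = cp.bonferroni_posthoc(table_from_cube(np.abs(y) + 0.1), "AE")
        for row in res.rows:
            if not row.zero_variance:
                assert row.p_bonferroni == pytest.approx(min(1.0, res.m * row.p_raw))

    def test_all_zero_differences_flagged(self):
        y = np.abs(np.random.default_rng(15).normal(size=(8, 7, 1)))
        res = cp.bonferroni_posthoc(table_from_cube(np.repeat(y, 2, axis=2)), "AE")
        for row in res.rows:
            assert row.zero_variance and row.p_bonferroni == 1.0

    def test_effect_injected_at_pain_joint_is_most_significant(self):
        cfg = cp.SyntheticConfig(
            n_subjects=30,
            ce_mean_deg={"control": (0.0,) * 7, "pain": (0.0,) * 7},
            ce_sd_deg={"control": (1.5,) * 7, "pain": (1.5, 1.5, 1.5, 1.5, 4.5, 1.5, 1.5)},
            marking_noise_sd_mm=0.0,
            seed=77,
        )
        df, _ = cp.generate_study(cfg)
        table = cp.build_error_table(cp.angle_table(df))
        res = cp.bonferroni_posthoc(table, "AE")
        best = min(res.rows, key=lambda r: r.p_raw)
        assert best.joint == "C4/C5"

    def test_too_few_subjects_rejected(self):
        y = np.random.default_rng(16).normal(size=(2, 7, 2))
        with pytest.raises(ValueError):
            cp.bonferroni_posthoc(table_from_cube(y), "AE")


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

class TestIcc:
    TOY = np.array([[9.0, 8.0, 10.0], [5.0, 6.0, 4.0], [2.0, 3.0, 3.0]])

    def test_identical_occasions_give_one(self):
        x = np.tile(np.array([[1.0], [5.0], [9.0]]), (1, 3))
        assert cp.icc_3_1(x).icc == pytest.approx(1.0)

    def test_toy_matrix_matches_bruteforce_decomposition(self):
        # brute-force variance components computed by explicit two-way mean
        # decomposition (frozen): MSR=30.7778, MSE=1.1111, ICC=89/99
        res = cp.icc_3_1(self.TOY)
        assert res.icc == pytest.approx(89.0 / 99.0, abs=1e-10)
        assert res.ms_targets == pytest.approx(30.77777777777778, abs=1e-8)
        assert res.ms_error == pytest.approx(1.111111111111112, abs=1e-8)

    def test_matches_pingouin_icc3(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(12, 4)) + rng.normal(0, 2, size=(12, 1))
        res = cp.icc_3_1(x)
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(12), 4),
                "rater": np.tile(np.arange(4), 12),
                "score": x.ravel(),
            }
        )
        icc = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
        expected = float(icc.set_index("Type").loc["ICC(C,1)", "ICC"])
        assert res.icc == pytest.approx(expected, rel=1e-8)

    def test_consistency_invariant_to_occasion_shift(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(10, 3)) + rng.normal(0, 2, size=(10, 1))
        shifted = x.copy()
        shifted[:, 1] += 5.0
        assert cp.icc_3_1(shifted).icc == pytest.approx(cp.icc_3_1(x).icc, rel=1e-10)

    def test_occasion_noise_dominating_targets_gives_near_zero(self):
        rng = np.random.default_rng(19)
        targets = rng.normal(0, 0.05, size=(30, 1))
        x = targets + rng.normal(0, 5.0, size=(30, 4))
        assert cp.icc_3_1(x).icc < 0.2

    def test_zero_target_variance_rejected(self):
        with pytest.raises(ValueError):
            cp.icc_3_1(np.array([[1.0, 2.0], [1.0, 2.0]]))


class TestIntraRaterError:
    def test_identical_repetitions(self):
        a = np.tile(np.random.default_rng(20).normal(size=(5, 1, 7)), (1, 3, 1))
        mean, sd = cp.intra_rater_error(a)
        assert mean == pytest.approx(0.0) and sd == pytest.approx(0.0)

    def test_constant_offset_between_repetitions(self):
        base = np.random.default_rng(22).normal(size=(4, 1, 7))
        reps = np.concatenate([base, base + 0.2, base + 0.4], axis=1)
        mean, sd = cp.intra_rater_error(reps)
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_single_repetition_rejected(self):
        with pytest.raises(ValueError):
            cp.intra_rater_error(np.zeros((3, 1, 7)))


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def _oracle_n(d, alpha=0.05, power=0.9):
    """Independent brute-force power curve via the noncentral-t CDF."""
    import math

    n = 2
    while True:
        df = n - 1
        nc = d * math.sqrt(n)
        tc = sps.t.ppf(1 - alpha / 2, df)
        pw = sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc)
        if pw >= power:
            return n
        n += 1


class TestSampleSize:
    def test_large_effect_needs_five_subjects(self):
        assert cp.required_sample_size(cp.PowerRequest(effect_size=2.0)) == 5

    def test_agrees_with_noncentral_t_oracle(self):
        # d_z=0.7, alpha=0.05, power=0.9: the two-tailed paired-t computation
        # gives n=24; the contract is agreement with the independent oracle.
        for d in (0.3, 0.5, 0.7, 1.0):
            assert cp.required_sample_size(cp.PowerRequest(effect_size=d)) == _oracle_n(d)
        assert cp.required_sample_size(cp.PowerRequest(effect_size=0.7)) == 24

    def test_power_monotone_in_n(self):
        powers = [paired_t_power(n, 0.5) for n in range(3, 60)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError):
            cp.PowerRequest(effect_size=0.7, power=0.0)
        with pytest.raises(ValueError):
            cp.PowerRequest(effect_size=-1.0)
        with pytest.raises(ValueError):
            cp.PowerRequest(effect_size=0.7, alpha=1.5)
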