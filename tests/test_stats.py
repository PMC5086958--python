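"""Shared statistics: paired t, FDR, sign-flip permutations, rm-ANOVA."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from tmseeg.stats import (bonferroni_posthoc, fdr_bh, paired_t, rm_anova,
                          sign_flip_null)

# ---------------------------------------------------------------------------
# paired t


def test_paired_t_hand_computed_example():
    t, df, p = paired_t([1, 2, 4], [2, 3, 3])
    assert t == pytest.approx(-0.5)
    assert df == 2


def test_paired_t_constant_shift_raises_zero_variance():
    with pytest.raises(ZeroDivisionError):
        paired_t([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])


def test_paired_t_antisymmetric_differences_give_zero():
    t, _, p = paired_t([-1.0, 1.0, 0.0], [0.0, 0.0, 0.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_paired_t_null_p_values_are_uniform():
    """Kolmogorov-Smirnov check on many simulated null datasets."""
    rng = np.random.default_rng(0)
    n_sets, n = 10_000, 8
    d = rng.normal(size=(n_sets, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    assert sps.kstest(p, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# FDR


def _bh_oracle(p, q):
    """Brute-force BH: largest k with p_(k) <= k q / m, reject the k smallest."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    best = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best = k
    mask = np.zeros(m, bool)
    mask[order[:best]] = True
    return mask


def test_fdr_bh_worked_example():
    assert fdr_bh([0.01, 0.02, 0.03, 0.5], 0.05).tolist() == [True, True, True, False]


@pytest.mark.parametrize("p,q,expected", [
    ([1.0, 1.0, 1.0], 0.05, [False, False, False]),
    ([0.04], 0.05, [True]),
])
def test_fdr_bh_edge_cases(p, q, expected):
    assert fdr_bh(p, q).tolist() == expected


@given(st.integers(0, 2 ** 31 - 1))
def test_fdr_bh_matches_brute_force_and_is_monotone_in_q(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(1, 40)) ** rng.uniform(0.5, 3)
    for q in (0.01, 0.05, 0.2):
        np.testing.assert_array_equal(fdr_bh(p, q), _bh_oracle(p, q))
    assert not (fdr_bh(p, 0.01) & ~fdr_bh(p, 0.2)).any()  # monotone in q


def test_fdr_controls_false_discovery_rate_empirically():
    """Empirical FDR <= q within binomial error on mixed null/alt p-values."""
    rng = np.random.default_rng(1)
    q, reps, m, m0 = 0.1, 2000, 40, 30
    fdp = np.empty(reps)
    for r in range(reps):
        p_null = rng.uniform(size=m0)
        p_alt = rng.beta(0.1, 10, size=m - m0)
        p = np.concatenate([p_null, p_alt])
        mask = fdr_bh(p, q)
        n_rej = mask.sum()
        fdp[r] = mask[:m0].sum() / n_rej if n_rej else 0.0
    margin = 3 * fdp.std(ddof=1) / np.sqrt(reps)
    assert fdp.mean() <= q + margin


# ---------------------------------------------------------------------------
# sign-flip permutations


def test_exhaustive_sign_flip_p_equals_brute_force_enumeration():
    rng = np.random.default_rng(3)
    d = rng.normal(0.4, 1.0, size=5)
    stat = lambda x: float(np.mean(x))  # noqa: E731
    res = sign_flip_null(d, stat, n_perm=3000, seed=0)
    assert res.scheme == "exhaustive"
    assert res.n_permutations == 32
    null = [stat(d * np.array(s)) for s in itertools.product((1, -1), repeat=5)]
    expected = (1 + sum(v >= stat(d) for v in null)) / (1 + 32)
    assert res.monte_carlo_p == pytest.approx(expected)


def test_all_zero_differences_give_p_one():
    res = sign_flip_null(np.zeros(6), lambda x: float(np.mean(x)), seed=0)
    assert res.monte_carlo_p == pytest.approx(1.0)


def test_sign_flip_null_is_seed_reproducible_and_never_zero():
    d = np.random.default_rng(4).normal(size=20)  # 2^20 > n_perm: random scheme
    r1 = sign_flip_null(d, lambda x: float(np.mean(x)), n_perm=500, seed=9)
    r2 = sign_flip_null(d, lambda x: float(np.mean(x)), n_perm=500, seed=9)
    np.testing.assert_array_equal(r1.null, r2.null)
    assert r1.scheme == "sign_flip"
    assert r1.monte_carlo_p >= 1.0 / 501


def test_exhaustive_sign_flip_type_one_error_is_exact():
    """Exchangeable-exact: null rejection rate <= nominal alpha."""
    rng = np.random.default_rng(5)
    alpha, reps, n = 0.1, 400, 6
    rejections = 0
    for r in range(reps):
        d = rng.standard_normal(n)
        res = sign_flip_null(d, lambda x: float(np.mean(x)), n_perm=10_000,
                             seed=r, tail="abs")
        rejections += res.monte_carlo_p <= alpha
    rate = rejections / reps
    assert rate <= alpha + 2.5 * np.sqrt(alpha * (1 - alpha) / reps)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _anova_oracle_two_way(cube):
    """Textbook cell-means SS decomposition for a subjects x A x B cube."""
    n, a, b = cube.shape
    m = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)
    ss = {}
    ss["A"] = n * b * np.sum((m_a - m) ** 2)
    ss["B"] = n * a * np.sum((m_b - m) ** 2)
    ss["A_err"] = b * np.sum((m_sa - m_a[None, :] - m_s[:, None] + m) ** 2)
    ss["B_err"] = a * np.sum((m_sb - m_b[None, :] - m_s[:, None] + m) ** 2)
    ss["AB"] = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    resid = (cube - m_ab[None] - m_sa[:, :, None] - m_sb[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - m)
    ss["AB_err"] = np.sum(resid ** 2)
    return ss


def _long_table(cube):
    n, a, b = cube.shape
    rows = [(f"s{s}", f"a{i}", f"b{j}", cube[s, i, j])
            for s in range(n) for i in range(a) for j in range(b)]
    return pd.DataFrame(rows, columns=["subject", "A", "B", "value"])


def test_rm_anova_single_two_level_factor_equals_paired_t_squared(rng):
    n = 9
    x = rng.normal(size=(n, 2))
    rows = [(f"s{i}", f"c{j}", x[i, j]) for i in range(n) for j in range(2)]
    df = pd.DataFrame(rows, columns=["subject", "A", "value"])
    res = rm_anova(df, within=["A"]).effects["A"]
    t, tdf, p = paired_t(x[:, 0], x[:, 1])
    assert res.F == pytest.approx(t ** 2)
    assert (res.df_num, res.df_den) == (1, n - 1)
    assert res.p == pytest.approx(p)
    # sphericity is vacuous at two levels
    assert res.epsilon_gg == 1.0 and not res.corrected


def test_rm_anova_sums_of_squares_match_cell_means_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(5, 9))
        a = int(rng.integers(2, 4))
        b = int(rng.integers(2, 5))
        cube = rng.normal(size=(n, a, b)) + rng.normal(size=(1, a, b))
        res = rm_anova(_long_table(cube), within=["A", "B"])
        oracle = _anova_oracle_two_way(cube)
        assert res.effects["A"].ss_effect == pytest.approx(oracle["A"], abs=1e-8)
        assert res.effects["A"].ss_error == pytest.approx(oracle["A_err"], abs=1e-8)
        assert res.effects["B"].ss_effect == pytest.approx(oracle["B"], abs=1e-8)
        assert res.effects["B"].ss_error == pytest.approx(oracle["B_err"], abs=1e-8)
        assert res.effects["A x B"].ss_effect == pytest.approx(oracle["AB"], abs=1e-8)
        assert res.effects["A x B"].ss_error == pytest.approx(oracle["AB_err"], abs=1e-8)


def test_rm_anova_three_way_matches_statsmodels(rng):
    from statsmodels.stats.anova import AnovaRM

    rows = []
    for s in range(8):
        for i in range(2):
            for j in range(2):
                for k in range(4):
                    rows.append((f"s{s}", f"a{i}", f"b{j}", f"c{k}",
                                 rng.normal() + 0.3 * i * k))
    df = pd.DataFrame(rows, columns=["subject", "A", "B", "D", "value"])
    ours = rm_anova(df, within=["A", "B", "D"])
    ref = AnovaRM(df, "value", "subject", within=["A", "B", "D"]).fit().anova_table
    for effect, ref_name in [("A", "A"), ("B", "B"), ("D", "D"),
                             ("A x B", "A:B"), ("A x D", "A:D"),
                             ("B x D", "B:D"), ("A x B x D", "A:B:D")]:
        assert ours.effects[effect].F == pytest.approx(
            ref.loc[ref_name, "F Value"]), effect
        assert ours.effects[effect].df_num == ref.loc[ref_name, "Num DF"]
        assert ours.effects[effect].df_den == ref.loc[ref_name, "Den DF"]


def test_rm_anova_gg_and_mauchly_match_pingouin(rng):
    import pingouin as pg

    rows = [(f"s{s}", f"b{j}", rng.normal() + 0.4 * j + rng.normal() * j)
            for s in range(10) for j in range(4)]
    df = pd.DataFrame(rows, columns=["subject", "B", "value"])
    ours = rm_anova(df, within=["B"]).effects["B"]
    wide = df.pivot(index="subject", columns="B", values="value")
    spher = pg.sphericity(wide)
    assert ours.mauchly_w == pytest.approx(spher.W)
    assert ours.mauchly_p == pytest.approx(spher.pval)
    assert ours.epsilon_gg == pytest.approx(pg.epsilon(wide, correction="gg"))


def test_rm_anova_partial_eta_squared_definition(rng):
    cube = rng.normal(size=(7, 3, 2))
    res = rm_anova(_long_table(cube), within=["A", "B"])
    for e in res.effects.values():
        assert 0.0 <= e.partial_eta_sq <= 1.0
        assert e.partial_eta_sq == pytest.approx(
            e.ss_effect / (e.ss_effect + e.ss_error))


def test_rm_anova_rejects_unbalanced_tables(rng):
    cube = rng.normal(size=(5, 2, 2))
    df = _long_table(cube).iloc[:-1]
    with pytest.raises(ValueError, match="balanced"):
        rm_anova(df, within=["A", "B"])


def test_bonferroni_posthoc_scales_p_by_number_of_pairs(rng):
    x = rng.normal(size=(8, 3)) + np.array([0.0, 0.0, 1.5])
    rows = [(f"s{i}", f"c{j}", x[i, j]) for i in range(8) for j in range(3)]
    df = pd.DataFrame(rows, columns=["subject", "cond", "value"])
    ph = bonferroni_posthoc(df, factor="cond")
    assert len(ph) == 3
    for row in ph.itertuples():
        assert row.p_bonferroni == pytest.approx(min(1.0, row.p_uncorrected * 3))
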