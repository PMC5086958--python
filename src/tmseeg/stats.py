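"""Shared statistical machinery.

Paired t-tests, Benjamini–Hochberg FDR, a seed-reproducible sign-flip
permutation engine with exhaustive enumeration for small samples, and a
repeated-measures ANOVA for fully within-subject factorial designs with
Mauchly's sphericity test, Greenhouse–Geisser correction, partial eta
squared, and Bonferroni pairwise post-hocs.

Monte Carlo p-values use the add-one correction
``p = (1 + #{null >= observed}) / (1 + n_permutations)`` so that no
permutation p-value can be exactly zero.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "paired_t",
    "fdr_bh",
    "PermutationNull",
    "sign_flip_null",
    "sign_flip_matrix",
    "AnovaResult",
    "rm_anova",
    "bonferroni_posthoc",
]


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Dependent-samples t-test on paired values.

    Returns ``(t, df, p_two_sided)`` with ``df = n - 1``. Raises on
    zero-variance differences (the t statistic is undefined there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def t_values_1samp(diffs: np.ndarray, axis: int = 0,
                   zero_variance: str = "zero") -> np.ndarray:
    """Vectorized one-sample t over ``axis`` of a difference array.

    ``zero_variance='zero'`` maps degenerate (constant-zero) entries to
    t = 0 instead of raising, for use in spatiotemporal maps where flat
    channels must not poison the statistic.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = diffs.mean(axis=axis)
    sd = diffs.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = ~np.isfinite(t)
    if bad.any():
        if zero_variance == "zero":
            t = np.where(bad, 0.0, t)
        else:
            raise ZeroDivisionError("zero-variance differences in t map")
    return t


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up procedure; returns a rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask


@dataclass
class PermutationNull:
    """A sign-flip permutation null distribution for a paired design."""

    observed: float
    null: np.ndarray
    n_permutations: int
    scheme: str  # "sign_flip" | "exhaustive"
    seed: int | None
    monte_carlo_p: float


def sign_flip_matrix(n_subjects: int, n_perm: int,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[np.ndarray, str]:
    """Sign matrix (n_used, n_subjects) of ±1 flips and the scheme used.

    Switches to exhaustive enumeration of all 2^n assignments whenever
    that is no larger than ``n_perm``; otherwise draws ``n_perm`` random
    flip vectors.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if 2 ** n_subjects <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_subjects)))
        return signs, "exhaustive"
    if rng is None:
        raise ValueError("rng required for random sign flips")
    signs = rng.choice([1.0, -1.0], size=(n_perm, n_subjects))
    return signs, "sign_flip"


def sign_flip_null(
    differences: np.ndarray,
    statistic_fn: Callable[[np.ndarray], float],
    n_perm: int = 3000,
    seed: int | None = 0,
    tail: str = "greater",
) -> PermutationNull:
    """Permutation null of ``statistic_fn`` under per-subject sign flips.

    ``differences`` has subjects on axis 0 (values or arrays).
    ``tail='greater'`` counts null >= observed; ``'abs'`` compares
    absolute values.
    """
    diffs = np.asarray(differences, dtype=float)
    n = diffs.shape[0]
    rng = np.random.default_rng(seed)
    signs, scheme = sign_flip_matrix(n, n_perm, rng)
    null = np.empty(signs.shape[0])
    shape = (n,) + (1,) * (diffs.ndim - 1)
    for i, s in enumerate(signs):
        null[i] = statistic_fn(diffs * s.reshape(shape))
    if not np.all(np.isfinite(null)):
        raise ValueError("statistic_fn returned non-finite values")
    observed = float(statistic_fn(diffs))
    if tail == "abs":
        exceed = np.sum(np.abs(null) >= abs(observed))
    else:
        exceed = np.sum(null >= observed)
    p = (1.0 + exceed) / (1.0 + signs.shape[0])
    return PermutationNull(observed, null, signs.shape[0], scheme, seed, float(p))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class EffectResult:
    name: str
    ss_effect: float
    ss_error: float
    df_num: float
    df_den: float
    F: float
    p: float
    partial_eta_sq: float
    epsilon_gg: float
    mauchly_w: float
    mauchly_p: float
    corrected: bool
    df_num_gg: float
    df_den_gg: float


@dataclass
class AnovaResult:
    """Per-effect F table plus optional Bonferroni post-hoc table."""

    effects: dict[str, EffectResult]
    posthoc: pd.DataFrame | None = None
    factors: dict[str, list] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append({
                "effect": e.name, "F": e.F, "df_num": e.df_num_gg if e.corrected else e.df_num,
                "df_den": e.df_den_gg if e.corrected else e.df_den, "p": e.p,
                "partial_eta_sq": e.partial_eta_sq, "epsilon_gg": e.epsilon_gg,
                "mauchly_p": e.mauchly_p, "gg_corrected": e.corrected,
            })
        return pd.DataFrame(rows)


def _cell_cube(table: pd.DataFrame, subject: str, factors: list[str], value: str,
               ) -> tuple[np.ndarray, list[list]]:
    """Reshape a long table into an (n_subjects, k1, ..., km) cube."""
    levels = [list(dict.fromkeys(table[f])) for f in factors]
    subjects = list(dict.fromkeys(table[subject]))
    shape = (len(subjects),) + tuple(len(lv) for lv in levels)
    cube = np.full(shape, np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    l_idx = [{lv: i for i, lv in enumerate(lvs)} for lvs in levels]
    counts = np.zeros(shape, dtype=int)
    for row in table.itertuples():
        idx = (s_idx[getattr(row, subject)],) + tuple(
            l_idx[j][getattr(row, f)] for j, f in enumerate(factors))
        cube[idx] = getattr(row, value)
        counts[idx] += 1
    if (counts != 1).any():
        raise ValueError("design must be complete and balanced with one "
                         "observation per subject x cell")
    return cube, levels


def _ss_term(cube: np.ndarray, keep_axes: tuple[int, ...]) -> float:
    """Sum over the kept-margin cells of total^2 / n_obs_per_cell."""
    total_axes = tuple(ax for ax in range(cube.ndim) if ax not in keep_axes)
    totals = cube.sum(axis=total_axes)
    n_per = np.prod([cube.shape[ax] for ax in total_axes]) if total_axes else 1
    return float(np.sum(totals ** 2) / n_per)


def _effect_contrast(levels_count: int) -> np.ndarray:
    """Orthonormal contrast columns (k x (k-1)) via Helmert + QR."""
    k = levels_count
    c = np.zeros((k, k - 1))
    for j in range(k - 1):
        c[: j + 1, j] = 1.0
        c[j + 1, j] = -(j + 1.0)
    qn, _ = np.linalg.qr(c)
    return qn


def _gg_mauchly(cube: np.ndarray, effect_axes: tuple[int, ...],
                ) -> tuple[float, float, float]:
    """Greenhouse–Geisser epsilon and Mauchly's test for one effect.

    Subject scores are projected onto the effect's orthonormal contrast
    (Kronecker product of per-factor contrasts, averaging over the
    factors not in the effect); epsilon and Mauchly's W come from the
    sample covariance of the projected scores.
    """
    n_subj = cube.shape[0]
    mats = []
    for ax in range(1, cube.ndim):
        k = cube.shape[ax]
        mats.append(_effect_contrast(k) if ax in effect_axes
                    else np.full((k, 1), 1.0 / k))
    m = mats[0]
    for nxt in mats[1:]:
        m = np.kron(m, nxt)
    flat = cube.reshape(n_subj, -1)
    scores = flat @ m  # (n_subj, d)
    d = scores.shape[1]
    if d == 1:
        return 1.0, 1.0, 1.0
    cov = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(cov)
    eps = tr ** 2 / (d * np.sum(cov * cov.T))
    eps = float(np.clip(eps, 1.0 / d, 1.0))
    # Mauchly's W with chi-square approximation
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 1e-300, None)
    w = float(np.prod(eigvals) / (tr / d) ** d)
    if n_subj - 1 <= d:
        return eps, w, np.nan  # covariance singular: test undefined
    # chi-square approximation with the second-order term (as in ezANOVA)
    k = d + 1
    f_corr = 1.0 - (2.0 * d ** 2 + d + 2.0) / (6.0 * d * (n_subj - 1.0))
    w2 = ((d + 2.0) * (d - 1.0) * (d - 2.0) * (2.0 * d ** 3 + 6.0 * d ** 2 + 3.0 * k + 2.0)
          / (288.0 * ((n_subj - 1.0) * d * f_corr) ** 2))
    chi2 = -(n_subj - 1.0) * f_corr * np.log(max(w, 1e-300))
    df = d * (d + 1) / 2.0 - 1.0
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return eps, w, p


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: Sequence[str] = (),
    mauchly_alpha: float = 0.05,
) -> AnovaResult:
    """Repeated-measures ANOVA for a fully within-subject factorial design.

    ``table`` is long-format with one observation per subject x cell.
    Sums of squares follow the classical within-subject decomposition:
    for an effect A, the error term is the A x subject interaction.
    Greenhouse–Geisser-corrected degrees of freedom are used for an
    effect whenever its Mauchly test has p < ``mauchly_alpha``; partial
    eta squared is SS_effect / (SS_effect + SS_error).
    """
    within = list(within)
    if not within:
        raise ValueError("at least one within factor required")
    cube, levels = _cell_cube(table, subject, within, dv)
    n_subj = cube.shape[0]
    max_df = max(len(lv) - 1 for lv in levels)
    if n_subj - 1 <= 0 or n_subj < 2 or n_subj - 1 < 1:
        raise ValueError("need at least 2 subjects")
    if n_subj <= max_df:
        raise ValueError("need more subjects than the largest factor df")
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    subj_axis = 0

    def ss_for(axes: tuple[int, ...]) -> float:
        """Inclusion-exclusion SS for the margin spanned by ``axes``."""
        total = 0.0
        for r in range(len(axes) + 1):
            for sub in itertools.combinations(axes, r):
                total += (-1) ** (len(axes) - len(sub)) * _ss_term(cube, sub)
        return total

    effects: dict[str, EffectResult] = {}
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            axes = tuple(factor_axes[f] for f in combo)
            ss_eff = ss_for(axes)
            ss_err = ss_for(axes + (subj_axis,))
            df_num = float(np.prod([len(levels[factor_axes[f] - 1]) - 1 for f in combo]))
            df_den = df_num * (n_subj - 1)
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            F = ms_eff / ms_err if ms_err > 0 else np.inf
            eps, w, mauchly_p = _gg_mauchly(cube, axes)
            corrected = bool(np.isfinite(mauchly_p) and mauchly_p < mauchly_alpha
                             and df_num > 1)
            dfn = df_num * eps if corrected else df_num
            dfd = df_den * eps if corrected else df_den
            p = float(sps.f.sf(F, dfn, dfd)) if np.isfinite(F) else 0.0
            effects[" x ".join(combo)] = EffectResult(
                " x ".join(combo), ss_eff, ss_err, df_num, df_den, float(F), p,
                float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err > 0 else 0.0,
                eps, w, mauchly_p, corrected, dfn, dfd)
    return AnovaResult(effects, factors={f: levels[factor_axes[f] - 1] for f in within})


def bonferroni_posthoc(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factor: str = "condition",
    within_levels_of: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise paired t-tests over one factor.

    ``within_levels_of`` restricts the table to fixed levels of other
    factors before averaging over any remaining ones. The correction
    multiplies by the number of pairwise comparisons actually made.
    """
    sub = table
    if within_levels_of:
        for col, lev in within_levels_of.items():
            sub = sub[sub[col] == lev]
    cells = sub.groupby([subject, factor], sort=False)[dv].mean().reset_index()
    levels = list(dict.fromkeys(cells[factor]))
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for la, lb in pairs:
        pa = cells[cells[factor] == la].set_index(subject)[dv]
        pb = cells[cells[factor] == lb].set_index(subject)[dv]
        common = pa.index.intersection(pb.index)
        t, df, p = paired_t(pa.loc[common].to_numpy(), pb.loc[common].to_numpy())
        rows.append({"level_a": la, "level_b": lb, "t": t, "df": df,
                     "p_uncorrected": p,
                     "p_bonferroni": min(1.0, p * len(pairs)),
                     "mean_diff": float((pa.loc[common] - pb.loc[common]).mean())})
    return pd.DataFrame(rows)
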