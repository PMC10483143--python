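"""Cohort-level statistics: Student's t, one-way ANOVA with Tukey HSD, and
two-way repeated-measures ANOVA.

The quadrant-occupancy analyses compare the four role fractions, which are
compositional (they sum to one and are therefore not independent across
roles).  The tests are run as conventionally published for this assay; the
violation is recorded in the result metadata rather than "corrected".

``students_t`` and ``one_way_anova`` wrap scipy; the repeated-measures
decomposition (factor A, factor B, A x B, subject, and per-effect error
strata on a complete balanced within-subject design) is computed here, with
an optional Greenhouse-Geisser sphericity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError

COMPOSITIONAL_NOTE = (
    "quadrant fractions are compositional (sum to 1); tests run as published"
)


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``df`` is an int for t tests and an (effect, error) pair for F tests;
    ``posthoc`` is a tidy pairwise table when a multiple-comparison procedure
    applies; ``summary`` holds mean and 95% CI per cell.
    """

    name: str
    statistic: float
    df: tuple
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    summary: Optional[pd.DataFrame] = None
    effects: Optional[pd.DataFrame] = None
    notes: list[str] = field(default_factory=list)


def _check_group(g, label: str, min_n: int = 2) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or len(g) < min_n:
        raise DesignError(f"group {label} needs >= {min_n} observations")
    return g


def summarize(groups: dict[str, Sequence[float]], ci: float = 0.95) -> pd.DataFrame:
    """Mean and two-sided t-interval per cell (default 95%)."""
    rows = []
    for name, vals in groups.items():
        v = _check_group(vals, name)
        n = len(v)
        m = float(np.mean(v))
        sem = float(np.std(v, ddof=1) / np.sqrt(n))
        half = float(sps.t.ppf(0.5 + ci / 2.0, n - 1) * sem)
        rows.append(
            {"cell": name, "n": n, "mean": m, "ci_low": m - half, "ci_high": m + half}
        )
    return pd.DataFrame(rows)


def students_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
) -> TestResult:
    """Two-tailed Student's t-test; unpaired pooled-variance by default."""
    a = _check_group(group_a, "a")
    b = _check_group(group_b, "b")
    if paired:
        if len(a) != len(b):
            raise DesignError("paired test requires equal group sizes")
        res = sps.ttest_rel(a, b)
        df = len(a) - 1
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):  # zero variance, zero difference
        stat, p = 0.0, 1.0
    return TestResult(
        name="students_t_paired" if paired else "students_t_unpaired",
        statistic=stat,
        df=(df,),
        p_value=p,
        summary=summarize({"a": a, "b": b}),
    )


def one_way_anova(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
) -> TestResult:
    """Classical one-way ANOVA with Tukey HSD post-hoc comparisons."""
    if isinstance(groups, dict):
        names = list(groups)
        data = [_check_group(groups[k], k) for k in names]
    else:
        names = [f"g{i+1}" for i in range(len(groups))]
        data = [_check_group(g, n) for g, n in zip(groups, names)]
    k = len(data)
    if k < 2:
        raise DesignError("one-way ANOVA needs >= 2 groups")
    N = sum(len(g) for g in data)
    grand = np.concatenate(data).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    sst = sum(((g - grand) ** 2).sum() for g in data)
    notes = []
    if sst < 1e-300:
        # all observations identical: no between-group signal
        f_stat, p = 0.0, 1.0
        notes.append("degenerate design: zero between- and within-group variance")
        posthoc = None
    elif ssb < 1e-300:
        f_stat, p = 0.0, 1.0
        posthoc = _tukey_table(names, data)
    else:
        res = sps.f_oneway(*data)
        f_stat, p = float(res.statistic), float(res.pvalue)
        posthoc = _tukey_table(names, data)
    notes.append(COMPOSITIONAL_NOTE)
    return TestResult(
        name="one_way_anova",
        statistic=f_stat,
        df=(k - 1, N - k),
        p_value=p,
        posthoc=posthoc,
        summary=summarize({n: g for n, g in zip(names, data)}),
        notes=notes,
    )


def _tukey_table(names: list[str], data: list[np.ndarray]) -> pd.DataFrame:
    res = sps.tukey_hsd(*data)
    rows = []
    for i, j in combinations(range(len(data)), 2):
        rows.append(
            {
                "a": names[i],
                "b": names[j],
                "mean_diff": float(data[i].mean() - data[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA


def _pivot_balanced(
    table: pd.DataFrame,
    subject: str,
    factor_a: str,
    factor_b: str,
    response: str,
) -> tuple[np.ndarray, list, list, list]:
    """(s, a, b) response array from a long table; errors name missing cells."""
    subjects = sorted(table[subject].unique())
    a_levels = sorted(table[factor_a].unique())
    b_levels = sorted(table[factor_b].unique())
    grid = table.set_index([subject, factor_a, factor_b])[response]
    if grid.index.has_duplicates:
        raise DesignError("more than one response per subject x cell")
    y = np.empty((len(subjects), len(a_levels), len(b_levels)))
    for i, s in enumerate(subjects):
        for j, a in enumerate(a_levels):
            for k, b in enumerate(b_levels):
                try:
                    y[i, j, k] = grid.loc[(s, a, b)]
                except KeyError:
                    raise DesignError(
                        f"missing cell: subject={s}, {factor_a}={a}, {factor_b}={b}"
                    ) from None
    return y, subjects, a_levels, b_levels


def _gg_epsilon(y_cells: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one within effect.

    ``y_cells`` is subjects x cells; ``contrast`` is cells x d orthonormal.
    """
    sigma = np.cov(y_cells, rowvar=False)
    s = contrast.T @ sigma @ contrast
    d = s.shape[0]
    tr = np.trace(s)
    denom = d * np.trace(s @ s)
    if denom < 1e-300:
        return 1.0
    return float(min(1.0, max(1.0 / d, tr**2 / denom)))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (Helmert, normalized)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0 / j
        h[j, j - 1] = -1.0
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def two_way_rm_anova(
    table: pd.DataFrame,
    subject: str = "subject",
    within: tuple[str, str] = ("role", "time_bin"),
    response: str = "value",
    gg_correction: bool = False,
) -> TestResult:
    """Two-way fully within-subject ANOVA on a complete balanced design.

    Sums of squares are partitioned into factor A, factor B, A x B, subject,
    and the three matching error strata (A x subject, B x subject,
    A x B x subject).  Sphericity is uncorrected by default;
    ``gg_correction=True`` applies Greenhouse-Geisser df scaling per effect.
    The headline ``statistic``/``df``/``p_value`` are factor A's; the full
    table is in ``effects``.  Tukey pairwise comparisons over each factor's
    marginal means use that factor's error stratum.
    """
    fa, fb = within
    y, subjects, a_levels, b_levels = _pivot_balanced(
        table, subject, fa, fb, response
    )
    s, a, b = y.shape
    if s < 2 or a < 2 or b < 2:
        raise DesignError("need >= 2 subjects and >= 2 levels per factor")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_a = s * b * np.sum((m_a - grand) ** 2)
    ss_b = s * a * np.sum((m_b - grand) ** 2)
    ss_ab = s * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    )
    ss_as = b * np.sum(
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    )
    ss_bs = a * np.sum(
        (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_as, df_bs, df_abs = df_a * (s - 1), df_b * (s - 1), df_ab * (s - 1)

    # per-effect GG epsilons from orthonormal contrasts on the cell covariance
    y_cells = y.reshape(s, a * b)
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    one_a = np.full((a, 1), 1.0 / np.sqrt(a))
    one_b = np.full((b, 1), 1.0 / np.sqrt(b))
    eps = {
        fa: _gg_epsilon(y_cells, np.kron(ca, one_b)),
        fb: _gg_epsilon(y_cells, np.kron(one_a, cb)),
        f"{fa}:{fb}": _gg_epsilon(y_cells, np.kron(ca, cb)),
    }

    # SS at rounding-noise level (relative to the total) counts as zero
    ss_tol = 1e-12 * max(float(ss_total), 1.0)

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in (
        (fa, ss_a, df_a, ss_as, df_as),
        (fb, ss_b, df_b, ss_bs, df_bs),
        (f"{fa}:{fb}", ss_ab, df_ab, ss_abs, df_abs),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ss_eff < ss_tol:
            f_stat = 0.0
        else:
            f_stat = ms_eff / max(ms_err, 1e-300)
        e = eps[name] if gg_correction else 1.0
        p = float(sps.f.sf(f_stat, e * df_eff, e * df_err))
        rows.append(
            {
                "effect": name,
                "ss": ss_eff,
                "df": df_eff,
                "ss_error": ss_err,
                "df_error": df_err,
                "F": f_stat,
                "p": p,
                "gg_epsilon": eps[name],
            }
        )
    effects = pd.DataFrame(rows)

    posthoc = pd.concat(
        [
            _rm_tukey(fa, a_levels, m_a, ss_as / df_as, df_as, s * b),
            _rm_tukey(fb, b_levels, m_b, ss_bs / df_bs, df_bs, s * a),
        ],
        ignore_index=True,
    )
    cell_means = {
        f"{fa}={al}|{fb}={bl}": y[:, j, k]
        for j, al in enumerate(a_levels)
        for k, bl in enumerate(b_levels)
    }
    head = effects.iloc[0]
    return TestResult(
        name="two_way_rm_anova",
        statistic=float(head["F"]),
        df=(int(head["df"]), int(head["df_error"])),
        p_value=float(head["p"]),
        posthoc=posthoc,
        summary=summarize(cell_means),
        effects=effects,
        notes=[COMPOSITIONAL_NOTE],
    )


def _rm_tukey(
    factor: str,
    levels: list,
    means: np.ndarray,
    ms_err: float,
    df_err: int,
    n_per_mean: int,
) -> pd.DataFrame:
    """Tukey studentized-range comparisons of marginal means in an RM design."""
    k = len(levels)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(ms_err / n_per_mean)
        if se < 1e-300:
            p = 1.0 if abs(diff) < 1e-300 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
        rows.append(
            {
                "factor": factor,
                "a": levels[i],
                "b": levels[j],
                "mean_diff": float(diff),
                "p_adj": p,
            }
        )
    return pd.DataFrame(rows)
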