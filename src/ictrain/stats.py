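"""ANOVA engine for randomized waitlist-control training studies.

Covers the designs used to analyze such a trial: one-way ANOVA on raw data
or on printed summary statistics (baseline tables), the time x condition
split-plot (mixed) ANOVA with simple-effects follow-up, one-way
repeated-measures ANOVA with adjacent planned contrasts for the three
training-session blocks, a generic balanced mixed-factorial routine for
multi-way ERP amplitude designs, partial eta squared, and the dependent-
means power computation used for sample-size planning.

All sums of squares are the classical balanced-design decompositions on
complete cases; p-values come from the central F distribution and alpha is
conventionally .05 with no multiplicity correction.  Sphericity correction
for the 3-level repeated factor is available (Greenhouse-Geisser) but off
by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    """One tested effect: F ratio, degrees of freedom, p, partial eta squared."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False

    @classmethod
    def from_f(
        cls, effect: str, F: float, df1: int, df2: int, degenerate: bool = False
    ) -> "AnovaResult":
        if np.isinf(F):
            return cls(effect, float("inf"), df1, df2, 0.0, 1.0, True)
        p = float(sps.f.sf(F, df1, df2)) if F > 0 else 1.0
        return cls(effect, float(F), df1, df2, p, partial_eta_sq(F, df1, df2), degenerate)


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Effect size eta_p^2 = F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


def _f_from_ss(effect, ss_eff, df1, ss_err, df2) -> AnovaResult:
    if ss_err <= 0:
        if ss_eff <= 0:
            return AnovaResult(effect, 0.0, df1, df2, 1.0, 0.0, True)
        return AnovaResult.from_f(effect, float("inf"), df1, df2, degenerate=True)
    F = (ss_eff / df1) / (ss_err / df2)
    return AnovaResult.from_f(effect, F, df1, df2)


# ---------------------------------------------------------------------------
# one-way ANOVA (raw and from summary statistics)

def oneway_anova(*groups) -> AnovaResult:
    """Classical between/within one-way ANOVA on raw observations.

    With two groups, F equals the squared pooled-variance two-sample t.
    The fully degenerate case (all observations identical) returns F = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    return _f_from_ss("group", ssb, df1, ssw, df2)


def oneway_from_summary(means, sds, ns) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (mean, sd, n) summaries.

    Algebraically identical to :func:`oneway_anova` on any raw data sharing
    those exact summaries — the route used to re-derive F ratios from a
    printed baseline table.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if len(means) < 2 or (ns < 2).any():
        raise ValueError("need >= 2 groups with n >= 2 each")
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    return _f_from_ss("group", ssb, len(means) - 1, ssw, N - len(means))


# ---------------------------------------------------------------------------
# time x condition mixed (split-plot) ANOVA

def _complete_cases(
    table: pd.DataFrame, outcome: str, subject: str, within: str
) -> pd.DataFrame:
    n_levels = table[within].nunique()
    counts = table.groupby(subject)[outcome].count()
    complete = counts[counts == n_levels].index
    dropped = counts.index.difference(complete)
    if len(dropped):
        logger.info(
            "dropping %d participant(s) missing a %s level", len(dropped), within
        )
    return table[table[subject].isin(complete)]


def mixed_anova(
    table: pd.DataFrame,
    outcome: str,
    subject: str = "participant_id",
    within: str = "time",
    between: str = "condition",
) -> dict[str, AnovaResult]:
    """Split-plot ANOVA: between-subjects condition x within-subjects time.

    Complete cases only (participants missing a time point are dropped with
    a logged count).  Returns the between main effect, the within main
    effect and the interaction; on balanced two-by-two data the interaction
    has df (1, N-2).
    """
    df = _complete_cases(table.dropna(subset=[outcome]), outcome, subject, within)
    wide = df.pivot_table(index=subject, columns=within, values=outcome)
    groups = df.groupby(subject)[between].first().reindex(wide.index)
    y = wide.to_numpy(dtype=float)
    n_subj, n_t = y.shape
    if n_t < 2 or groups.nunique() < 2:
        raise ValueError("need >= 2 within levels and >= 2 groups")
    g_codes, g_levels = pd.factorize(groups)
    n_g = len(g_levels)
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[g_codes == g].mean() for g in range(n_g)])
    group_ns = np.bincount(g_codes)

    ss_between_subj = n_t * ((subj_means - grand) ** 2).sum()
    ss_cond = n_t * (group_ns * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_cond

    cell_means = np.zeros((n_g, n_t))
    for g in range(n_g):
        cell_means[g] = y[g_codes == g].mean(axis=0)
    time_means = (group_ns[:, None] * cell_means).sum(axis=0) / n_subj
    ss_cells = (group_ns[:, None] * (cell_means - grand) ** 2).sum()
    ss_time = n_subj * ((time_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_cond - ss_time

    ss_total = ((y - grand) ** 2).sum()
    ss_within = ss_total - ss_between_subj
    ss_err_within = ss_within - ss_time - ss_inter

    df_g, df_sw = n_g - 1, n_subj - n_g
    df_t = n_t - 1
    df_ew = df_sw * df_t
    return {
        between: _f_from_ss(between, ss_cond, df_g, ss_subj_within, df_sw),
        within: _f_from_ss(within, ss_time, df_t, ss_err_within, df_ew),
        f"{within}:{between}": _f_from_ss(
            f"{within}:{between}", ss_inter, df_g * df_t, ss_err_within, df_ew
        ),
    }


def _paired_f(effect: str, diffs: np.ndarray) -> AnovaResult:
    """Within-subjects two-level F as the squared paired t."""
    n = len(diffs)
    if n < 2:
        raise ValueError("need >= 2 participants")
    mean = diffs.mean()
    var = diffs.var(ddof=1)
    if var == 0:
        if mean == 0:
            return AnovaResult(effect, 0.0, 1, n - 1, 1.0, 0.0, True)
        return AnovaResult.from_f(effect, float("inf"), 1, n - 1, degenerate=True)
    t = mean / np.sqrt(var / n)
    return AnovaResult.from_f(effect, t**2, 1, n - 1)


def simple_effects(
    table: pd.DataFrame,
    outcome: str,
    subject: str = "participant_id",
    within: str = "time",
    by: str = "condition",
) -> dict[str, AnovaResult]:
    """Planned follow-up: per-condition within-subjects effect of time.

    For two time points each F equals the squared paired t.  Zero
    within-condition change yields F = 0; zero error variance with nonzero
    change is flagged degenerate (infinite F).
    """
    out = {}
    df = _complete_cases(table.dropna(subset=[outcome]), outcome, subject, within)
    for level, sub in df.groupby(by):
        wide = sub.pivot_table(index=subject, columns=within, values=outcome)
        if wide.shape[1] != 2:
            raise ValueError("simple_effects expects exactly 2 within levels")
        if wide.shape[0] < 2:
            raise ValueError(f"condition {level!r} has < 2 participants")
        diffs = wide.iloc[:, 1].to_numpy() - wide.iloc[:, 0].to_numpy()
        out[level] = _paired_f(f"{within} | {by}={level}", diffs)
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with planned contrasts (training sessions)

def rm_anova_contrasts(
    session_values: np.ndarray | pd.DataFrame, greenhouse_geisser: bool = False
) -> tuple[AnovaResult, list[AnovaResult]]:
    """One-way repeated-measures ANOVA over k sessions + adjacent contrasts.

    ``session_values`` is (n_participants, k) with complete rows.  The main
    effect has df (k-1, (k-1)(n-1)) — uncorrected by default; pass
    ``greenhouse_geisser=True`` for epsilon-adjusted dfs and p.  Each
    adjacent planned contrast (session i vs i+1) is a paired comparison
    with df (1, n-1), F equal to the squared paired t.
    """
    y = np.asarray(
        session_values.to_numpy() if isinstance(session_values, pd.DataFrame)
        else session_values,
        dtype=float,
    )
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need an (n_participants, k>=2) array")
    if np.isnan(y).any():
        raise ValueError("missing session values")
    n, k = y.shape
    grand = y.mean()
    ss_time = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    main = _f_from_ss("session", ss_time, df1, ss_err, df2)
    if greenhouse_geisser and not main.degenerate and k > 2:
        eps = _gg_epsilon(y)
        p = float(sps.f.sf(main.F, eps * df1, eps * df2))
        main = AnovaResult(
            "session (GG)", main.F, df1, df2, p, main.partial_eta_sq
        )
    contrasts = [
        _paired_f(f"session {i + 1} vs {i + 2}", y[:, i + 1] - y[:, i])
        for i in range(k - 1)
    ]
    return main, contrasts


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of measures."""
    k = y.shape[1]
    S = np.cov(y, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum()
                     + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0 / (k - 1)


# ---------------------------------------------------------------------------
# generic balanced mixed-factorial ANOVA (ERP amplitude designs)

def factorial_mixed_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str | None = None,
) -> pd.DataFrame:
    """Balanced mixed-factorial ANOVA with any number of within factors.

    Requires one observation per subject x within-cell and, if a between
    factor is given, equal group sizes.  Each within-term's error is its
    interaction with subject(group), per the standard univariate split-plot
    decomposition.  Used for multi-way ERP peak-amplitude designs such as
    condition x time x stimulus x RTD x laterality.
    """
    wide = table.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("design must be complete: every subject in every cell")
    y = wide.to_numpy(dtype=float)
    n_subj, m = y.shape
    levels = [wide.columns.get_level_values(i).unique() for i in range(len(within))] \
        if len(within) > 1 else [wide.columns.unique()]
    shape = [len(l) for l in levels]
    if int(np.prod(shape)) != m:
        raise ValueError("within cells must form a full cross")
    # reorder columns into the canonical cross product
    order_index = pd.MultiIndex.from_product(levels, names=within) \
        if len(within) > 1 else pd.Index(levels[0], name=within[0])
    wide = wide.reindex(columns=order_index)
    y = wide.to_numpy(dtype=float)

    if between is not None:
        groups = table.groupby(subject)[between].first().reindex(wide.index)
        g_codes, g_levels = pd.factorize(groups)
        n_g = len(g_levels)
        if len(set(np.bincount(g_codes))) != 1:
            raise ValueError("factorial_mixed_anova requires equal group sizes")
    else:
        g_codes = np.zeros(n_subj, dtype=int)
        n_g = 1
    n_per_g = n_subj // n_g

    # cube of cell means: (group, w1, ..., wk)
    cube = np.zeros([n_g] + shape)
    for g in range(n_g):
        cube[g] = y[g_codes == g].mean(axis=0).reshape(shape)
    k = len(within)
    axes_all = tuple(range(1, k + 1))

    def mean_over(keep_g: bool, keep_w: tuple[int, ...]) -> np.ndarray:
        axes = tuple(a for a in axes_all if (a - 1) not in keep_w)
        out = cube.mean(axis=axes, keepdims=True)
        if not keep_g:
            out = out.mean(axis=0, keepdims=True)
        return out

    def effect_ss(with_g: bool, w_set: tuple[int, ...]) -> tuple[float, int]:
        # inclusion-exclusion over sub-terms; eff keeps singleton dims for
        # collapsed axes, so (eff**2).sum() counts each distinct effect value
        # once and `reps` is the raw-observation count behind each value
        target_shape = [n_g if with_g else 1] + [
            shape[a] if a in w_set else 1 for a in range(k)
        ]
        eff = np.zeros(target_shape)
        members = (["G"] if with_g else []) + list(w_set)
        for r in range(len(members) + 1):
            for sub in combinations(members, r):
                keep_g = "G" in sub
                keep_w = tuple(a for a in sub if a != "G")
                sign = (-1) ** (len(members) - len(sub))
                eff = eff + sign * mean_over(keep_g, keep_w)
        reps = (n_per_g if with_g else n_subj) * int(
            np.prod([shape[a] for a in range(k) if a not in w_set])
        )
        ss = reps * float((eff**2).sum())
        df = int(np.prod([shape[a] - 1 for a in w_set])) * (n_g - 1 if with_g else 1)
        return ss, df

    rows = []

    # between-subjects stratum
    subj_means = y.mean(axis=1)
    grand = y.mean()
    ss_subj = m * ((subj_means - grand) ** 2).sum()
    if between is not None:
        gm = np.array([subj_means[g_codes == g].mean() for g in range(n_g)])
        ss_g = m * n_per_g * ((gm - grand) ** 2).sum()
        ss_sw = ss_subj - ss_g
        rows.append((between, ss_g, n_g - 1, ss_sw, n_subj - n_g))
    else:
        ss_sw = ss_subj

    # within strata: every non-empty subset of within factors
    err_cache: dict[tuple[int, ...], tuple[float, int]] = {}

    def error_term(w_set: tuple[int, ...]) -> tuple[float, int]:
        if w_set in err_cache:
            return err_cache[w_set]
        # subject x S means, collapsing the other within factors
        z = y.reshape([n_subj] + shape)
        other = tuple(1 + a for a in range(k) if a not in w_set)
        if other:
            z = z.mean(axis=other)
        z2 = z.reshape(n_subj, -1)
        gmean_cells = np.zeros((n_g, z2.shape[1]))
        for g in range(n_g):
            gmean_cells[g] = z2[g_codes == g].mean(axis=0)
        g_overall = gmean_cells.mean(axis=1)
        resid = (
            z2
            - z2.mean(axis=1, keepdims=True)
            - gmean_cells[g_codes]
            + g_overall[g_codes][:, None]
        )
        c = int(np.prod([shape[a] for a in range(k) if a not in w_set]))
        r_full = c * float((resid**2).sum())
        df_full = (n_subj - n_g) * int(np.prod([shape[a] - 1 for a in w_set]))
        # subtract lower-order within x subject errors contained in the residual
        ss, df = r_full, df_full
        for r in range(1, len(w_set)):
            for sub in combinations(w_set, r):
                ss_u, _ = error_term(sub)
                df_u = (n_subj - n_g) * int(np.prod([shape[a] - 1 for a in sub]))
                ss -= ss_u
        err_cache[w_set] = (ss, df)
        return ss, df

    for r in range(1, k + 1):
        for w_set in combinations(range(k), r):
            ss_err, df_err = error_term(w_set)
            ss_e, df_e = effect_ss(False, w_set)
            name = ":".join(within[a] for a in w_set)
            rows.append((name, ss_e, df_e, ss_err, df_err))
            if between is not None:
                ss_eg, df_eg = effect_ss(True, w_set)
                rows.append((f"{name}:{between}", ss_eg, df_eg, ss_err, df_err))

    out = []
    for name, ss_e, df_e, ss_err, df_err in rows:
        res = _f_from_ss(name, ss_e, df_e, ss_err, df_err)
        out.append(
            {
                "effect": name,
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "partial_eta_sq": res.partial_eta_sq,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# power / sample size for the dependent-means t test

def power_dependent_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Two-tailed power of a paired t test at effect size d and sample size n."""
    if n < 2:
        return 0.0
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    nc = d * np.sqrt(n)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def required_n_dependent_t(
    d: float, alpha: float = 0.05, power: float = 0.95, n_max: int = 1_000_000
) -> int:
    """Smallest n whose noncentral-t paired-test power meets the target.

    Matches standard a priori power software for dependent means (e.g.
    d = 0.5 at two-tailed alpha .05 and 95% power requires n = 54).
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_dependent_t(n, d, alpha) >= power:
            return n
    raise ValueError("target power unattainable within n_max")


def anova_results_frame(results: dict[str, AnovaResult]) -> pd.DataFrame:
    """Tidy table (effect, F, df1, df2, p, partial_eta_sq) from result dicts."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df1": r.df1,
                "df2": r.df2,
                "p": r.p,
                "partial_eta_sq": r.partial_eta_sq,
                "degenerate": r.degenerate,
            }
            for r in results.values()
        ]
    )
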