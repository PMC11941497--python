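"""The statistical battery used throughout the pipeline.

Group comparisons follow a normality-gated branch: each group is run
through four normality tests (Shapiro–Wilk, Kolmogorov–Smirnov against
the fitted normal, D'Agostino–Pearson, Anderson–Darling); if every group
passes all four at alpha, the omnibus is one-way ANOVA with Tukey's HSD
post hoc, otherwise Kruskal–Wallis with Dunn's post hoc
(Bonferroni-adjusted by default).  The all-pass rule is deliberately
conservative and configurable via ``min_tests_passed``.

The Kolmogorov–Smirnov test is run against the normal fitted to the
sample; estimating the parameters from the same data makes the nominal
KS p-values conservative (the Lilliefors correction is not applied).
The Anderson–Darling p-value is interpolated from its critical-value
table (falling back to a plain critical-value comparison on scipy
versions without interpolation).

Dixon's Q (two-sided r10 variant, Q = gap/range) flags at most one
outlier per pass against the published alpha = 0.05 critical table for
3 <= n <= 30.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as ss

from .datatypes import ParameterError, StatResult

log = logging.getLogger(__name__)

ALPHA = 0.05

# Dixon's Q two-tailed critical values, alpha = 0.05 (r10), n = 3..30
# (Rorabacher, Anal. Chem. 63 (1991) 139-146)
DIXON_Q_CRIT_05 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.298,
}


def normality_battery(x, alpha: float = ALPHA) -> dict:
    """Run the four-test normality battery on one sample.

    Returns per-test p-values (Anderson–Darling reports its statistic and
    5% critical value instead) and booleans, plus the joint verdict:
    ``normal`` is True iff no test rejects at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ParameterError("normality battery needs n >= 8")
    if not np.isfinite(x).all():
        raise ParameterError("normality battery requires finite values")
    if np.ptp(x) == 0:
        raise ParameterError("normality is undefined for a constant vector")

    sw_stat, sw_p = ss.shapiro(x)
    ks_stat, ks_p = ss.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    da_stat, da_p = ss.normaltest(x)
    try:
        ad = ss.anderson(x, dist="norm", method="interpolate")
        ad_entry = {
            "statistic": float(ad.statistic),
            "p": float(ad.pvalue),
            "pass": bool(ad.pvalue > alpha),
        }
    except TypeError:  # older scipy without the method argument
        ad = ss.anderson(x, dist="norm")
        ad_idx = int(np.argmin(np.abs(ad.significance_level - alpha * 100)))
        ad_crit = float(ad.critical_values[ad_idx])
        ad_entry = {
            "statistic": float(ad.statistic),
            "critical_value": ad_crit,
            "pass": bool(ad.statistic < ad_crit),
        }
    tests = {
        "shapiro_wilk": {"statistic": float(sw_stat), "p": float(sw_p), "pass": sw_p > alpha},
        "kolmogorov_smirnov": {"statistic": float(ks_stat), "p": float(ks_p), "pass": ks_p > alpha},
        "dagostino_pearson": {"statistic": float(da_stat), "p": float(da_p), "pass": da_p > alpha},
        "anderson_darling": ad_entry,
    }
    tests["normal"] = all(t["pass"] for t in tests.values() if isinstance(t, dict))
    return tests


def _dunn_posthoc(groups: list[np.ndarray], names, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's z-tests on mean ranks after Kruskal–Wallis, with tie correction."""
    all_values = np.concatenate(groups)
    n_total = all_values.size
    ranks = ss.rankdata(all_values)
    splits = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]

    _, tie_counts = np.unique(all_values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))

    rows = []
    raw_ps = []
    for (i, a), (j, b) in itertools.combinations(enumerate(groups), 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12 - tie_term) * (1 / a.size + 1 / b.size)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * ss.norm.sf(abs(z))
        raw_ps.append(p)
        rows.append({"group_a": names[i], "group_b": names[j], "statistic": float(z), "p_raw": float(p)})
    m = len(rows)
    if adjust == "bonferroni":
        adj = [min(1.0, p * m) for p in raw_ps]
    elif adjust == "holm":
        order = np.argsort(raw_ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw_ps[idx])
            adj[idx] = min(1.0, running)
        adj = adj.tolist()
    elif adjust == "none":
        adj = raw_ps
    else:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    for row, p in zip(rows, adj):
        row["p_adjusted"] = float(p)
    return pd.DataFrame(rows)


def _tukey_posthoc(groups: list[np.ndarray], names) -> pd.DataFrame:
    res = ss.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adjusted": float(res.pvalue[i, j]),  # Tukey p is family-adjusted
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    groups,
    names=None,
    alpha: float = ALPHA,
    min_tests_passed: int = 4,
    dunn_adjust: str = "bonferroni",
) -> StatResult:
    """Omnibus + post-hoc comparison with a normality-gated branch.

    If every group passes at least ``min_tests_passed`` of the four
    normality tests, runs one-way ANOVA with Tukey's HSD; otherwise
    Kruskal–Wallis with Dunn's test.  Groups too small or too degenerate
    for the battery fall to the nonparametric branch with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    if any(g.size < 3 for g in groups):
        raise ParameterError("each group needs n >= 3")
    names = list(names) if names is not None else [f"group{i + 1}" for i in range(len(groups))]

    verdicts = {}
    all_normal = True
    for name, g in zip(names, groups):
        try:
            battery = normality_battery(g, alpha=alpha)
            n_passed = sum(
                t["pass"] for t in battery.values() if isinstance(t, dict)
            )
            verdicts[name] = battery
        except ParameterError as err:
            log.warning("normality battery inapplicable for %s (%s)", name, err)
            verdicts[name] = {"normal": False, "error": str(err)}
            n_passed = 0
        if n_passed < min_tests_passed:
            all_normal = False

    if all_normal:
        stat, p = ss.f_oneway(*groups)
        post = _tukey_posthoc(groups, names)
        branch, test_name = "anova_tukey", "one-way ANOVA"
    else:
        if np.ptp(np.concatenate(groups)) == 0:
            log.warning("all values identical across groups; no test to run")
            stat, p = 0.0, 1.0
            post = None
        else:
            stat, p = ss.kruskal(*groups)
            post = _dunn_posthoc(groups, names, adjust=dunn_adjust)
        branch, test_name = "kw_dunn", "Kruskal-Wallis"
    return StatResult(
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        groups=names,
        post_hoc=post,
        normality_verdicts=verdicts,
        chosen_branch=branch,
    )


def dixon_q(x, alpha: float = ALPHA) -> tuple[list[int], float]:
    """Dixon's Q test (two-sided r10): flag the most extreme point if
    Q = gap/range exceeds the critical value.  Valid for 3 <= n <= 30.

    Returns (outlier indices — at most one —, Q statistic).
    """
    if alpha != 0.05:
        raise ParameterError("critical values tabulated for alpha = 0.05 only")
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 3 <= n <= 30:
        raise ParameterError("Dixon's Q is tabulated for 3 <= n <= 30")
    order = np.argsort(x)
    xs = x[order]
    rng = xs[-1] - xs[0]
    if rng == 0:
        return [], 0.0
    gap_low = xs[1] - xs[0]
    gap_high = xs[-1] - xs[-2]
    if gap_high >= gap_low:
        q, idx = gap_high / rng, int(order[-1])
    else:
        q, idx = gap_low / rng, int(order[0])
    crit = DIXON_Q_CRIT_05[n]
    return ([idx] if q > crit else [], float(q))


def pearson_r(x, y) -> StatResult:
    """Sample Pearson correlation with its two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ParameterError("pearson_r needs two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("pearson_r is undefined for constant input")
    r, p = ss.pearsonr(x, y)
    return StatResult(test_name="pearson", statistic=float(r), p_value=float(p))


def two_sample_t(a, b, welch: bool = True) -> StatResult:
    """Two-sample t-test; Welch (unequal variances) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("two_sample_t needs n >= 2 per sample")
    degenerate_equal = (
        np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]
    )
    if np.array_equal(a, b) or degenerate_equal:
        stat, p = 0.0, 1.0
    else:
        stat, p = ss.ttest_ind(a, b, equal_var=not welch)
    return StatResult(
        test_name="welch_t" if welch else "student_t",
        statistic=float(stat),
        p_value=float(p),
        groups=("a", "b"),
    )


def stat_result_frame(results: dict[str, StatResult]) -> pd.DataFrame:
    """Tidy one-row-per-comparison frame with branch provenance."""
    rows = []
    for label, res in results.items():
        rows.append(
            {
                "comparison": label,
                "test": res.test_name,
                "branch": res.chosen_branch,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
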