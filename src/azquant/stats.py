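"""Assumption-gated group comparisons with multiplicity-corrected post hocs.

The decision tree: Shapiro–Wilk normality per group and Levene's test
(median-centred, Brown–Forsythe variant) for homogeneity of variances,
both at a configurable alpha; when all assumptions hold, a two-sided
t-test (2 groups) or one-way ANOVA (>2 groups) is used, otherwise
Mann–Whitney U or Kruskal–Wallis.  Post hoc comparisons use Tukey–Kramer
on the parametric path and pairwise Mann–Whitney with Holm step-down
correction on the nonparametric path; all pairs are always tested, with an
option to report only comparisons against a reference group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_ASSUMPTION_ALPHA = 0.05
MIN_N_FOR_ASSUMPTION_TESTS = 3

PARAMETRIC_TESTS = {2: "t-test", "many": "one-way ANOVA"}
NONPARAMETRIC_TESTS = {2: "Mann-Whitney U", "many": "Kruskal-Wallis"}


@dataclass
class TestSelection:
    test_name: str
    parametric: bool
    shapiro_p: dict[str, float]
    levene_p: float
    forced_nonparametric: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    selection: TestSelection
    posthoc: pd.DataFrame  # group1, group2, raw_p, adj_p, method, reported
    summary: pd.DataFrame  # group, n, mean, sem


def _as_groups(data) -> dict[str, np.ndarray]:
    if isinstance(data, dict):
        groups = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    else:
        raise TypeError("data must be a mapping of group name -> values")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    return groups


def select_test(data: dict, alpha_assumption: float = DEFAULT_ASSUMPTION_ALPHA) -> TestSelection:
    """Choose the test per the normality/variance-homogeneity decision tree.

    Groups with n < 3 (too small for the assumption tests) or zero
    variance force the nonparametric branch, flagged in the result.
    """
    groups = _as_groups(data)
    k = len(groups)
    which = 2 if k == 2 else "many"
    notes: list[str] = []
    shapiro_p: dict[str, float] = {}
    forced = False
    for name, v in groups.items():
        if v.size < MIN_N_FOR_ASSUMPTION_TESTS:
            forced = True
            notes.append(f"group {name!r} has n < {MIN_N_FOR_ASSUMPTION_TESTS}; nonparametric test forced")
            shapiro_p[name] = math.nan
        elif np.ptp(v) == 0:
            forced = True
            notes.append(f"group {name!r} has zero variance; nonparametric test forced")
            shapiro_p[name] = math.nan
        else:
            shapiro_p[name] = float(sps.shapiro(v).pvalue)
    try:
        levene_p = float(sps.levene(*groups.values(), center="median").pvalue)
    except ValueError:
        levene_p = math.nan
        forced = True
        notes.append("Levene's test undefined; nonparametric test forced")

    if forced:
        parametric = False
    else:
        parametric = all(p > alpha_assumption for p in shapiro_p.values()) and levene_p > alpha_assumption
    name = (PARAMETRIC_TESTS if parametric else NONPARAMETRIC_TESTS)[which]
    return TestSelection(
        test_name=name,
        parametric=parametric,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        forced_nonparametric=forced,
        notes=notes,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving.

    Sorted raw p-values are multiplied by (m - rank), a running maximum
    enforces monotonicity, results are capped at 1 and mapped back to the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _omnibus(groups: dict[str, np.ndarray], selection: TestSelection) -> tuple[float, float]:
    values = list(groups.values())
    if selection.test_name == "t-test":
        res = sps.ttest_ind(*values)
    elif selection.test_name == "one-way ANOVA":
        res = sps.f_oneway(*values)
    elif selection.test_name == "Mann-Whitney U":
        res = sps.mannwhitneyu(*values, alternative="two-sided")
    else:
        res = sps.kruskal(*values)
    return float(res.statistic), float(res.pvalue)


def _posthoc(groups: dict[str, np.ndarray], selection: TestSelection, reference_group: str | None) -> pd.DataFrame:
    names = list(groups)
    pairs = list(combinations(names, 2))
    if selection.parametric and len(names) > 2:
        flat = np.concatenate([groups[n] for n in names])
        labels = np.concatenate([[n] * groups[n].size for n in names])
        tk = pairwise_tukeyhsd(flat, labels)
        # statsmodels orders pairs as combinations of the sorted group names
        tk_pairs = list(combinations(list(tk.groupsunique), 2))
        adj = {frozenset(pr): float(p) for pr, p in zip(tk_pairs, tk.pvalues)}
        rows = [
            {"group1": a, "group2": b, "raw_p": math.nan, "adj_p": adj[frozenset((a, b))], "method": "Tukey-Kramer"}
            for a, b in pairs
        ]
    else:
        if selection.parametric:
            raw = [float(sps.ttest_ind(groups[a], groups[b]).pvalue) for a, b in pairs]
            method = "t-test"
        else:
            raw = [
                float(sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue)
                for a, b in pairs
            ]
            method = "Mann-Whitney U + Holm"
        adj = holm_adjust(raw) if len(raw) > 1 else np.asarray(raw)
        rows = [
            {"group1": a, "group2": b, "raw_p": r, "adj_p": float(q), "method": method}
            for (a, b), r, q in zip(pairs, raw, adj)
        ]
    df = pd.DataFrame(rows)
    if reference_group is not None:
        if reference_group not in names:
            raise ValueError(f"reference group {reference_group!r} not among the groups")
        df["reported"] = (df["group1"] == reference_group) | (df["group2"] == reference_group)
    else:
        df["reported"] = True
    return df


def run_comparison(
    data: dict,
    reference_group: str | None = None,
    alpha_assumption: float = DEFAULT_ASSUMPTION_ALPHA,
) -> TestReport:
    """Omnibus test plus all-pairs post hoc with multiplicity correction.

    Adjustment always spans all pairs; ``reference_group`` only controls
    which comparisons are marked as reported.
    """
    groups = _as_groups(data)
    selection = select_test(groups, alpha_assumption)
    statistic, p_value = _omnibus(groups, selection)
    posthoc = _posthoc(groups, selection, reference_group)
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": int(v.size),
                "mean": float(np.mean(v)),
                "sem": float(np.std(v, ddof=1) / math.sqrt(v.size)),
            }
            for name, v in groups.items()
        ]
    )
    return TestReport(
        test_name=selection.test_name,
        statistic=statistic,
        p_value=p_value,
        selection=selection,
        posthoc=posthoc,
        summary=summary,
    )


def chi_square_ratio_test(observed_counts, expected_ratio) -> tuple[float, float]:
    """Goodness-of-fit of observed counts against an expected ratio.

    Used e.g. for Mendelian survival ratios: ``expected_ratio`` is
    normalised to the observed total.
    """
    obs = np.asarray(observed_counts, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed and expected must have the same length")
    expected = ratio / ratio.sum() * obs.sum()
    res = sps.chisquare(obs, expected)
    return float(res.statistic), float(res.pvalue)
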