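"""Univariate group statistics for imaging features.

Each feature is compared across tumour groups with a normality-gated
omnibus test: one-way ANOVA when every group passes Shapiro–Wilk at
alpha = 0.05, Kruskal–Wallis otherwise.  Post-hoc pairwise comparisons use
Tukey HSD after ANOVA and a rank-based Dunn test (Bonferroni-adjusted)
after Kruskal–Wallis; a flag forces Tukey in both branches.  Significance
across the feature battery is Bonferroni-corrected by the number of
features tested, and discrimination of each class pair is summarised by
the Mann–Whitney AUC.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "normality_gate",
    "gated_omnibus",
    "compare_groups",
    "roc_auc",
    "dunn_posthoc",
    "univariate_battery",
    "GroupComparison",
]

log = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of one feature's group comparison."""

    test: str                      # "anova" | "kruskal"
    p_value: float
    pairwise_p: dict[tuple[str, str], float]
    significant_bonferroni: bool
    alpha_adjusted: float
    auc: dict[tuple[str, str], float] = field(default_factory=dict)


def normality_gate(groups: dict[str, np.ndarray], alpha: float = SHAPIRO_ALPHA) -> str:
    """Choose the omnibus test: "anova" if every group passes Shapiro–Wilk,
    else "kruskal".  Groups too small for the test (< 3) force the
    non-parametric branch."""
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            log.info("group %s has n=%d < 3; falling back to Kruskal–Wallis",
                     name, vals.size)
            return "kruskal"
        if np.ptp(vals) == 0:
            return "kruskal"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.shapiro(vals)
        if p < alpha:
            return "kruskal"
    return "anova"


def roc_auc(values: np.ndarray, labels: np.ndarray, positive) -> float:
    """Mann–Whitney AUC of ``values`` for separating ``positive`` from the
    rest; ties count one half.  Reported as-is for the stated positive class
    (values below 0.5 mean the positive class tends to score lower) —
    no folding to max(a, 1-a)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def gated_omnibus(groups: dict[str, np.ndarray]) -> tuple[str, float]:
    """Normality-gated omnibus test only (no post-hoc, no AUC): returns
    ("anova" | "kruskal", p).  The cheap core for simulation studies."""
    if all(np.ptp(np.asarray(v, dtype=float)) == 0 for v in groups.values()):
        return "kruskal", 1.0
    test = normality_gate(groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "anova":
            _, p = sps.f_oneway(*groups.values())
        else:
            _, p = sps.kruskal(*groups.values())
    return test, (float(p) if np.isfinite(p) else 1.0)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise test with a tie correction, Bonferroni
    adjusted over the pairs (the post-hoc companion to Kruskal–Wallis)."""
    names = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    n = all_vals.size
    ranks = sps.rankdata(all_vals)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    out = {}
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out[(a, b)] = float(min(1.0, p * len(pairs)))
    return out


def compare_groups(
    values: np.ndarray,
    labels: np.ndarray,
    n_features_tested: int = 1,
    alpha: float = 0.05,
    force_tukey: bool = False,
    posthoc: bool = True,
) -> GroupComparison:
    """Omnibus + post-hoc comparison of one feature across groups, with
    Bonferroni adjustment ``alpha / n_features_tested`` over the battery.

    A constant feature is untestable and returned with p = 1.  Pairwise
    post-hoc tests can be skipped (``posthoc=False``) when only the omnibus
    decision and AUCs are needed, e.g. inside fold-wise feature selection.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    groups = {g: values[labels == g] for g in names}
    alpha_adj = alpha / n_features_tested

    auc = {
        pair: roc_auc(
            values[np.isin(labels, pair)], labels[np.isin(labels, pair)], pair[0]
        )
        for pair in itertools.combinations(names, 2)
    }

    if np.ptp(values) == 0:
        log.info("constant feature; p set to 1")
        pairwise = {pair: 1.0 for pair in itertools.combinations(names, 2)}
        return GroupComparison("kruskal", 1.0, pairwise, False, alpha_adj, auc)

    test, p = gated_omnibus(groups)

    if not posthoc:
        pairwise = {}
    elif test == "anova" or force_tukey:
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        # result-table rows carry the (group1, group2) names in columns 0, 1
        pairwise = {
            (row[0], row[1]): float(pv)
            for row, pv in zip(res._results_table.data[1:], res.pvalues)
        }
    else:
        pairwise = dunn_posthoc(groups)

    return GroupComparison(
        test=test,
        p_value=float(p),
        pairwise_p=pairwise,
        significant_bonferroni=bool(p < alpha_adj),
        alpha_adjusted=alpha_adj,
        auc=auc,
    )


def univariate_battery(
    table: pd.DataFrame,
    feature_columns: list[str],
    label_column: str = "label",
    alpha: float = 0.05,
    force_tukey: bool = False,
    posthoc: bool = True,
) -> pd.DataFrame:
    """Run :func:`compare_groups` over every feature; returns a tidy frame
    with one row per feature (test used, omnibus p, Bonferroni flag,
    pairwise p's and AUCs as nested dicts, and the best pairwise
    discrimination ``max |AUC - 0.5|``)."""
    n = len(feature_columns)
    rows = []
    for col in feature_columns:
        cmp_ = compare_groups(
            table[col].to_numpy(), table[label_column].to_numpy(),
            n_features_tested=n, alpha=alpha, force_tukey=force_tukey,
            posthoc=posthoc,
        )
        rows.append(
            {
                "feature": col,
                "test": cmp_.test,
                "p_value": cmp_.p_value,
                "significant_bonferroni": cmp_.significant_bonferroni,
                "alpha_adjusted": cmp_.alpha_adjusted,
                "pairwise_p": cmp_.pairwise_p,
                "auc": cmp_.auc,
                "max_auc_distance": max(
                    abs(a - 0.5) for a in cmp_.auc.values()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
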