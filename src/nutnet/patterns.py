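"""Abundance-of-consumption transform and dietary-pattern discovery.

Borrowing the relative-abundance idea from ecology, each subject's food
group intakes (grams/day) are rescaled to fractions of that subject's
total daily intake, so the profile describes the *composition* of the
diet rather than its volume.  Dietary patterns are then found by
unsupervised agglomerative clustering of the abundance rows (Ward's
minimum-variance criterion on Euclidean distances), and each pattern is
profiled by its mean +/- SD abundance per food group with a per-group
one-way ANOVA across patterns (Holm-Bonferroni adjusted over groups).

Clustering operates on the raw fractions in [0, 1]; optional per-group
z-scoring is available but off by default, since composition profiles
are already on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .stats import chi_square_table, holm_adjust

__all__ = [
    "PatternsError",
    "PatternAssignment",
    "PatternProfile",
    "abundance_transform",
    "cluster_patterns",
    "pattern_profile",
    "pattern_composition",
    "silhouette_scan",
]

ROW_SUM_TOL = 1e-9


class PatternsError(ValueError):
    """Invalid input to the pattern-analysis stage."""


@dataclass
class PatternAssignment:
    """Subject-to-pattern labels plus the full Ward linkage tree."""

    labels: pd.Series  # index = subject id, values 1..k
    linkage: np.ndarray  # scipy linkage matrix (Ward, Euclidean)
    k: int

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class PatternProfile:
    """Per-pattern abundance summary with across-pattern ANOVA."""

    mean: pd.DataFrame  # pattern x group
    sd: pd.DataFrame  # pattern x group (ddof=1; singletons -> 0)
    anova: pd.DataFrame  # group, F, p_raw, p_holm
    singleton_patterns: list


def abundance_transform(intake: pd.DataFrame) -> pd.DataFrame:
    """Convert grams/day to fractions of each subject's total intake.

    Every row of the result sums to 1.  Subjects whose total intake is
    zero have no defined composition and are reported by id rather than
    propagated as NaN.
    """
    values = intake.to_numpy(dtype=float)
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise PatternsError("intakes must be finite and nonnegative")
    totals = values.sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        ids = list(intake.index[zero])
        raise PatternsError(f"zero total intake for subjects: {ids}")
    out = intake.div(totals, axis=0)
    return out


def cluster_patterns(
    abundance: pd.DataFrame, k: int = 4, standardize: bool = False
) -> PatternAssignment:
    """Ward hierarchical clustering of abundance rows into k patterns.

    The tree is built with Ward's criterion on Euclidean distances and cut
    at ``k`` clusters.  Labels are renumbered 1..k by first occurrence in
    subject order, making the assignment deterministic for a given input
    ordering (SciPy breaks merge ties by lowest cluster index).
    """
    n = len(abundance)
    if k < 2 or k > n:
        raise PatternsError(f"k must lie in [2, n={n}], got {k}")
    X = abundance.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # Renumber by first occurrence so labels do not depend on scipy internals.
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([remap[l] for l in raw], index=abundance.index, name="pattern")
    return PatternAssignment(labels=labels, linkage=Z, k=len(remap))


def pattern_profile(
    abundance: pd.DataFrame, assignment: PatternAssignment
) -> PatternProfile:
    """Mean +/- SD abundance per (pattern, food group) with per-group ANOVA.

    The one-way ANOVA tests, for each food group, whether mean abundance
    differs across patterns; p-values are Holm-Bonferroni adjusted over
    the food groups.  Patterns with a single subject contribute SD = 0
    and are listed in ``singleton_patterns``.
    """
    labels = assignment.labels.reindex(abundance.index)
    if labels.isna().any():
        raise PatternsError("assignment does not cover all subjects")
    pats = sorted(labels.unique())
    mean = abundance.groupby(labels).mean()
    sd = abundance.groupby(labels).std(ddof=1).fillna(0.0)
    singletons = [p for p in pats if (labels == p).sum() == 1]

    rows = []
    for group in abundance.columns:
        samples = [abundance.loc[labels == p, group].to_numpy() for p in pats]
        pooled = abundance[group].to_numpy()
        if np.allclose(pooled, pooled[0]) or len(pats) < 2:
            f_stat, p_raw = 0.0, 1.0
        else:
            f_stat, p_raw = sps.f_oneway(*samples)
            if not np.isfinite(p_raw):
                f_stat, p_raw = 0.0, 1.0
        rows.append({"food_group": group, "F": float(f_stat), "p_raw": float(p_raw)})
    anova = pd.DataFrame(rows)
    anova["p_holm"] = holm_adjust(anova["p_raw"].to_numpy())
    return PatternProfile(mean=mean, sd=sd, anova=anova, singleton_patterns=singletons)


def pattern_composition(
    assignment: PatternAssignment, covariates: pd.DataFrame
) -> dict[str, dict]:
    """Pattern x covariate contingency tables with Pearson chi-square tests.

    For each categorical covariate column (sex, anthropometric status,
    DMPW, ...) returns the pattern-by-level count table, the chi-square
    statistic/df/p, and a low-expected-count flag (any expected cell < 5).
    """
    labels = assignment.labels.reindex(covariates.index)
    if labels.isna().any():
        raise PatternsError("assignment does not cover all covariate rows")
    out: dict[str, dict] = {}
    for col in covariates.columns:
        table = pd.crosstab(labels, covariates[col])
        obs = table.to_numpy(dtype=float)
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        stat, dof, p = chi_square_table(obs)
        out[col] = {
            "table": table,
            "statistic": stat,
            "df": dof,
            "p": p,
            "low_expected": bool(np.any(expected < 5)),
        }
    return out


def silhouette_scan(
    abundance: pd.DataFrame, k_range=range(2, 9)
) -> pd.DataFrame:
    """Mean silhouette width of the Ward partition for each candidate k.

    A transparency aid for choosing the number of patterns; the pipeline
    default (k = 4) is a convention, not an optimum this function enforces.
    """
    from sklearn.metrics import silhouette_score

    rows = []
    for k in k_range:
        if k >= len(abundance):
            continue
        labels = cluster_patterns(abundance, k=k).labels
        rows.append(
            {
                "k": k,
                "silhouette": float(
                    silhouette_score(abundance.to_numpy(), labels.to_numpy())
                ),
            }
        )
    return pd.DataFrame(rows)
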