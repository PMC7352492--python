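"""Group-comparison statistics and the multinomial dietary-pattern model.

Contents:

* Kruskal-Wallis with Dunn's pairwise post hoc z-tests (tie-corrected)
  and Holm-Bonferroni adjustment across pairs.
* Pearson chi-square for contingency tables.
* A weighted multinomial (baseline-category) logistic regression fit by
  Newton-Raphson, reporting odds ratios with Wald 95% CIs.  Sampling
  weights support the cluster-sampling designs these cohorts come from.
* Design effect Deff = 1 + (m_bar - 1) * ICC for cluster ("conglomerate")
  sampling, with the ICC estimated from one-way ANOVA variance components.
* A Monte-Carlo power calculation for detecting a fold-change in one
  food-group's intake between design groups with the Kruskal-Wallis test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError",
    "ConvergenceError",
    "ComparisonResult",
    "MultinomialFit",
    "DesignEffect",
    "holm_adjust",
    "kruskal_wallis_dunn",
    "chi_square_table",
    "frequency_table",
    "fit_multinomial",
    "fit_dietary_pattern_model",
    "cluster_weights",
    "estimate_icc",
    "design_effect",
    "design_effect_from_components",
    "power_simulation",
]


class StatsError(ValueError):
    """Invalid statistical input."""


class ConvergenceError(RuntimeError):
    """Model fit failed to converge (possible separation)."""


def holm_adjust(pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (monotone, capped at 1).

    Implemented directly (adj_(i) = cummax((m - i + 1) p_(i)) clipped at
    1) rather than through ``statsmodels.multipletests``, which carries
    per-call overhead that matters inside the bootstrap loop; the two
    agree to machine precision.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class ComparisonResult:
    """Outcome of a >=2-group comparison with post hoc pairwise tests."""

    test: str
    statistic: float
    pvalue: float
    group_summary: pd.DataFrame
    pairwise: pd.DataFrame | None = None


def _rank_tie_term(values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tied groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis_dunn(values, labels) -> ComparisonResult:
    """Kruskal-Wallis H test with Dunn's pairwise z-tests, Holm-adjusted.

    Dunn's statistic for groups i, j uses mean ranks of the pooled ranking
    with the tie correction folded into the variance:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where T = sum(t^3 - t) over tied value groups.  All-identical data
    short-circuits to p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise StatsError("values and labels must have equal length")
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) == 0 for s in samples):
        raise StatsError("every group needs at least one observation")

    summary = pd.DataFrame(
        {
            "group": groups,
            "n": [len(s) for s in samples],
            "median": [float(np.median(s)) for s in samples],
            "q1": [float(np.percentile(s, 25)) for s in samples],
            "q3": [float(np.percentile(s, 75)) for s in samples],
        }
    )

    if np.all(values == values[0]):
        pairs = pd.DataFrame(
            [
                {"group1": a, "group2": b, "z": 0.0, "p_raw": 1.0, "p_holm": 1.0}
                for a, b in combinations(groups, 2)
            ]
        )
        return ComparisonResult("kruskal-wallis", 0.0, 1.0, summary, pairs)

    stat, p = sps.kruskal(*samples)

    ranks = sps.rankdata(values)
    n_total = len(values)
    tie = _rank_tie_term(values)
    var_term = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    mean_ranks = {g: float(np.mean(ranks[labels == g])) for g in groups}
    sizes = {g: int(np.sum(labels == g)) for g in groups}
    rows = []
    for a, b in combinations(groups, 2):
        se = np.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group1": a, "group2": b, "z": float(z), "p_raw": p_raw})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    return ComparisonResult("kruskal-wallis", float(stat), float(p), summary, pairwise)


def chi_square_table(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table: (statistic, df, p).

    No continuity correction is applied.  A zero row or column marginal
    makes expected counts degenerate and raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise StatsError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise StatsError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise StatsError("zero row or column marginal")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def frequency_table(series: pd.Series, ndigits: int = 1) -> pd.DataFrame:
    """Counts and rounded percentages of a categorical column."""
    if len(series) == 0:
        raise StatsError("empty series")
    counts = series.value_counts()
    return pd.DataFrame(
        {
            "level": counts.index.to_numpy(),
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / len(series), ndigits),
        }
    )


# ---------------------------------------------------------------------------
# Multinomial (baseline-category) logistic regression
# ---------------------------------------------------------------------------


@dataclass
class MultinomialFit:
    """Weighted multinomial logit fit summarised as odds ratios."""

    table: pd.DataFrame  # outcome, term, coef, se, or_, ci_low, ci_high, p
    baseline: object
    loglik: float
    n_obs: int
    converged: bool
    coef: np.ndarray = field(repr=False)  # (J-1, K)
    cov: np.ndarray = field(repr=False)  # ((J-1)K, (J-1)K)
    outcome_levels: list = field(default_factory=list)
    terms: list = field(default_factory=list)


def _multinomial_newton(
    X: np.ndarray,
    y_idx: np.ndarray,
    n_levels: int,
    weights: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson for the baseline-category multinomial logit.

    ``y_idx`` holds outcome indices 0..J-1 with 0 the baseline.  Returns
    (beta (J-1, K), covariance, loglik, converged).  The covariance is the
    inverse observed information.
    """
    n, k = X.shape
    j1 = n_levels - 1
    beta = np.zeros((j1, k))
    onehot = np.zeros((n, n_levels))
    onehot[np.arange(n), y_idx] = 1.0
    w = weights

    def probs(b):
        eta = np.hstack([np.zeros((n, 1)), X @ b.T])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    loglik = -np.inf
    converged = False
    info = np.eye(j1 * k)
    for _ in range(max_iter):
        p = probs(beta)
        loglik = float(np.sum(w * np.log(np.clip(p[np.arange(n), y_idx], 1e-300, None))))
        resid = onehot[:, 1:] - p[:, 1:]  # n x (J-1)
        grad = (X.T @ (w[:, None] * resid)).T.ravel()  # (J-1)*K
        info = np.empty((j1 * k, j1 * k))
        for a in range(j1):
            for b_ in range(a, j1):
                wab = w * p[:, a + 1] * ((1.0 if a == b_ else 0.0) - p[:, b_ + 1])
                block = X.T @ (wab[:, None] * X)  # Fisher information contribution
                info[a * k : (a + 1) * k, b_ * k : (b_ + 1) * k] = block
                info[b_ * k : (b_ + 1) * k, a * k : (a + 1) * k] = block.T
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(j1 * k), grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # Damped update guards against overshoot early on.
        if np.max(np.abs(step)) > 10.0:
            step *= 10.0 / np.max(np.abs(step))
        beta = beta + step.reshape(j1, k)
        if np.max(np.abs(beta)) > 50.0:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 50): likely separation or an "
                "empty outcome/predictor cell"
            )
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ConvergenceError(f"information matrix not invertible: {err}") from err
    return beta, cov, loglik, converged


def fit_multinomial(
    outcome,
    design: pd.DataFrame,
    baseline=None,
    weights=None,
    conf_level: float = 0.95,
    on_separation: str = "raise",
) -> MultinomialFit:
    """Fit a weighted multinomial logit of ``outcome`` on a design matrix.

    Parameters
    ----------
    outcome : array-like
        Categorical outcome with >= 2 levels.
    design : DataFrame
        Numeric design matrix (include an ``intercept`` column explicitly
        or use :func:`fit_dietary_pattern_model` for the standard recipe).
    baseline : optional
        Outcome level used as the reference category (default: first level
        in sorted order).
    weights : array-like, optional
        Per-subject sampling weights (default 1).
    on_separation : {"raise", "warn"}
        (Quasi-)separation — a diverging coefficient or an essentially
        infinite Wald SE, typically from an empty outcome x predictor
        cell — raises :class:`ConvergenceError` by default; ``"warn"``
        instead emits a warning and marks the affected rows with
        ``identified = False`` in the result table.

    Returns
    -------
    MultinomialFit
        Odds ratios ``exp(coef)`` with Wald confidence intervals per
        (non-baseline outcome, term).
    """
    y = pd.Series(outcome).reset_index(drop=True)
    levels = sorted(y.unique(), key=str)
    if len(levels) < 2:
        raise StatsError("outcome needs at least 2 levels")
    if baseline is None:
        baseline = levels[0]
    if baseline not in levels:
        raise StatsError(f"baseline {baseline!r} not among outcome levels {levels}")
    ordered = [baseline] + [l for l in levels if l != baseline]
    y_idx = y.map({l: i for i, l in enumerate(ordered)}).to_numpy()

    X = design.to_numpy(dtype=float)
    if X.shape[0] != len(y):
        raise StatsError("outcome and design have different lengths")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise StatsError("weights must be nonnegative")

    beta, cov, loglik, converged = _multinomial_newton(X, y_idx, len(ordered), w)

    z = sps.norm.ppf(0.5 + conf_level / 2.0)
    k = X.shape[1]
    rows = []
    for j, level in enumerate(ordered[1:]):
        for t, term in enumerate(design.columns):
            coef = beta[j, t]
            se = float(np.sqrt(cov[j * k + t, j * k + t]))
            zval = coef / se if se > 0 else np.inf
            identified = abs(coef) < 15.0 and se < 50.0
            with np.errstate(over="ignore"):
                rows.append(
                    {
                        "outcome": level,
                        "term": term,
                        "coef": float(coef),
                        "se": se,
                        "or": float(np.exp(coef)),
                        "ci_low": float(np.exp(coef - z * se)),
                        "ci_high": float(np.exp(coef + z * se)),
                        "p": float(2.0 * sps.norm.sf(abs(zval))),
                        "identified": identified,
                    }
                )
    table = pd.DataFrame(rows)
    bad = table.loc[~table["identified"], ["outcome", "term"]]
    if len(bad):
        cells = [f"{r.outcome}:{r.term}" for r in bad.itertuples(index=False)]
        message = (
            "separation or empty outcome x predictor cell; non-identified "
            f"coefficients for {cells}"
        )
        if on_separation == "raise":
            raise ConvergenceError(message)
        import warnings

        warnings.warn(message)
    return MultinomialFit(
        table=table,
        baseline=baseline,
        loglik=loglik,
        n_obs=len(y),
        converged=converged,
        coef=beta,
        cov=cov,
        outcome_levels=ordered,
        terms=list(design.columns),
    )


def _dummies(series: pd.Series, reference, prefix: str) -> pd.DataFrame:
    levels = [l for l in sorted(series.unique(), key=str) if l != reference]
    if reference not in set(series):
        raise StatsError(f"reference level {reference!r} absent from {prefix}")
    return pd.DataFrame(
        {f"{prefix}[{l}]": (series == l).astype(float).to_numpy() for l in levels}
    )


def fit_dietary_pattern_model(
    patterns,
    dmpw,
    sex,
    status,
    weights=None,
    baseline_pattern=2,
    dmpw_ref: str = "Agreed",
    sex_ref: str = "male",
    status_ref: str = "normal",
    on_separation: str = "raise",
) -> MultinomialFit:
    """Multinomial model of dietary pattern on DMPW, adjusted for sex and status.

    The outcome is the pattern label with the configured baseline pattern
    (default pattern 2 — the profile with no predominant food group and
    the lowest abundances).  The exposure is DMPW with "Agreed" as
    reference; sex and anthropometric status enter as adjustment dummies.
    """
    patterns = pd.Series(patterns).reset_index(drop=True)
    design = pd.concat(
        [
            pd.DataFrame({"intercept": np.ones(len(patterns))}),
            _dummies(pd.Series(dmpw).reset_index(drop=True), dmpw_ref, "dmpw"),
            _dummies(pd.Series(sex).reset_index(drop=True), sex_ref, "sex"),
            _dummies(pd.Series(status).reset_index(drop=True), status_ref, "status"),
        ],
        axis=1,
    )
    return fit_multinomial(
        patterns,
        design,
        baseline=baseline_pattern,
        weights=weights,
        on_separation=on_separation,
    )


def cluster_weights(cluster_ids) -> np.ndarray:
    """Cluster-size-proportional sampling weights, normalised to sum to n.

    Each subject gets weight inversely proportional to its cluster's size,
    so every conglomerate contributes equally regardless of how many
    students were enrolled from it.
    """
    ids = pd.Series(cluster_ids).reset_index(drop=True)
    sizes = ids.map(ids.value_counts())
    w = 1.0 / sizes.to_numpy(dtype=float)
    return w * len(ids) / w.sum()


# ---------------------------------------------------------------------------
# Design effect
# ---------------------------------------------------------------------------


@dataclass
class DesignEffect:
    """Design effect of cluster sampling: Deff = 1 + (m_bar - 1) * ICC."""

    deff: float
    icc: float
    mean_cluster_size: float
    n_clusters: int
    #: Deff > 3 flags strong intra-conglomerate homogeneity, i.e. the
    #: sampling design may have influenced the association tested.
    sampling_influenced: bool


def estimate_icc(values, cluster_ids) -> float:
    """One-way ANOVA intraclass correlation, clamped at >= 0.

    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW) with n0 the ANOVA-adjusted
    mean cluster size n0 = (N - sum m_i^2 / N) / (k - 1).
    """
    values = np.asarray(values, dtype=float)
    ids = np.asarray(cluster_ids)
    clusters = np.unique(ids)
    if len(clusters) < 2:
        raise StatsError("need at least 2 clusters to estimate an ICC")
    n_total = len(values)
    grand = values.mean()
    ssb = ssw = 0.0
    sizes = []
    for c in clusters:
        grp = values[ids == c]
        sizes.append(len(grp))
        ssb += len(grp) * (grp.mean() - grand) ** 2
        ssw += float(np.sum((grp - grp.mean()) ** 2))
    sizes = np.asarray(sizes, dtype=float)
    k = len(clusters)
    msb = ssb / (k - 1)
    dfw = n_total - k
    if dfw <= 0:
        raise StatsError("no within-cluster degrees of freedom")
    msw = ssw / dfw
    n0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    denom = msb + (n0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float(max(0.0, (msb - msw) / denom))


def design_effect_from_components(mean_cluster_size: float, icc: float) -> float:
    """Deff = 1 + (m_bar - 1) * ICC."""
    if mean_cluster_size < 1:
        raise StatsError("mean cluster size must be >= 1")
    if not 0.0 <= icc <= 1.0:
        raise StatsError("ICC must lie in [0, 1]")
    return 1.0 + (mean_cluster_size - 1.0) * icc


def design_effect(outcome, cluster_ids) -> DesignEffect:
    """Design effect of the cluster sampling for an outcome variable.

    Numeric outcomes use the one-way ANOVA ICC directly.  Categorical
    outcomes (e.g. the dietary-pattern label) are expanded to one binary
    indicator per level; the reported ICC is the mean over levels, giving
    a single outcome-level Deff.
    """
    ids = np.asarray(cluster_ids)
    clusters, counts = np.unique(ids, return_counts=True)
    if len(clusters) < 2:
        raise StatsError("design effect undefined for a single cluster")
    series = pd.Series(outcome).reset_index(drop=True)
    if pd.api.types.is_numeric_dtype(series):
        icc = estimate_icc(series.to_numpy(dtype=float), ids)
    else:
        iccs = [
            estimate_icc((series == level).to_numpy(dtype=float), ids)
            for level in sorted(series.unique(), key=str)
        ]
        icc = float(np.mean(iccs))
    m_bar = float(np.mean(counts))
    deff = design_effect_from_components(m_bar, icc)
    return DesignEffect(
        deff=deff,
        icc=icc,
        mean_cluster_size=m_bar,
        n_clusters=len(clusters),
        sampling_influenced=deff > 3.0,
    )


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


def power_simulation(
    n_per_group: int = 50,
    fold_change: float = 2.0,
    alpha: float = 0.01,
    n_groups: int = 3,
    cv: float = 1.2,
    reps: int = 500,
    seed: int | None = None,
) -> float:
    """Monte-Carlo power of a Kruskal-Wallis fold-change detection.

    Intakes are log-normal with a common coefficient of variation ``cv``;
    one group's median is shifted by ``fold_change`` relative to the
    others.  Power is the fraction of ``reps`` simulations in which the
    Kruskal-Wallis p-value falls below ``alpha``.
    """
    if n_per_group <= 1 or fold_change <= 0 or n_groups < 2:
        raise StatsError("n_per_group > 1, fold_change > 0, n_groups >= 2 required")
    if not 0.0 < alpha < 1.0:
        raise StatsError("alpha must be in (0, 1)")
    if reps < 100:
        import warnings

        warnings.warn("fewer than 100 replicates gives a noisy power estimate")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    shift = float(np.log(fold_change))
    hits = 0
    for _ in range(reps):
        groups = [
            np.exp(rng.normal(shift if g == 0 else 0.0, sigma, n_per_group))
            for g in range(n_groups)
        ]
        if fold_change == 1.0 and len({tuple(g) for g in groups}) == 1:
            continue
        _, p = sps.kruskal(*groups)
        if p < alpha:
            hits += 1
    return hits / reps
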