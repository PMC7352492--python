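"""Bootstrap-stabilized signed Spearman correlation networks.

For each subject subgroup (e.g. the three DMPW strata) a food-group
co-consumption network is built from the Spearman rank correlations of
total gram intakes:

1. ``spearman_matrix`` — tie-corrected rho with two-sided p-values from
   the t approximation; a constant food group yields rho = 0, p = 1 and a
   degeneracy flag instead of NaN.
2. ``bootstrap_ensemble`` — B resamples of subjects with replacement
   (default B = 100), each of the original size, with a correlation
   matrix per replicate.
3. ``stable_edges`` — an edge between two food groups survives when, in
   at least ``persistence`` x B replicates, it *simultaneously* has
   (i) Holm-adjusted p < alpha over the G(G-1)/2 tests of that replicate,
   (ii) |rho| > rho_threshold, and (iii) a consistent sign.  The retained
   edge carries the median rho over its qualifying replicates.

Network density is L / (N(N-1)/2) — retained edges over all possible
pairs — and ``compare_densities`` contrasts the per-replicate density
distributions between subgroups with Kruskal-Wallis + Dunn tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import ComparisonResult, holm_adjust, kruskal_wallis_dunn

__all__ = [
    "NetworkError",
    "CorrelationMatrix",
    "BootstrapEnsemble",
    "StableNetwork",
    "spearman_matrix",
    "bootstrap_ensemble",
    "stable_edges",
    "replicate_densities",
    "network_density",
    "node_degrees",
    "compare_densities",
]


class NetworkError(ValueError):
    """Invalid input to the network stage."""


@dataclass
class CorrelationMatrix:
    """Spearman rho / p matrices over food groups for one subject subset."""

    rho: np.ndarray
    p: np.ndarray
    nodes: list[str]
    #: True for food groups that were constant in the subset (rho forced
    #: to 0, p to 1 for every pair touching them).
    degenerate: np.ndarray


@dataclass
class BootstrapEnsemble:
    """B replicate correlation matrices from subject resampling."""

    replicates: list[CorrelationMatrix]
    indices: np.ndarray = field(repr=False)  # B x n resampled row indices
    nodes: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_boot(self) -> int:
        return len(self.replicates)


@dataclass
class StableNetwork:
    """Signed food-group network surviving the three-criterion filter."""

    nodes: list[str]
    edges: pd.DataFrame  # node1, node2, sign, median_rho, persistence
    n_boot: int
    rho_threshold: float
    alpha: float
    persistence: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        return network_density(self.n_edges, len(self.nodes))

    def to_networkx(self):
        """Export as a networkx Graph with sign/rho/persistence edge data."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.node1,
                row.node2,
                sign=row.sign,
                median_rho=row.median_rho,
                persistence=row.persistence,
            )
        return g


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    return arr, [f"g{i}" for i in range(arr.shape[1])]


def spearman_matrix(data) -> CorrelationMatrix:
    """Tie-corrected Spearman correlation matrix with two-sided p-values.

    ``data`` is a subjects x food-groups table (DataFrame or array) with
    at least 4 subjects and 2 groups.  Constant columns are flagged as
    degenerate with rho = 0, p = 1 on their pairs.
    """
    X, nodes = _as_matrix(data)
    if X.shape[0] < 4:
        raise NetworkError(f"need at least 4 subjects, got {X.shape[0]}")
    return _spearman_core(X, nodes)


def _spearman_core(X: np.ndarray, nodes: list[str]) -> CorrelationMatrix:
    """Spearman rho/p without the minimum-n guard (bootstrap replicates of
    tiny subsets degrade to degenerate flags instead of errors)."""
    n, g = X.shape
    if g < 2:
        raise NetworkError(f"need at least 2 food groups, got {g}")
    degenerate = np.array([np.all(col == col[0]) for col in X.T])
    if n < 2 or degenerate.all():
        rho = np.eye(g)
        p = np.ones((g, g)) - np.eye(g)
        return CorrelationMatrix(
            rho=rho, p=p, nodes=nodes, degenerate=np.ones(g, dtype=bool)
        )

    ranks = sps.rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)

    # Two-sided p via the t approximation with n-2 df.
    df = max(n - 2, 1)
    r = np.clip(rho, -0.9999999999, 0.9999999999)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 0.0)
    for i in np.where(degenerate)[0]:
        rho[i, :] = rho[:, i] = 0.0
        p[i, :] = p[:, i] = 1.0
        rho[i, i] = 1.0
        p[i, i] = 0.0
    return CorrelationMatrix(rho=rho, p=p, nodes=nodes, degenerate=degenerate)


def bootstrap_ensemble(
    data, n_boot: int = 100, seed: int | None = None, rng: np.random.Generator | None = None
) -> BootstrapEnsemble:
    """Resample subjects with replacement B times and correlate each replicate."""
    if n_boot < 1:
        raise NetworkError(f"n_boot must be >= 1, got {n_boot}")
    X, nodes = _as_matrix(data)
    n = X.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    indices = rng.integers(0, n, size=(n_boot, n))
    replicates = [_spearman_core(X[idx], nodes) for idx in indices]
    return BootstrapEnsemble(replicates=replicates, indices=indices, nodes=nodes, seed=seed)


def _pair_index(g: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(g, k=1)


def _qualifying_signs(
    matrix: CorrelationMatrix, rho_threshold: float, alpha: float, adjust: bool
) -> np.ndarray:
    """Per-pair qualification sign (-1, 0, +1) for one replicate.

    A pair qualifies when its (optionally Holm-adjusted) p-value is below
    alpha AND |rho| strictly exceeds rho_threshold; the returned sign is
    the sign of rho for qualifying pairs, else 0.
    """
    iu, ju = _pair_index(len(matrix.nodes))
    rho = matrix.rho[iu, ju]
    p = matrix.p[iu, ju]
    p_eff = holm_adjust(p) if adjust else p
    qual = (p_eff < alpha) & (np.abs(rho) > rho_threshold)
    return np.where(qual, np.sign(rho), 0.0)


def stable_edges(
    ensemble: BootstrapEnsemble,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
    persistence: float = 0.5,
    adjust: bool = True,
) -> StableNetwork:
    """Apply the three-criterion bootstrap filter and return the network.

    An edge is retained iff one sign qualifies (p and |rho| criteria met
    with that sign) in at least ``persistence * n_boot`` replicates; a
    replicate qualifying with the opposite sign does not count.  Exactly
    meeting the threshold (e.g. 50 of 100 at persistence 0.5) retains the
    edge.  ``adjust=False`` turns off the within-replicate Holm
    adjustment of criterion (i).
    """
    if ensemble.n_boot < 1:
        raise NetworkError("empty bootstrap ensemble")
    if not 0.0 < persistence <= 1.0:
        raise NetworkError("persistence must be in (0, 1]")
    g = len(ensemble.nodes)
    iu, ju = _pair_index(g)
    n_pairs = len(iu)
    b = ensemble.n_boot

    signs = np.empty((b, n_pairs))
    rhos = np.empty((b, n_pairs))
    for r, rep in enumerate(ensemble.replicates):
        signs[r] = _qualifying_signs(rep, rho_threshold, alpha, adjust)
        rhos[r] = rep.rho[iu, ju]

    need = persistence * b - 1e-9
    pos_count = (signs > 0).sum(axis=0)
    neg_count = (signs < 0).sum(axis=0)
    rows = []
    for k in range(n_pairs):
        np_, nn_ = pos_count[k], neg_count[k]
        if max(np_, nn_) < need:
            continue
        if np_ >= need and nn_ >= need:
            # Both signs persistent (possible only when persistence <= 0.5):
            # keep the majority sign; break exact ties by the overall median.
            if np_ > nn_:
                sign = 1
            elif nn_ > np_:
                sign = -1
            else:
                sign = 1 if np.median(rhos[:, k]) >= 0 else -1
        else:
            sign = 1 if np_ >= need else -1
        mask = signs[:, k] == sign
        rows.append(
            {
                "node1": ensemble.nodes[iu[k]],
                "node2": ensemble.nodes[ju[k]],
                "sign": int(sign),
                "median_rho": float(np.median(rhos[mask, k])),
                "persistence": float(mask.sum() / b),
            }
        )
    edges = pd.DataFrame(
        rows, columns=["node1", "node2", "sign", "median_rho", "persistence"]
    )
    return StableNetwork(
        nodes=list(ensemble.nodes),
        edges=edges,
        n_boot=b,
        rho_threshold=rho_threshold,
        alpha=alpha,
        persistence=persistence,
    )


def replicate_densities(
    ensemble: BootstrapEnsemble,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
    adjust: bool = True,
) -> np.ndarray:
    """Network density of each bootstrap replicate (criteria i-ii applied within).

    The B values form the within-group density distribution used by
    :func:`compare_densities`.
    """
    g = len(ensemble.nodes)
    n_pairs = g * (g - 1) // 2
    out = np.empty(ensemble.n_boot)
    for r, rep in enumerate(ensemble.replicates):
        qual = _qualifying_signs(rep, rho_threshold, alpha, adjust)
        out[r] = np.count_nonzero(qual) / n_pairs
    return out


def network_density(n_edges: int, n_nodes: int) -> float:
    """Density = L / (N(N-1)/2): retained edges over all possible pairs."""
    if n_nodes < 2:
        raise NetworkError(f"need at least 2 nodes, got {n_nodes}")
    total = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= total:
        raise NetworkError(f"edge count {n_edges} outside [0, {total}]")
    return n_edges / total


def node_degrees(network: StableNetwork) -> pd.Series:
    """Number of retained correlations per food group, descending."""
    counts = pd.Series(0, index=pd.Index(network.nodes, name="food_group"), dtype=int)
    for row in network.edges.itertuples(index=False):
        counts[row.node1] += 1
        counts[row.node2] += 1
    return counts.sort_values(ascending=False, kind="stable")


def compare_densities(densities_by_group: dict[str, np.ndarray]) -> ComparisonResult:
    """Kruskal-Wallis + Dunn comparison of per-replicate density samples."""
    if len(densities_by_group) < 2:
        raise NetworkError("need at least 2 groups of density samples")
    for name, d in densities_by_group.items():
        if len(np.asarray(d)) < 2:
            raise NetworkError(f"group {name!r} has fewer than 2 density samples")
    values = np.concatenate([np.asarray(d, dtype=float) for d in densities_by_group.values()])
    labels = np.concatenate(
        [np.repeat(name, len(np.asarray(d))) for name, d in densities_by_group.items()]
    )
    return kruskal_wallis_dunn(values, labels)
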