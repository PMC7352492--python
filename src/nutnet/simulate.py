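"""Synthetic adolescent cohorts with planted, recoverable structure.

The generator emulates the kind of cross-sectional school survey this
pipeline targets: ~1,500 adolescents sampled by conglomerate (school /
class clusters), each with anthropometric measurements, a self-perceived
weight response, and a semi-quantitative FFQ.  Its defaults reproduce the
published marginal frequencies of such a cohort (57.1% female; DMPW
68.3% Agreed / 19.7% Underestimated / 12.0% Overestimated; status 77.2%
eutrophic, 8.8% overweight, 5.9% obese) and Table-2-scale gram intakes
over 14 food groups.

Planted structure, recorded in :class:`PlantedTruth` for recovery tests:

* a dietary-pattern label per subject (mixture of log-intake centroids);
* a DMPW label per subject, realised by *inverting* the ordinal
  truth table — the emitted (status, perception) pair always
  re-classifies to the planted label;
* per-DMPW-stratum signed Spearman correlation structure among food
  groups, imposed exactly via a Gaussian copula on the log scale
  (rank correlations are invariant under the monotone exp transform,
  and target Spearman rhos are converted to Pearson correlations of the
  normal scores via rho_P = 2 sin(pi rho_S / 6) before sampling, so the
  planted values are calibrated rather than approximate);
* school-cluster ids whose influence on the pattern label is controlled
  by an intra-cluster correlation (Dirichlet-perturbed mixture weights
  with concentration (1 - icc) / icc).

All draws are deterministic given the config seed; independent stages
draw from independently derived substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import ffq as ffq_mod
from .anthropometry import classify_status

__all__ = [
    "FOOD_GROUPS",
    "BASE_MEDIANS",
    "GeneratorConfigError",
    "GeneratorConfig",
    "PlantedTruth",
    "default_pattern_centroids",
    "default_correlation_spec",
    "default_item_map",
    "nearest_psd",
    "spearman_to_pearson",
    "pearson_to_spearman",
    "generate_cohort",
    "generate_ffq_intakes",
    "generate_ffq_responses",
]

#: Default 14 food groups (Northeast-Brazil FFQ style schema).
FOOD_GROUPS = (
    "sugar_and_sweets",
    "sweetened_beverages",
    "processed_meat",
    "fast_food",
    "brazilian_dishes",
    "oils",
    "milk_dairy",
    "meat",
    "rice_cereals",
    "roots",
    "beans_legumes",
    "vegetables",
    "fruits",
    "coffee_tea",
)

#: Realistic grams/day medians per group (cosmetic scale anchor only).
BASE_MEDIANS = (
    243.3, 480.4, 11.0, 170.4, 97.3, 29.3, 166.4,
    122.7, 460.7, 24.7, 148.8, 67.3, 465.7, 106.7,
)

DMPW_ORDER = ("Agreed", "Underestimated", "Overestimated")
STATUS_ORDER = ("underweight", "normal", "overweight", "obese")
#: Which measured statuses can realise each DMPW label under the ordinal
#: truth table (underweight cannot be underestimated; overweight/obese
#: cannot be overestimated).
FEASIBLE_STATUS = {
    "Agreed": STATUS_ORDER,
    "Underestimated": ("normal", "overweight", "obese"),
    "Overestimated": ("underweight", "normal"),
}
_STATUS_BANDS = {
    "underweight": (0.0, 3.0),
    "normal": (3.0, 85.0),
    "overweight": (85.0, 97.0),
    "obese": (97.0, 100.0),
}
_MEASURED_LEVEL = {"underweight": 0, "normal": 1, "overweight": 2, "obese": 2}

_STAGE_IDS = {"cohort": 11, "intakes": 23, "responses": 37, "networks": 53, "model": 71}


class GeneratorConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for a named pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_IDS[stage]]))


def default_pattern_centroids(
    n_patterns: int = 4, groups: tuple[str, ...] = FOOD_GROUPS
) -> np.ndarray:
    """k x G matrix of mean log-intakes mirroring the qualitative pattern
    anatomy of this literature: one coffee/tea-led pattern, one uniformly
    low pattern, one legume-led pattern, one high-everything pattern."""
    base = np.log(np.asarray(BASE_MEDIANS[: len(groups)], dtype=float))
    if len(groups) != len(base):
        base = np.resize(np.log(np.asarray(BASE_MEDIANS)), len(groups))
    cents = np.tile(base, (n_patterns, 1))
    idx = {g: i for i, g in enumerate(groups)}

    def bump(k: int, group: str, amount: float) -> None:
        if k < n_patterns and group in idx:
            cents[k, idx[group]] += amount

    if n_patterns >= 2:
        cents[1] -= 0.5  # uniformly lowest abundances
    bump(0, "coffee_tea", 1.2)
    bump(0, "beans_legumes", 0.4)
    bump(2, "beans_legumes", 1.0)
    if n_patterns >= 4:
        cents[3] += 0.5
        bump(3, "sweetened_beverages", 0.4)
    return cents


def _edges_to_matrix(
    groups: tuple[str, ...], edges: list[tuple[str, str, float]]
) -> np.ndarray:
    idx = {g: i for i, g in enumerate(groups)}
    m = np.eye(len(groups))
    for a, b, rho in edges:
        i, j = idx[a], idx[b]
        m[i, j] = m[j, i] = rho
    return m


def default_correlation_spec(
    groups: tuple[str, ...] = FOOD_GROUPS,
) -> dict[str, np.ndarray]:
    """Per-DMPW-stratum target Spearman matrices.

    Agreed and Underestimated carry only positive planted correlations
    (block cliques of jointly eaten groups); Overestimated is sparser and
    contains negative blocks — roots inversely tied to oils and processed
    meat, vegetables to sweetened beverages — so inverse consumption
    trends are a recoverable feature of that stratum only.  Blocks are
    disjoint, keeping each matrix positive semi-definite by construction.
    """
    agreed = [
        ("rice_cereals", "beans_legumes", 0.65),
        ("rice_cereals", "meat", 0.6),
        ("rice_cereals", "brazilian_dishes", 0.6),
        ("beans_legumes", "meat", 0.6),
        ("beans_legumes", "brazilian_dishes", 0.6),
        ("meat", "brazilian_dishes", 0.6),
        ("sugar_and_sweets", "sweetened_beverages", 0.6),
        ("sugar_and_sweets", "milk_dairy", 0.6),
        ("sweetened_beverages", "milk_dairy", 0.6),
        ("fruits", "vegetables", 0.65),
        ("fast_food", "processed_meat", 0.6),
    ]
    under = [
        ("milk_dairy", "sugar_and_sweets", 0.65),
        ("milk_dairy", "sweetened_beverages", 0.6),
        ("sugar_and_sweets", "sweetened_beverages", 0.6),
        ("rice_cereals", "beans_legumes", 0.6),
        ("rice_cereals", "meat", 0.6),
        ("beans_legumes", "meat", 0.6),
        ("fruits", "vegetables", 0.6),
    ]
    over = [
        ("roots", "oils", -0.7),
        ("roots", "processed_meat", -0.55),
        ("vegetables", "sweetened_beverages", -0.6),
        ("rice_cereals", "meat", 0.6),
        ("rice_cereals", "fruits", 0.6),
    ]
    return {
        "Agreed": _edges_to_matrix(groups, agreed),
        "Underestimated": _edges_to_matrix(groups, under),
        "Overestimated": _edges_to_matrix(groups, over),
    }


def default_item_map(
    groups: tuple[str, ...] = FOOD_GROUPS, items_per_group: int = 3
) -> dict[str, str]:
    """Synthetic item-to-group map with ``items_per_group`` items each."""
    return {
        f"{g}_item{j + 1}": g for g in groups for j in range(items_per_group)
    }


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Pearson correlation of normal scores giving a target Spearman rho."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def pearson_to_spearman(rho_p: np.ndarray) -> np.ndarray:
    """Inverse of :func:`spearman_to_pearson`."""
    return 6.0 / np.pi * np.arcsin(np.asarray(rho_p, dtype=float) / 2.0)


def nearest_psd(
    matrix: np.ndarray, eps: float = 1e-10, max_shift: float = 0.075
) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the diagonal rescaled to 1
    (iterated a few times).  If any entry moves by more than ``max_shift``
    the requested structure is too inconsistent to plant faithfully and a
    :class:`GeneratorConfigError` is raised.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise GeneratorConfigError("correlation matrix is not symmetric")
    out = (m + m.T) / 2.0
    for _ in range(5):
        w, v = np.linalg.eigh(out)
        if w.min() >= eps:
            break
        w = np.clip(w, eps, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(out), eps, None))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    shift = float(np.max(np.abs(out - m)))
    if shift > max_shift:
        raise GeneratorConfigError(
            f"requested correlation structure is {shift:.3f} away from the "
            f"nearest PSD matrix (tolerance {max_shift}); relax the targets"
        )
    return out


@dataclass
class GeneratorConfig:
    """Conditions of the emulated study; see module docstring for defaults."""

    n_subjects: int = 1496
    sex_proportion_female: float = 0.571
    #: (Agreed, Underestimated, Overestimated)
    dmpw_proportions: tuple[float, float, float] = (0.683, 0.197, 0.120)
    #: (underweight, normal, overweight, obese) marginal targets.
    status_proportions: tuple[float, float, float, float] = (0.081, 0.772, 0.088, 0.059)
    food_groups: tuple[str, ...] = FOOD_GROUPS
    n_patterns: int = 4
    pattern_mixture_weights: tuple[float, ...] | None = None
    pattern_centroids: np.ndarray | None = None  # k x G mean log-intakes
    correlation_spec: dict[str, np.ndarray] | None = None
    noise_scale: float = 0.8  # SD of log intake around the centroid
    n_clusters: int = 30
    #: Intra-cluster correlation of the pattern label; the default lands
    #: the planted design effect near 1.12 at ~50 subjects per cluster.
    icc: float = 0.0025
    seed: int = 2020

    def __post_init__(self) -> None:
        if self.pattern_mixture_weights is None:
            self.pattern_mixture_weights = tuple(
                1.0 / self.n_patterns for _ in range(self.n_patterns)
            )
        if self.pattern_centroids is None:
            self.pattern_centroids = default_pattern_centroids(
                self.n_patterns, self.food_groups
            )
        else:
            self.pattern_centroids = np.asarray(self.pattern_centroids, dtype=float)
        if self.correlation_spec is None:
            self.correlation_spec = default_correlation_spec(self.food_groups)
        else:
            self.correlation_spec = {
                k: np.asarray(v, dtype=float) for k, v in self.correlation_spec.items()
            }
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise GeneratorConfigError("n_subjects must be positive")
        if not 0.0 <= self.sex_proportion_female <= 1.0:
            raise GeneratorConfigError("sex_proportion_female must be in [0,1]")
        for name, props in [
            ("dmpw_proportions", self.dmpw_proportions),
            ("status_proportions", self.status_proportions),
            ("pattern_mixture_weights", self.pattern_mixture_weights),
        ]:
            arr = np.asarray(props, dtype=float)
            if np.any(arr < 0) or np.any(arr > 1):
                raise GeneratorConfigError(f"{name} entries must be in [0,1]")
            if abs(arr.sum() - 1.0) > 1e-6:
                raise GeneratorConfigError(f"{name} must sum to 1, got {arr.sum()}")
        if len(self.dmpw_proportions) != 3:
            raise GeneratorConfigError("dmpw_proportions must have 3 entries")
        if len(self.status_proportions) != 4:
            raise GeneratorConfigError("status_proportions must have 4 entries")
        if len(self.pattern_mixture_weights) != self.n_patterns:
            raise GeneratorConfigError("pattern_mixture_weights length != n_patterns")
        g = len(self.food_groups)
        if self.pattern_centroids.shape != (self.n_patterns, g):
            raise GeneratorConfigError(
                f"pattern_centroids must be {self.n_patterns} x {g}, "
                f"got {self.pattern_centroids.shape}"
            )
        if not np.all(np.isfinite(self.pattern_centroids)):
            raise GeneratorConfigError("pattern_centroids must be finite")
        if self.noise_scale <= 0:
            raise GeneratorConfigError("noise_scale must be positive")
        if not 0.0 <= self.icc < 1.0:
            raise GeneratorConfigError("icc must lie in [0, 1)")
        if self.n_clusters < 1 or self.n_clusters > self.n_subjects:
            raise GeneratorConfigError("n_clusters must be in [1, n_subjects]")
        status_p = dict(zip(STATUS_ORDER, self.status_proportions))
        for label, prop in zip(DMPW_ORDER, self.dmpw_proportions):
            if prop > 0 and sum(status_p[s] for s in FEASIBLE_STATUS[label]) <= 0:
                raise GeneratorConfigError(
                    f"DMPW {label!r} requested (proportion {prop}) but no "
                    f"feasible anthropometric status has positive probability "
                    f"(feasible: {FEASIBLE_STATUS[label]}) — e.g. overestimation "
                    f"is impossible for obese subjects"
                )
        for name, mat in self.correlation_spec.items():
            if name not in DMPW_ORDER:
                raise GeneratorConfigError(f"unknown DMPW stratum {name!r}")
            if mat.shape != (g, g):
                raise GeneratorConfigError(f"correlation_spec[{name}] must be {g}x{g}")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
                raise GeneratorConfigError(f"correlation_spec[{name}] diagonal != 1")
            if not np.allclose(mat, mat.T, atol=1e-8):
                raise GeneratorConfigError(f"correlation_spec[{name}] not symmetric")
            if np.any(np.abs(mat) > 1.0 + 1e-12):
                raise GeneratorConfigError(f"correlation_spec[{name}] entries > 1")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["food_groups"] = list(self.food_groups)
        d["dmpw_proportions"] = list(self.dmpw_proportions)
        d["status_proportions"] = list(self.status_proportions)
        d["pattern_mixture_weights"] = list(self.pattern_mixture_weights)
        d["pattern_centroids"] = self.pattern_centroids.tolist()
        d["correlation_spec"] = {
            k: v.tolist() for k, v in self.correlation_spec.items()
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("dmpw_proportions", "status_proportions", "pattern_mixture_weights"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "food_groups" in raw:
            raw["food_groups"] = tuple(raw["food_groups"])
        if raw.get("pattern_centroids") is not None:
            raw["pattern_centroids"] = np.asarray(raw["pattern_centroids"], float)
        if raw.get("correlation_spec") is not None:
            raw["correlation_spec"] = {
                k: np.asarray(v, float) for k, v in raw["correlation_spec"].items()
            }
        return cls(**raw)


@dataclass
class PlantedTruth:
    """Generator-side ground truth for parameter-recovery tests."""

    pattern_labels: np.ndarray  # 1..k per subject
    dmpw_labels: np.ndarray
    cluster_ids: np.ndarray
    #: Signed planted edges with |target Spearman| > 0.5, per DMPW stratum.
    planted_edges: dict[str, list[tuple[str, str, float]]]
    #: Target Spearman matrices actually realised after PSD repair.
    effective_spearman: dict[str, np.ndarray]
    food_groups: tuple[str, ...] = FOOD_GROUPS

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pattern_labels": [int(x) for x in self.pattern_labels],
            "dmpw_labels": [str(x) for x in self.dmpw_labels],
            "cluster_ids": [str(x) for x in self.cluster_ids],
            "planted_edges": {
                k: [[a, b, float(r)] for a, b, r in v]
                for k, v in self.planted_edges.items()
            },
            "effective_spearman": {
                k: np.asarray(v).tolist() for k, v in self.effective_spearman.items()
            },
            "food_groups": list(self.food_groups),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _allocate_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder allocation of n into integer counts matching
    proportions exactly up to rounding."""
    p = np.asarray(proportions, dtype=float)
    raw = n * p
    counts = np.floor(raw).astype(int)
    remainder = int(n - counts.sum())
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _planted_edges(spec: dict[str, np.ndarray], groups) -> dict[str, list]:
    edges: dict[str, list] = {}
    for name, mat in spec.items():
        found = []
        g = len(groups)
        for i in range(g):
            for j in range(i + 1, g):
                if abs(mat[i, j]) > 0.5:
                    found.append((groups[i], groups[j], float(mat[i, j])))
        edges[name] = found
    return edges


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Draw the subject table and the planted ground truth.

    Sex, DMPW and anthropometric-status counts are allocated by largest
    remainder (so configured marginals are matched exactly up to integer
    rounding) and then randomly assigned to subjects.  Each subject's
    BMI-for-age percentile is drawn uniformly within the band of the
    assigned status, and the perceived-weight response is drawn so that
    the ordinal truth table maps (status, perception) back to the planted
    DMPW label for every subject.
    """
    rng = _stage_rng(config.seed, "cohort")
    n = config.n_subjects
    groups = config.food_groups

    # DMPW labels: exact marginal counts, randomly placed.
    dmpw_counts = _allocate_counts(n, config.dmpw_proportions)
    dmpw = np.repeat(DMPW_ORDER, dmpw_counts)
    rng.shuffle(dmpw)

    # Sex: exact marginal counts, random placement (independent of DMPW).
    n_female = int(round(n * config.sex_proportion_female))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)

    # Status: drawn per subject from the configured marginal restricted to
    # the statuses that can realise the subject's DMPW label.
    status_p = dict(zip(STATUS_ORDER, config.status_proportions))
    status = np.empty(n, dtype=object)
    for label in DMPW_ORDER:
        mask = dmpw == label
        feas = [s for s in FEASIBLE_STATUS[label] if status_p[s] > 0]
        probs = np.array([status_p[s] for s in feas])
        probs = probs / probs.sum()
        status[mask] = rng.choice(feas, size=int(mask.sum()), p=probs)

    # Percentile uniform within the status band; BMI consistent with it.
    lo = np.array([_STATUS_BANDS[s][0] for s in status])
    hi = np.array([_STATUS_BANDS[s][1] for s in status])
    percentile = rng.uniform(lo, hi)
    z = np.clip(sps.norm.ppf(np.clip(percentile / 100.0, 1e-6, 1 - 1e-6)), -3.5, 3.5)
    bmi = 18.9 * np.exp(0.13 * z)
    height = rng.normal(1.58 + 0.05 * (sex == "male"), 0.07)
    height = np.clip(height, 1.30, 1.95)
    weight_scale = bmi * height**2 + 0.1  # scale reading includes the uniform

    # Perception: invert the ordinal truth table.
    measured = np.array([_MEASURED_LEVEL[s] for s in status])
    perceived = np.empty(n, dtype=int)
    for i in range(n):
        m = measured[i]
        if dmpw[i] == "Agreed":
            perceived[i] = m
        elif dmpw[i] == "Underestimated":
            perceived[i] = m - 1 if m == 1 else rng.choice([0, 1], p=[0.2, 0.8])
        else:  # Overestimated
            perceived[i] = m + 1 if m == 1 else rng.choice([1, 2], p=[0.8, 0.2])
    raw_perception = np.empty(n, dtype=object)
    for i, lev in enumerate(perceived):
        if lev == 0:
            raw_perception[i] = rng.choice(["thin", "very thin"], p=[0.8, 0.2])
        elif lev == 1:
            raw_perception[i] = "normal"
        else:
            raw_perception[i] = rng.choice(["fat", "very fat"], p=[0.8, 0.2])

    age = np.clip(rng.normal(14.3, 1.6, n), 11.0, 17.0)
    ses = rng.choice(["good", "poor"], size=n, p=[0.502, 0.498])
    pubertal = rng.choice(
        ["pre-pubertal", "pubertal", "post-pubertal"], size=n, p=[0.084, 0.218, 0.698]
    )

    # School conglomerates: near-equal contiguous blocks.
    cluster_sizes = _allocate_counts(n, np.full(config.n_clusters, 1.0 / config.n_clusters))
    cluster_ids = np.repeat(
        [f"school_{i + 1:02d}" for i in range(config.n_clusters)], cluster_sizes
    )

    # Pattern labels: per-cluster mixture weights perturbed to the target ICC.
    w = np.asarray(config.pattern_mixture_weights, dtype=float)
    patterns = np.empty(n, dtype=int)
    pattern_values = np.arange(1, config.n_patterns + 1)
    for cid in np.unique(cluster_ids):
        mask = cluster_ids == cid
        if config.icc > 0 and config.n_patterns > 1:
            alpha0 = (1.0 - config.icc) / config.icc
            cw = rng.dirichlet(alpha0 * w)
        else:
            cw = w
        patterns[mask] = rng.choice(pattern_values, size=int(mask.sum()), p=cw)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "age": np.round(age, 1),
            "weight_kg": np.round(weight_scale, 2),
            "height_m": np.round(height, 3),
            "bmi": bmi,
            "bmi_for_age_percentile": percentile,
            "status": status,
            "perceived_response": raw_perception,
            "dmpw": dmpw,
            "cluster_id": cluster_ids,
            "socioeconomic": ses,
            "pubertal_stage": pubertal,
        }
    ).set_index("subject_id")

    # Consistency guard: every emitted pair must re-classify to the label.
    for s, p in zip(status, percentile):
        assert classify_status(p) == s

    effective = {}
    for name, mat in config.correlation_spec.items():
        pear = nearest_psd(spearman_to_pearson(mat))
        effective[name] = pearson_to_spearman(pear)
    truth = PlantedTruth(
        pattern_labels=patterns,
        dmpw_labels=dmpw.copy(),
        cluster_ids=cluster_ids.copy(),
        planted_edges=_planted_edges(config.correlation_spec, groups),
        effective_spearman=effective,
        food_groups=groups,
    )
    return cohort, truth


def generate_ffq_intakes(
    cohort: pd.DataFrame, config: GeneratorConfig, truth: PlantedTruth
) -> pd.DataFrame:
    """Daily gram intakes per food group from the log-normal Gaussian copula.

    Within each DMPW stratum, normal scores Z are drawn with the Pearson
    correlation 2 sin(pi rho_S / 6) of the stratum's target Spearman
    matrix (PSD-repaired if needed); subject i's intake for group g is
    exp(centroid[pattern_i, g] + noise_scale * Z_ig), so rank correlations
    match the planted structure and marginals are log-normal around the
    subject's pattern centroid.
    """
    rng = _stage_rng(config.seed, "intakes")
    groups = list(config.food_groups)
    g = len(groups)
    intake = np.empty((len(cohort), g))
    patterns = truth.pattern_labels
    dmpw = cohort["dmpw"].to_numpy()
    for name in DMPW_ORDER:
        mask = dmpw == name
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        pear = nearest_psd(spearman_to_pearson(config.correlation_spec[name]))
        L = np.linalg.cholesky(pear + 1e-10 * np.eye(g))
        z = rng.standard_normal((n_g, g)) @ L.T
        mu = config.pattern_centroids[patterns[mask] - 1]
        intake[mask] = np.exp(mu + config.noise_scale * z)
    frame = pd.DataFrame(intake, index=cohort.index, columns=groups)
    frame.columns.name = "food_group"
    return frame


def generate_ffq_responses(
    intakes: pd.DataFrame,
    item_map: dict[str, str] | None = None,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Item-level FFQ responses whose reconstruction recovers the intakes.

    Each group's daily grams are split evenly over its mapped items.  For
    each item a frequency category is chosen so that the implied portion
    (target grams / daily factor) is closest on the log scale to the
    item's typical portion, and the portion is set exactly to
    target / factor — so aggregating the responses through the FFQ module
    reproduces the planted group intakes to numerical precision.  A zero
    intake maps to "never/rare".
    """
    if item_map is None:
        groups = tuple(intakes.columns)
        item_map = default_item_map(groups)
    by_group: dict[str, list[str]] = {}
    for item, grp in item_map.items():
        by_group.setdefault(grp, []).append(item)
    missing = [g for g in intakes.columns if g not in by_group]
    if missing:
        raise GeneratorConfigError(f"groups with no mapped items: {missing}")

    if seed is None:
        seed = config.seed if config is not None else 0
    rng = _stage_rng(seed, "responses")
    items = sorted(item_map)
    typical_portion = dict(zip(items, rng.uniform(50.0, 250.0, len(items))))

    cats = [c for c in ffq_mod.FREQUENCY_CATEGORIES if c != "never/rare"]
    factors = np.array([ffq_mod.DEFAULT_FREQUENCY_FACTORS[c] for c in cats])

    rows = []
    for sid, row in intakes.iterrows():
        for grp in intakes.columns:
            grp_items = by_group[grp]
            target = row[grp] / len(grp_items)
            for item in grp_items:
                if target <= 0:
                    rows.append((sid, item, "never/rare", round(typical_portion[item], 1)))
                    continue
                implied = target / factors
                k = int(np.argmin(np.abs(np.log(implied / typical_portion[item]))))
                rows.append((sid, item, cats[k], implied[k]))
    return pd.DataFrame(
        rows, columns=["subject_id", "item_id", "frequency", "portion_g"]
    )


# ---------------------------------------------------------------------------
# Reference recovery conditions
# ---------------------------------------------------------------------------


def network_recovery_config(n_per_group: int = 300, seed: int = 0) -> GeneratorConfig:
    """Conditions for correlation-network recovery tests.

    Three equal DMPW strata of ``n_per_group`` subjects, a single dietary
    pattern (so pooled rank correlations reflect the planted copula
    structure alone), and the default per-stratum correlation spec:
    positive-only cliques in Agreed / Underestimated and a sparser
    Overestimated stratum containing negative blocks (roots-oils -0.7
    among them).
    """
    return GeneratorConfig(
        n_subjects=3 * n_per_group,
        dmpw_proportions=(1 / 3, 1 / 3, 1 / 3),
        n_patterns=1,
        pattern_mixture_weights=(1.0,),
        n_clusters=max(2, (3 * n_per_group) // 50),
        seed=seed,
    )


def pattern_recovery_config(n_subjects: int = 600, seed: int = 0) -> GeneratorConfig:
    """Conditions for dietary-pattern recovery tests.

    Four centroids, each boosting one signature food group by +2.0 on the
    log scale over the shared base profile, with log-intake noise 0.35
    and no planted correlation structure.  At this separation-to-noise
    ratio Ward clustering of the abundance rows should reproduce the
    planted labels nearly perfectly (ARI >= 0.9).
    """
    centroids = default_pattern_centroids(4)
    idx = {g: i for i, g in enumerate(FOOD_GROUPS)}
    base = np.log(np.asarray(BASE_MEDIANS, dtype=float))
    centroids = np.tile(base, (4, 1))
    for k, group in enumerate(
        ["coffee_tea", "beans_legumes", "sweetened_beverages", "fruits"]
    ):
        centroids[k, idx[group]] += 2.0
    identity = {name: np.eye(len(FOOD_GROUPS)) for name in DMPW_ORDER}
    return GeneratorConfig(
        n_subjects=n_subjects,
        n_patterns=4,
        pattern_centroids=centroids,
        correlation_spec=identity,
        noise_scale=0.35,
        n_clusters=max(2, n_subjects // 50),
        icc=0.0,
        seed=seed,
    )
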