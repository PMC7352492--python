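"""End-to-end orchestration: generate -> FFQ -> classify -> cluster -> model -> network.

``run_pipeline`` executes the whole analysis on either a synthetic cohort
(generated in-process from a :class:`~nutnet.simulate.GeneratorConfig`)
or on user-supplied cohort/intake tables, writing every stage output as
delimited text plus a machine-readable ``summary.json`` and a
``manifest.json`` (config hash, seed, package/library versions) so a run
can be reproduced and diffed byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import anthropometry, ffq, networks, patterns, simulate, stats

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Knobs of an end-to-end run; defaults mirror the study conditions."""

    generator: simulate.GeneratorConfig = field(
        default_factory=simulate.GeneratorConfig
    )
    k_patterns: int = 4
    n_boot: int = 100
    rho_threshold: float = 0.5
    alpha: float = 0.05
    persistence: float = 0.5
    adjust_within_replicate: bool = True
    baseline_pattern: int = 2
    seed: int | None = None  # overrides generator.seed when given

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.generator.seed = int(self.seed)
        if not 0 < self.persistence <= 1:
            raise PipelineError("persistence must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")
        if not 0 <= self.rho_threshold < 1:
            raise PipelineError("rho_threshold must be in [0, 1)")
        if self.n_boot < 1:
            raise PipelineError("n_boot must be >= 1")

    def to_dict(self) -> dict:
        d = {
            "generator": self.generator.to_dict(),
            "k_patterns": self.k_patterns,
            "n_boot": self.n_boot,
            "rho_threshold": self.rho_threshold,
            "alpha": self.alpha,
            "persistence": self.persistence,
            "adjust_within_replicate": self.adjust_within_replicate,
            "baseline_pattern": self.baseline_pattern,
            "seed": self.seed,
            "schema_version": SCHEMA_VERSION,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("schema_version", None)
        gen = raw.pop("generator", None)
        if gen is not None:
            for key in (
                "dmpw_proportions",
                "status_proportions",
                "pattern_mixture_weights",
                "food_groups",
            ):
                if key in gen and gen[key] is not None:
                    gen[key] = tuple(gen[key])
            if gen.get("pattern_centroids") is not None:
                gen["pattern_centroids"] = np.asarray(gen["pattern_centroids"], float)
            if gen.get("correlation_spec") is not None:
                gen["correlation_spec"] = {
                    k: np.asarray(v, float) for k, v in gen["correlation_spec"].items()
                }
            generator = simulate.GeneratorConfig(**gen)
        else:
            generator = simulate.GeneratorConfig()
        return cls(generator=generator, **raw)


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _round_json(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_json(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_json(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic-cohort analysis and write the report bundle.

    Returns the summary dictionary that is also written to
    ``summary.json``.  Any stage failure is re-raised as
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    summary: dict = {"schema_version": SCHEMA_VERSION}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return wrap

    # -- simulate ----------------------------------------------------------
    cohort, truth = stage("simulate")(simulate.generate_cohort, gen)
    intakes_true = stage("simulate")(simulate.generate_ffq_intakes, cohort, gen, truth)
    item_map = simulate.default_item_map(gen.food_groups)
    responses = stage("simulate")(
        simulate.generate_ffq_responses, intakes_true, item_map, gen
    )
    cohort.to_csv(out / "cohort.tsv", sep="\t")
    responses.to_csv(out / "ffq_responses.tsv", sep="\t", index=False)
    truth.to_json(out / "planted_truth.json")
    pd.Series(item_map, name="group").rename_axis("item_id").to_csv(
        out / "item_group_map.tsv", sep="\t"
    )

    # -- ffq: reconstruct group intakes from the raw responses -------------
    intakes = stage("ffq")(
        ffq.aggregate_food_groups,
        responses,
        item_map,
        None,
        list(cohort.index),
        list(gen.food_groups),
    )
    ffq.write_intakes(intakes, out / "group_intakes.tsv")
    roundtrip_err = float(
        np.max(np.abs(intakes.to_numpy() - intakes_true.to_numpy())
               / np.maximum(intakes_true.to_numpy(), 1e-9))
    )
    summary["ffq_roundtrip_max_rel_error"] = roundtrip_err

    # -- classify ----------------------------------------------------------
    cohort = stage("classify")(anthropometry.annotate_cohort, cohort, 0.1, True)
    dmpw_table = anthropometry.dmpw_frequency_table(cohort)
    dmpw_table.to_csv(out / "dmpw_frequency.tsv", sep="\t", index=False)
    anthropometry.dmpw_frequency_table(cohort, by="sex").to_csv(
        out / "dmpw_by_sex.tsv", sep="\t", index=False
    )
    anthropometry.dmpw_frequency_table(cohort, by="status").to_csv(
        out / "dmpw_by_status.tsv", sep="\t", index=False
    )
    summary["dmpw_percent"] = dict(
        zip(dmpw_table["dmpw"], [float(x) for x in dmpw_table["percent"]])
    )
    summary["dmpw_truth_agreement"] = float(
        np.mean(cohort["dmpw"].to_numpy() == truth.dmpw_labels)
    )

    # -- patterns ----------------------------------------------------------
    abundance = stage("patterns")(patterns.abundance_transform, intakes)
    abundance.to_csv(out / "abundance.tsv", sep="\t")
    assignment = stage("patterns")(patterns.cluster_patterns, abundance, config.k_patterns)
    assignment.labels.to_frame().to_csv(out / "pattern_assignment.tsv", sep="\t")
    profile = stage("patterns")(patterns.pattern_profile, abundance, assignment)
    profile.mean.to_csv(out / "pattern_profile_mean.tsv", sep="\t")
    profile.sd.to_csv(out / "pattern_profile_sd.tsv", sep="\t")
    profile.anova.to_csv(out / "pattern_profile_anova.tsv", sep="\t", index=False)
    covs = cohort[["sex", "status", "dmpw"]]
    composition = stage("patterns")(patterns.pattern_composition, assignment, covs)
    comp_rows = []
    for cov, res in composition.items():
        res["table"].to_csv(out / f"pattern_by_{cov}.tsv", sep="\t")
        comp_rows.append(
            {"covariate": cov, "chi2": res["statistic"], "df": res["df"], "p": res["p"]}
        )
    pd.DataFrame(comp_rows).to_csv(out / "pattern_composition_tests.tsv", sep="\t", index=False)
    from sklearn.metrics import adjusted_rand_score

    summary["pattern_sizes"] = {
        int(k): int(v) for k, v in assignment.sizes().items()
    }
    summary["pattern_recovery_ari"] = float(
        adjusted_rand_score(truth.pattern_labels, assignment.labels.to_numpy())
    )
    summary["pattern_composition_p"] = {
        r["covariate"]: r["p"] for r in comp_rows
    }

    # -- model -------------------------------------------------------------
    weights = stats.cluster_weights(cohort["cluster_id"])
    try:
        fit = stats.fit_dietary_pattern_model(
            assignment.labels.to_numpy(),
            cohort["dmpw"].to_numpy(),
            cohort["sex"].to_numpy(),
            cohort["status"].to_numpy(),
            weights=weights,
            baseline_pattern=config.baseline_pattern,
            on_separation="warn",  # sparse corner cells are flagged, not fatal
        )
        fit.table.to_csv(out / "multinomial_or.tsv", sep="\t", index=False)
        dmpw_terms = fit.table[
            fit.table["term"].str.startswith("dmpw") & fit.table["identified"]
        ]
        summary["multinomial_baseline"] = int(fit.baseline)
        summary["dmpw_or_ci_covers_1"] = bool(
            np.all((dmpw_terms["ci_low"] <= 1) & (dmpw_terms["ci_high"] >= 1))
        )
    except stats.ConvergenceError as err:
        summary["multinomial_error"] = str(err)
    deff = stage("model")(
        stats.design_effect, assignment.labels.to_numpy(), cohort["cluster_id"].to_numpy()
    )
    summary["deff"] = {
        "deff": deff.deff,
        "icc": deff.icc,
        "mean_cluster_size": deff.mean_cluster_size,
        "sampling_influenced": deff.sampling_influenced,
    }

    # -- networks ----------------------------------------------------------
    net_rng = np.random.default_rng(
        np.random.SeedSequence([int(gen.seed), simulate._STAGE_IDS["networks"]])
    )
    nets: dict[str, networks.StableNetwork] = {}
    dens: dict[str, np.ndarray] = {}
    for name in simulate.DMPW_ORDER:
        subset = intakes.loc[cohort["dmpw"] == name]
        if len(subset) < 4:
            continue
        ens = stage("network")(
            networks.bootstrap_ensemble, subset, config.n_boot, None, net_rng
        )
        net = networks.stable_edges(
            ens,
            rho_threshold=config.rho_threshold,
            alpha=config.alpha,
            persistence=config.persistence,
            adjust=config.adjust_within_replicate,
        )
        nets[name] = net
        dens[name] = networks.replicate_densities(
            ens, config.rho_threshold, config.alpha, config.adjust_within_replicate
        )
        net.edges.to_csv(out / f"network_edges_{name}.tsv", sep="\t", index=False)
        networks.node_degrees(net).to_frame("degree").to_csv(
            out / f"node_degrees_{name}.tsv", sep="\t"
        )
    density_rows = [
        {
            "dmpw": name,
            "n_edges": nets[name].n_edges,
            "n_negative_edges": int((nets[name].edges["sign"] < 0).sum()),
            "density": nets[name].density,
            "median_replicate_density": float(np.median(dens[name])),
        }
        for name in nets
    ]
    pd.DataFrame(density_rows).to_csv(out / "network_densities.tsv", sep="\t", index=False)
    summary["network"] = {r["dmpw"]: r for r in density_rows}
    if len(dens) >= 2:
        comp = networks.compare_densities(dens)
        comp.pairwise.to_csv(out / "density_comparison.tsv", sep="\t", index=False)
        summary["density_comparison"] = {
            "kw_statistic": comp.statistic,
            "kw_p": comp.pvalue,
            "pairwise_p_holm": {
                f"{r.group1}|{r.group2}": float(r.p_holm)
                for r in comp.pairwise.itertuples(index=False)
            },
        }

    # -- report ------------------------------------------------------------
    summary = _round_json(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "config_hash": _config_hash(config),
        "seed": int(gen.seed),
        "nutnet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "schema_version": SCHEMA_VERSION,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.generator.to_yaml(out / "generator_config.yaml")
    return summary
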