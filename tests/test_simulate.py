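"""Synthetic-cohort generator: determinism, marginals, copula calibration."""

import numpy as np
import pandas as pd
import pytest

from nutnet import anthropometry, ffq, networks, simulate


class TestConfig:
    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        loaded = simulate.GeneratorConfig.from_yaml(path)
        assert loaded.n_subjects == small_config.n_subjects
        np.testing.assert_allclose(loaded.pattern_centroids, small_config.pattern_centroids)
        np.testing.assert_allclose(
            loaded.correlation_spec["Agreed"], small_config.correlation_spec["Agreed"]
        )

    def test_proportions_validated(self):
        with pytest.raises(simulate.GeneratorConfigError):
            simulate.GeneratorConfig(dmpw_proportions=(0.9, 0.2, 0.1))
        with pytest.raises(simulate.GeneratorConfigError):
            simulate.GeneratorConfig(sex_proportion_female=1.4)

    def test_infeasible_dmpw_status_combination(self):
        # overestimation is impossible when everyone is overweight/obese
        with pytest.raises(simulate.GeneratorConfigError, match="impossible"):
            simulate.GeneratorConfig(status_proportions=(0.0, 0.0, 0.5, 0.5))

    def test_non_psd_spec_beyond_repair(self):
        bad = np.eye(14)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        spec = {n: bad for n in ("Agreed", "Underestimated", "Overestimated")}
        with pytest.raises(simulate.GeneratorConfigError, match="PSD"):
            cfg = simulate.GeneratorConfig(correlation_spec=spec)
            cohort, truth = simulate.generate_cohort(cfg)


class TestCohort:
    def test_determinism_bit_identical(self, small_config):
        a_cohort, a_truth = simulate.generate_cohort(small_config)
        b_cohort, b_truth = simulate.generate_cohort(small_config)
        pd.testing.assert_frame_equal(a_cohort, b_cohort)
        np.testing.assert_array_equal(a_truth.pattern_labels, b_truth.pattern_labels)
        a_int = simulate.generate_ffq_intakes(a_cohort, small_config, a_truth)
        b_int = simulate.generate_ffq_intakes(b_cohort, small_config, b_truth)
        pd.testing.assert_frame_equal(a_int, b_int)

    def test_dmpw_marginals_recovered(self):
        cfg = simulate.GeneratorConfig(n_subjects=1496, seed=42)
        cohort, _ = simulate.generate_cohort(cfg)
        props = cohort["dmpw"].value_counts(normalize=True)
        assert props["Agreed"] == pytest.approx(0.683, abs=0.02)
        assert props["Underestimated"] == pytest.approx(0.197, abs=0.02)
        assert props["Overestimated"] == pytest.approx(0.120, abs=0.02)

    def test_all_female_edge_case(self):
        cfg = simulate.GeneratorConfig(
            n_subjects=50, sex_proportion_female=1.0, n_clusters=2, seed=1
        )
        cohort, _ = simulate.generate_cohort(cfg)
        assert (cohort["sex"] == "female").all()

    def test_truth_table_consistency_every_subject(self, small_cohort):
        cohort, truth = small_cohort
        reclassified = [
            anthropometry.classify_dmpw(s, r)
            for s, r in zip(cohort["status"], cohort["perceived_response"])
        ]
        assert (np.array(reclassified) == truth.dmpw_labels).all()
        # and the percentile band matches the assigned status for everyone
        recomputed = [
            anthropometry.classify_status(p) for p in cohort["bmi_for_age_percentile"]
        ]
        assert (np.array(recomputed) == cohort["status"].to_numpy()).all()

    def test_cluster_ids_cover_configured_blocks(self, small_cohort, small_config):
        cohort, truth = small_cohort
        assert cohort["cluster_id"].nunique() == small_config.n_clusters
        np.testing.assert_array_equal(cohort["cluster_id"].to_numpy(), truth.cluster_ids)


class TestIntakes:
    def test_identity_spec_uncorrelated(self):
        cfg = simulate.GeneratorConfig(
            n_subjects=500,
            dmpw_proportions=(1.0, 0.0, 0.0),
            n_patterns=1,
            pattern_mixture_weights=(1.0,),
            correlation_spec={n: np.eye(14) for n in simulate.DMPW_ORDER},
            n_clusters=10,
            seed=9,
        )
        cohort, truth = simulate.generate_cohort(cfg)
        intakes = simulate.generate_ffq_intakes(cohort, cfg, truth)
        cm = networks.spearman_matrix(intakes)
        off = cm.rho[~np.eye(14, dtype=bool)]
        assert np.max(np.abs(off)) < 0.15

    def test_planted_strong_edge_recovered(self):
        spec = {n: np.eye(14) for n in simulate.DMPW_ORDER}
        mat = np.eye(14)
        mat[0, 1] = mat[1, 0] = 0.8
        spec["Agreed"] = mat
        cfg = simulate.GeneratorConfig(
            n_subjects=500,
            dmpw_proportions=(1.0, 0.0, 0.0),
            n_patterns=1,
            pattern_mixture_weights=(1.0,),
            correlation_spec=spec,
            n_clusters=10,
            seed=10,
        )
        cohort, truth = simulate.generate_cohort(cfg)
        intakes = simulate.generate_ffq_intakes(cohort, cfg, truth)
        cm = networks.spearman_matrix(intakes)
        assert cm.rho[0, 1] > 0.6

    def test_planted_negative_edge_negative_sample(self):
        cfg = simulate.network_recovery_config(250, seed=3)
        cohort, truth = simulate.generate_cohort(cfg)
        intakes = simulate.generate_ffq_intakes(cohort, cfg, truth)
        over = intakes.loc[cohort["dmpw"] == "Overestimated"]
        cm = networks.spearman_matrix(over)
        i = list(cfg.food_groups).index("roots")
        j = list(cfg.food_groups).index("oils")
        assert cm.rho[i, j] < -0.5

    def test_copula_fidelity_at_n2000(self):
        cfg = simulate.GeneratorConfig(
            n_subjects=2000,
            dmpw_proportions=(1.0, 0.0, 0.0),
            n_patterns=1,
            pattern_mixture_weights=(1.0,),
            n_clusters=40,
            seed=77,
        )
        cohort, truth = simulate.generate_cohort(cfg)
        intakes = simulate.generate_ffq_intakes(cohort, cfg, truth)
        cm = networks.spearman_matrix(intakes)
        dev = np.max(np.abs(cm.rho - truth.effective_spearman["Agreed"]))
        assert dev < 0.1

    def test_planted_edges_listed_from_spec(self, small_config):
        _, truth = simulate.generate_cohort(small_config)
        over = {(a, b): r for a, b, r in truth.planted_edges["Overestimated"]}
        assert over[("oils", "roots")] == -0.7 or over.get(("roots", "oils")) == -0.7
        assert all(abs(r) > 0.5 for r in over.values())


class TestResponses:
    def test_round_trip_recovers_intakes(self, small_config, small_cohort, small_intakes):
        cohort, _ = small_cohort
        item_map = simulate.default_item_map(small_config.food_groups)
        responses = simulate.generate_ffq_responses(
            small_intakes, item_map, small_config
        )
        recovered = ffq.aggregate_food_groups(
            responses,
            item_map,
            subjects=list(small_intakes.index),
            groups=list(small_config.food_groups),
        )
        rel = np.abs(recovered.to_numpy() - small_intakes.to_numpy()) / np.maximum(
            small_intakes.to_numpy(), 1e-12
        )
        assert np.max(rel) < 1e-9

    def test_zero_intake_maps_to_never_rare(self, small_config):
        intakes = pd.DataFrame(
            np.zeros((1, 14)), index=["s1"], columns=list(small_config.food_groups)
        )
        responses = simulate.generate_ffq_responses(intakes, seed=4)
        assert (responses["frequency"] == "never/rare").all()

    def test_single_item_group_weekly_70g(self):
        intakes = pd.DataFrame({"cereals": [10.0]}, index=["s1"])
        responses = simulate.generate_ffq_responses(
            intakes, {"rice": "cereals"}, seed=5
        )
        row = responses.iloc[0]
        factor = ffq.DEFAULT_FREQUENCY_FACTORS[row["frequency"]]
        assert row["portion_g"] * factor == pytest.approx(10.0)

    def test_unmapped_group_errors(self):
        intakes = pd.DataFrame({"cereals": [10.0], "fruits": [5.0]}, index=["s1"])
        with pytest.raises(simulate.GeneratorConfigError, match="fruits"):
            simulate.generate_ffq_responses(intakes, {"rice": "cereals"}, seed=6)


def test_truth_json_export(tmp_path, small_cohort):
    _, truth = small_cohort
    path = tmp_path / "truth.json"
    truth.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert len(payload["pattern_labels"]) == len(truth.pattern_labels)
    assert set(payload["planted_edges"]) == {"Agreed", "Underestimated", "Overestimated"}
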