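"""Synthetic-screen generators: determinism, distributions, planted truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnvwing.config import (
    PHENOTYPES,
    ConfigurationError,
    NetworkParams,
    SimulationConfig,
)
from cnvwing import synthetic as syn
from cnvwing.expression import preferential_tissues
from cnvwing.network import shortest_path, threshold_network
from cnvwing.stats import mann_whitney
from oracles import brute_shortest_path


def _dump(cfg):
    """Serialize every generated table for byte-identity comparison."""
    wings, truth = syn.gen_wing_scores(cfg)
    parts = [wings.records.to_csv(), wings.lethal.to_csv(), repr(sorted(truth.items()))]
    parts.append(syn.gen_measurements(cfg).to_csv())
    scores, controls = syn.gen_eye_scores(cfg)
    parts += [scores.to_csv(), controls.to_csv()]
    parts.append(syn.gen_cell_counts(cfg).to_csv())
    matrix, pref = syn.gen_expression(cfg)
    parts += [matrix.values.to_csv(), repr(sorted(pref.items()))]
    net = syn.gen_network(cfg)
    parts += [net.edges.to_csv(), repr(sorted(net.planted_paths.items())),
              repr(sorted((g, tuple(sorted(t))) for g, t in net.annotations.items()))]
    return "\n".join(parts)


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_config):
        assert _dump(small_config) == _dump(small_config)

    def test_different_seed_differs(self, small_config):
        other = dataclasses.replace(small_config, seed=8)
        assert _dump(small_config) != _dump(other)

    def test_streams_are_isolated(self, small_config):
        """Re-running one generator does not perturb another's draws."""
        m1 = syn.gen_measurements(small_config).to_csv()
        syn.gen_wing_scores(small_config)
        syn.gen_expression(small_config)
        assert syn.gen_measurements(small_config).to_csv() == m1


class TestWingScores:
    def test_degenerate_profile_scores_all_ones(self):
        profiles = {ph: [1.0, 0, 0, 0, 0] for ph in PHENOTYPES}
        cfg = SimulationConfig(
            seed=1, n_wings_per_line=5,
            class_sizes={"no_phenotype": 3},
            severity_profiles={"no_phenotype": profiles},
        )
        table, truth = syn.gen_wing_scores(cfg)
        assert (table.records["severity"] == 1).all()
        assert set(truth.values()) == {"no_phenotype"}

    def test_lethal_lines_have_no_wings_and_flag(self, small_config):
        table, truth = syn.gen_wing_scores(small_config)
        lethal_lines = {l for l, c in truth.items() if c == "lethal"}
        assert lethal_lines
        assert not table.records["line_id"].isin(lethal_lines).any()
        assert {l for l, _ in table.lethal_keys()} == lethal_lines

    def test_wing_counts_per_line_and_sex(self, small_config):
        table, truth = syn.gen_wing_scores(small_config)
        per = table.records.groupby(["line_id", "sex"])["wing_id"].nunique()
        assert (per == small_config.n_wings_per_line).all()

    def test_invalid_multinomial_rejected(self):
        profiles = {ph: [0.5, 0.2, 0, 0, 0] for ph in PHENOTYPES}  # sums to 0.7
        cfg = SimulationConfig(
            class_sizes={"mild": 2}, severity_profiles={"mild": profiles}
        )
        with pytest.raises(ConfigurationError):
            syn.gen_wing_scores(cfg)

    def test_severity_frequencies_match_multinomial(self):
        """Chi-square goodness of fit at n=10,000 wings does not reject."""
        probs = [0.4, 0.3, 0.2, 0.1, 0.0]
        cfg = SimulationConfig(
            seed=5, n_wings_per_line=1000,
            class_sizes={"moderate": 5},
            severity_profiles={"moderate": {ph: list(probs) for ph in PHENOTYPES}},
        )
        table, _ = syn.gen_wing_scores(cfg)
        sub = table.records[table.records["phenotype"] == "wrinkled"]
        obs = sub["severity"].value_counts().reindex([1, 2, 3, 4], fill_value=0)
        exp = np.asarray(probs[:4]) * len(sub)
        p = sps.chisquare(obs.to_numpy(), exp).pvalue
        assert p > 0.01


class TestMeasurements:
    def test_null_effect_same_law(self):
        cfg = SimulationConfig(seed=2, measurement_effects={"line_x": 1.0},
                               n_wings_measured=200)
        df = syn.gen_measurements(cfg)
        line = df[df["line_id"] == "line_x"]["area"]
        ctrl = df[df["line_id"] == "control_GD"]["area"]
        assert mann_whitney(line, ctrl).p > 0.01
        assert (df[syn._BASELINES.keys()] > 0).all().all()

    def test_half_effect_detected_in_most_seeds(self):
        """Effect 0.5 at n=50/group rejects at alpha=0.05 in >99% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, measurement_effects={"line_x": 0.5},
                                   n_wings_measured=50)
            df = syn.gen_measurements(cfg)
            line = df[(df["line_id"] == "line_x") & (df["sex"] == "F")]["area"]
            ctrl = df[(df["line_id"] == "control_GD") & (df["sex"] == "F")]["area"]
            hits += mann_whitney(line, ctrl).p < 0.05
        assert hits / n_seeds > 0.99

    def test_nonpositive_effect_rejected(self):
        cfg = SimulationConfig(measurement_effects={"line_x": -1.0})
        with pytest.raises(ConfigurationError):
            syn.gen_measurements(cfg)


class TestEyeScores:
    def test_null_fc_median_unbiased(self):
        """Median normalized score centers on 1 under a null fold change."""
        medians = []
        for seed in range(15):
            cfg = SimulationConfig(seed=seed, eye_fc_effects={"line_x": 1.0},
                                   eye_n_range=(40, 40))
            scores, controls = syn.gen_eye_scores(cfg)
            medians.append(np.median(scores["score"] / controls["score"].median()))
        assert abs(np.mean(medians) - 1.0) < 0.05

    def test_n_within_range(self, small_config):
        scores, _ = syn.gen_eye_scores(small_config)
        per = scores.groupby("line_id").size()
        lo, hi = small_config.eye_n_range
        assert per.between(lo, hi).all()


class TestCellCounts:
    def test_unit_ratio_normalized_median_near_one(self):
        cfg = SimulationConfig(seed=4, cell_rate_ratios={"line_x": 1.0},
                               cell_n_range=(18, 18))
        df = syn.gen_cell_counts(cfg)
        line = df[(df["line_id"] == "line_x") & (df["marker"] == "pH3")]["count"]
        ctrl = df[(df["line_id"] == "control") & (df["marker"] == "pH3")]["count"]
        assert abs(np.median(line) / np.median(ctrl) - 1.0) < 0.25

    def test_counts_are_nonnegative_ints(self, small_config):
        df = syn.gen_cell_counts(small_config)
        assert (df["count"] >= 0).all()
        assert df["count"].dtype.kind == "i"

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.gen_cell_counts(SimulationConfig(cell_rate_ratios={"x": 0.0}))


class TestExpression:
    def test_fraction_zero_truth_empty(self):
        cfg = SimulationConfig(seed=6, n_genes=20, n_tissues=5,
                               preferential_fraction=0.0)
        matrix, truth = syn.gen_expression(cfg)
        assert truth == {}
        # rejection sampling leaves no natural outliers either
        for gene in matrix.values.index:
            assert preferential_tissues(matrix.values.loc[gene]) == []

    def test_planted_tissues_recovered_exactly(self, small_config):
        matrix, truth = syn.gen_expression(small_config)
        assert len(truth) == round(
            small_config.preferential_fraction * small_config.n_genes
        )
        for gene, tissues in truth.items():
            assert preferential_tissues(matrix.values.loc[gene]) == tissues

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.gen_expression(SimulationConfig(preferential_fraction=1.5))


class TestNetwork:
    def test_planted_paths_are_unique_shortest(self, small_config):
        net = syn.gen_network(small_config)
        g = threshold_network(net.edges, p_min=0.2)
        for (s, t), path in net.planted_paths.items():
            r = shortest_path(g, s, t)
            assert r.path == path
            assert r.connectors == path[1:-1]

    def test_planted_path_beats_brute_force(self, small_config):
        """The generated graph's true minimum-weight route is the planted one
        (checked by exhaustive simple-path enumeration on a subgraph)."""
        cfg = dataclasses.replace(
            small_config,
            network_params=NetworkParams(
                n_nodes=8, edge_prob=0.3, n_planted_paths=1, n_connectors_per_path=2
            ),
        )
        net = syn.gen_network(cfg)
        edges = {
            frozenset((a, b)): 1.0 / p
            for a, b, p in net.edges.itertuples(index=False)
        }
        (s, t), path = next(iter(net.planted_paths.items()))
        length, best = brute_shortest_path(edges, s, t)
        assert best == path

    def test_zero_background_graph_is_planted_paths(self):
        cfg = SimulationConfig(
            seed=9, network_params=NetworkParams(n_nodes=20, edge_prob=0.0)
        )
        net = syn.gen_network(cfg)
        planted_edges = {
            (min(a, b), max(a, b))
            for p in net.planted_paths.values()
            for a, b in zip(p, p[1:])
        }
        got = {(a, b) for a, b, _ in net.edges.itertuples(index=False)}
        assert got == planted_edges

    def test_connector_annotation_enrichment_planted(self, small_config):
        net = syn.gen_network(small_config)
        connectors = {c for p in net.planted_paths.values() for c in p[1:-1]}
        rate_conn = np.mean([net.enriched_term in net.annotations[c] for c in connectors])
        others = [n for n in net.annotations if n not in connectors]
        rate_bg = np.mean([net.enriched_term in net.annotations[o] for o in others])
        assert rate_conn > rate_bg
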