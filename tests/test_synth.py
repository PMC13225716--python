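import pandas as pd
import pytest

from golgiscreen.evidence import EvidenceRecord, PhenotypeContext, literature_score
from golgiscreen.network import InteractionNetwork, count_golgi_interactors, filter_edges
from golgiscreen.screen import HIGHER_IN_ORGANIZED, fold_change
from golgiscreen.synth import (
    GroundTruth,
    PlantedGene,
    SynthConfig,
    build_synth_universe,
    default_config,
    simulate_evidence,
    simulate_expression,
    simulate_network,
)


def small_config(seed=5, **kw):
    defaults = dict(
        seed=seed,
        n_genes=60,
        n_universe=20,
        planted=(PlantedGene("CANDA", 12.0, HIGHER_IN_ORGANIZED, 2, 3),),
        edge_density=0.02,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestExpression:
    def test_seed_determinism(self):
        cfg = small_config()
        pd.testing.assert_frame_equal(simulate_expression(cfg), simulate_expression(cfg))

    def test_different_seeds_differ(self):
        assert not simulate_expression(small_config(seed=5)).equals(
            simulate_expression(small_config(seed=6))
        )

    def test_planted_ratio_recovered_exactly(self):
        cfg = small_config(planted=(PlantedGene("CANDA", 12.0, HIGHER_IN_ORGANIZED, 2, 3),))
        expr = simulate_expression(cfg)
        for pair in cfg.pairs:
            a = expr.at["CANDA", pair.organized_line]
            b = expr.at["CANDA", pair.disorganized_line]
            fc, direction = fold_change(a, b)
            assert fc == 12.0
            assert direction == "first"

    def test_shape_and_positivity(self):
        cfg = small_config(n_genes=500, n_universe=50)
        expr = simulate_expression(cfg)
        assert expr.shape == (500, 4)
        assert (expr > 0).all().all()

    def test_background_ratio_bound_enforced(self):
        cfg = small_config(max_background_ratio=3.0)
        expr = simulate_expression(cfg)
        background = expr.drop(index=["CANDA"])
        for pair in cfg.pairs:
            a, b = background[pair.organized_line], background[pair.disorganized_line]
            ratio = pd.concat([a / b, b / a], axis=1).max(axis=1)
            assert (ratio < 3.0).all()


class TestNetwork:
    def test_planted_golgi_neighbor_count_exact(self):
        cfg = small_config()
        uni = build_synth_universe(cfg)
        edges = simulate_network(cfg, uni)
        net = filter_edges(InteractionNetwork.from_edges(edges), cfg.channel, cfg.min_conf)
        assert count_golgi_interactors(net, "CANDA", uni).score2 == 3

    def test_no_self_loops_and_seed_determinism(self):
        cfg = small_config()
        e1, e2 = simulate_network(cfg), simulate_network(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        assert (e1["protein1"] != e1["protein2"]).all()

    def test_density_zero_leaves_only_planted_edges(self):
        cfg = small_config(edge_density=0.0)
        edges = simulate_network(cfg)
        assert set(edges["protein1"]) == {"CANDA"}
        assert len(edges) == 3

    def test_more_neighbors_than_universe_rejected_at_config(self):
        with pytest.raises(ValueError):
            small_config(planted=(PlantedGene("CANDA", 12.0, HIGHER_IN_ORGANIZED, 2, 20),))

    def test_neighbor_pool_exhaustion_rejected_at_generation(self):
        # two planted genes shrink the eligible (non-planted) universe pool to 18
        cfg = small_config(
            planted=(
                PlantedGene("CANDA", 12.0, HIGHER_IN_ORGANIZED, 2, 19),
                PlantedGene("CANDB", 12.0, HIGHER_IN_ORGANIZED, 2, 0),
            )
        )
        with pytest.raises(ValueError):
            simulate_network(cfg)


class TestEvidence:
    @pytest.mark.parametrize("setup", [0, 1, 2])
    @pytest.mark.parametrize("direction", [HIGHER_IN_ORGANIZED, "higher_in_disorganized"])
    def test_round_trip_reproduces_requested_score(self, setup, direction):
        cfg = small_config(planted=(PlantedGene("CANDA", 12.0, direction, setup, 0),))
        rows = simulate_evidence(cfg)
        row = rows[rows["gene"] == "CANDA"].iloc[0]
        ev = EvidenceRecord(
            gene="CANDA",
            knockdown_phenotype=row["knockdown_phenotype"],
            golgi_involvement=bool(row["golgi_involvement"]),
        )
        ctx = PhenotypeContext(pair=cfg.pairs[0], direction=direction)
        assert literature_score(ev, ctx).score1 == setup

    def test_background_universe_genes_have_no_data(self):
        rows = simulate_evidence(small_config())
        bg = rows[rows["gene"] != "CANDA"]
        assert (bg["knockdown_phenotype"] == "none_reported").all()


class TestGroundTruth:
    def test_unbounded_background_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth.from_config(small_config(max_background_ratio=None))

    def test_bound_at_or_above_threshold_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth.from_config(small_config(max_background_ratio=5.0))

    def test_default_config_truth(self):
        truth = GroundTruth.from_config(default_config(1))
        assert truth.common_genes == {"CAND1", "CAND2", "CAND3"}
        assert truth.expected_selected["breast"] == {"CAND1", "CAND2", "CAND3", "BREASTONLY"}
        assert truth.expected_selected["lung"] == {"CAND1", "CAND2", "CAND3"}
        assert "DECOYLOWFC" not in truth.expected_degs["breast"]
        assert truth.expected_scores["CAND1"] == (2, 3)


class TestConfigValidation:
    def test_planted_must_fit_universe(self):
        with pytest.raises(ValueError):
            SynthConfig(seed=1, n_genes=10, n_universe=1, planted=(
                PlantedGene("A", 12.0, HIGHER_IN_ORGANIZED, 2, 0),
                PlantedGene("B", 12.0, HIGHER_IN_ORGANIZED, 2, 0),
            ))

    def test_invalid_planted_direction_rejected(self):
        with pytest.raises(ValueError):
            PlantedGene("A", 12.0, "sideways", 2, 0)
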