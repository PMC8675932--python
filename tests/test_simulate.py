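"""Duplication-divergence generator: determinism, mechanism, recovery."""

import numpy as np
import pytest

from ohnonet import (SimulationParams, apply_rewiring, apply_ssd_events, apply_wgd,
                     count_bifan, count_ffl_bifan, count_lambda_motifs, generate,
                     generate_ancestral, replay_event_log, similarity_distribution)
from ohnonet.catalog import SSD, SSD_YOUNG, WGD


def small_params(**kw):
    base = dict(n_ancestral_genes=80, n_tfs=10, n_mirnas=5, tf_density=0.1,
                ppi_density=0.05, mirna_density=0.1, n_ssd_events=10, seed=0)
    base.update(kw)
    return SimulationParams(**base)


class TestParams:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(tf_density=1.5)
        with pytest.raises(ValueError):
            SimulationParams(wgd_retention={"tf": 2.0})

    def test_per_layer_broadcast(self):
        p = SimulationParams(wgd_retention=0.7)
        assert p.wgd_retention == {"tf": 0.7, "ppi": 0.7, "mirna": 0.7}

    def test_count_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(n_tfs=20, n_ancestral_genes=10)


class TestGenerateAncestral:
    def test_zero_density_empty(self):
        p = small_params(tf_density=0.0, ppi_density=0.0, mirna_density=0.0,
                         p_self_loop=0.0)
        layers = generate_ancestral(p)
        assert len(layers.tf) == len(layers.ppi) == len(layers.mirna) == 0

    def test_all_tfs_self_loop(self):
        p = small_params(p_self_loop=1.0)
        layers = generate_ancestral(p)
        tfs = [f"G{i:05d}" for i in range(p.n_tfs)]
        assert all(layers.tf.has_edge(t, t) for t in tfs)

    def test_edge_count_matches_binomial_sampling(self):
        p = small_params(n_ancestral_genes=200, n_tfs=50, tf_density=0.1,
                         p_self_loop=0.0)
        n_expected = 50 * 199 * 0.1
        sd = np.sqrt(50 * 199 * 0.1 * 0.9)
        counts = [len(generate_ancestral(small_params(
            n_ancestral_genes=200, n_tfs=50, tf_density=0.1, p_self_loop=0.0,
            seed=s)).tf) for s in range(10)]
        assert abs(np.mean(counts) - n_expected) < 3 * sd / np.sqrt(10)

    def test_deterministic_under_seed(self):
        a = generate_ancestral(small_params(seed=5))
        b = generate_ancestral(small_params(seed=5))
        assert a.tf.edges == b.tf.edges and a.ppi.edges == b.ppi.edges


class TestApplyWgd:
    def test_full_retention_selfloop_spawns_ffl_bifan(self):
        # one self-regulating TF with one target: after WGD at retention 1 the
        # TF pair and target pair form an FFL+Bifan
        p = small_params(wgd_retention=1.0, wgd_interaction_gain=0.0)
        from ohnonet import BipartiteLayer, DirectedLayer, Multilayer, UndirectedLayer
        anc = Multilayer(DirectedLayer.from_edges([("T", "T"), ("T", "G")]),
                         UndirectedLayer(frozenset()), BipartiteLayer(frozenset()))
        rng = np.random.default_rng(0)
        layers, pairs, _ = apply_wgd(anc, p, rng)
        tf_pair = [("T", "Tw")]
        tgt_pair = [("G", "Gw")]
        assert count_ffl_bifan(layers.tf, tf_pair, tgt_pair).count == 1
        assert count_bifan(layers.tf, tf_pair, tgt_pair).count == 0

    def test_zero_retention_isolates_copies(self):
        p = small_params(wgd_retention=0.0, wgd_interaction_gain=0.0)
        anc = generate_ancestral(p)
        layers, pairs, _ = apply_wgd(anc, p, np.random.default_rng(0))
        copies = {g + "w" for g in anc.tf.nodes}
        assert not (layers.tf.nodes & copies)
        assert layers.tf.edges == set()  # originals also subject to retention 0

    def test_all_pairs_labeled_wgd(self):
        p = small_params()
        anc = generate_ancestral(p)
        _, pairs, _ = apply_wgd(anc, p, np.random.default_rng(0))
        assert pairs and all(gp.class_label == WGD for gp in pairs)

    def test_interaction_gain_adds_pair_ppi(self):
        p = small_params(wgd_interaction_gain=1.0)
        anc = generate_ancestral(p)
        layers, pairs, _ = apply_wgd(anc, p, np.random.default_rng(0))
        assert all(layers.ppi.has_edge(gp.gene_a, gp.gene_b) for gp in pairs)


class TestApplySsd:
    def test_zero_events_unchanged(self):
        p = small_params()
        anc = generate_ancestral(p)
        layers, pairs, ev = apply_ssd_events(anc, p, np.random.default_rng(0), 0)
        assert layers.tf.edges == anc.tf.edges and pairs == [] and ev == []

    def test_target_duplication_creates_lambda(self):
        from ohnonet import BipartiteLayer, DirectedLayer, Multilayer, UndirectedLayer
        anc = Multilayer(DirectedLayer.from_edges([("T", "G00000")]),
                         UndirectedLayer(frozenset()), BipartiteLayer(frozenset()))
        p = small_params(ssd_retention=1.0, ssd_interaction_gain=0.0)
        seen_target_dup = False
        for seed in range(10):
            layers, pairs, ev = apply_ssd_events(anc, p, np.random.default_rng(seed), 1)
            (gp,) = pairs
            if gp.gene_a == "G00000":  # the pure target was duplicated
                seen_target_dup = True
                # T now regulates both parent and copy: one Λ instance
                assert count_lambda_motifs(layers.tf, [gp.key]).count == 1
        assert seen_target_dup

    def test_single_event_cannot_create_bifan(self):
        from ohnonet import BipartiteLayer, DirectedLayer, Multilayer, UndirectedLayer
        anc = Multilayer(DirectedLayer.from_edges([("T", "G"), ("T", "T")]),
                         UndirectedLayer(frozenset()), BipartiteLayer(frozenset()))
        p = small_params(ssd_retention=1.0)
        layers, pairs, _ = apply_ssd_events(anc, p, np.random.default_rng(3), 1)
        keys = [gp.key for gp in pairs]
        assert count_bifan(layers.tf, keys, keys).count == 0
        assert count_ffl_bifan(layers.tf, keys, keys).count == 0


class TestApplyRewiring:
    def test_zero_probability_identity(self):
        p = small_params(post_duplication_rewiring=0.0)
        anc = generate_ancestral(p)
        out, moves = apply_rewiring(anc, p, np.random.default_rng(0))
        assert out.tf.edges == anc.tf.edges and moves == []

    def test_simplicity_preserved(self):
        p = small_params(post_duplication_rewiring=0.5)
        anc = generate_ancestral(p)
        out, _ = apply_rewiring(anc, p, np.random.default_rng(0))
        assert all(u != v for u, v in out.ppi.edges)
        assert len(out.tf.edges) == len(anc.tf.edges)

    def test_full_rewiring_destroys_pair_similarity(self):
        p = small_params(n_ancestral_genes=150, tf_density=0.15,
                         wgd_retention=1.0, post_duplication_rewiring=1.0,
                         n_ssd_events=0, wgd_interaction_gain=0.0, seed=4)
        truth = generate(p)
        wgd = similarity_distribution(truth.layers.tf, truth.catalog.wgd_pairs,
                                      "regulators-TF", "WGD")
        import ohnonet
        bg_pairs = ohnonet.non_duplicated_pairs(
            truth.layers.tf.nodes, truth.catalog).sample(300, seed=0)
        bg = similarity_distribution(truth.layers.tf, bg_pairs, "regulators-TF")
        assert abs(np.mean(wgd.values) - np.mean(bg.values)) < \
            3 * np.std(wgd.values) / np.sqrt(len(wgd.values)) + \
            3 * np.std(bg.values) / np.sqrt(len(bg.values))


class TestGenerate:
    def test_deterministic(self):
        t1 = generate(small_params(seed=9))
        t2 = generate(small_params(seed=9))
        assert t1.layers.tf.edges == t2.layers.tf.edges
        assert t1.layers.ppi.edges == t2.layers.ppi.edges
        assert t1.layers.mirna.edges == t2.layers.mirna.edges
        assert set(t1.catalog.pairs) == set(t2.catalog.pairs)

    def test_event_log_replays_exactly(self):
        truth = generate(small_params(seed=2, n_ssd_events=15))
        replayed = replay_event_log(truth.ancestral, truth.event_log)
        assert replayed.tf.edges == truth.layers.tf.edges
        assert replayed.ppi.edges == truth.layers.ppi.edges
        assert replayed.mirna.edges == truth.layers.mirna.edges

    def test_classes_disjoint_and_labeled(self):
        truth = generate(small_params(seed=3, ssd_young_fraction=0.3))
        cat = truth.catalog
        assert cat.wgd_pairs & cat.ssd_pairs == set()
        assert cat.ssd_pairs & cat.young_ssd_pairs == set()
        assert len(cat.young_ssd_pairs) == 3  # 0.3 * 10 events

    def test_write_outputs(self, tmp_path):
        truth = generate(small_params(seed=1))
        files = truth.write(tmp_path)
        for key in ("tf", "ppi", "mirna", "catalog", "events"):
            assert key in files

    def test_wgd_dice_tracks_retention(self):
        """Mean partner-removed target Dice of WGD TF pairs ~= retention r."""
        means = {}
        for r in (0.2, 0.5, 0.8):
            per_seed = []
            for seed in range(5):
                p = SimulationParams(n_ancestral_genes=150, n_tfs=25, n_mirnas=2,
                                     tf_density=0.12, ppi_density=0.01,
                                     mirna_density=0.01, p_self_loop=0.0,
                                     wgd_retention=r, wgd_interaction_gain=0.0,
                                     n_ssd_events=0, post_duplication_rewiring=0.0,
                                     seed=seed)
                truth = generate(p)
                tf_pairs = [pr for pr in truth.catalog.wgd_pairs
                            if pr[0] in truth.layers.tf.regulators
                            and pr[1] in truth.layers.tf.regulators]
                d = similarity_distribution(truth.layers.tf, tf_pairs, "targets")
                per_seed.append(np.mean(d.values))
            means[r] = (np.mean(per_seed), np.std(per_seed, ddof=1))
        assert means[0.2][0] < means[0.5][0] < means[0.8][0]
        for r, (m, sd) in means.items():
            assert abs(m - r) < 3 * max(sd, 0.01)

    def test_class_separation_wgd_dominates_ssd(self):
        p = SimulationParams(n_ancestral_genes=300, n_tfs=30, n_mirnas=3,
                             tf_density=0.08, ppi_density=0.01, mirna_density=0.02,
                             wgd_retention=0.8, ssd_retention=0.3, n_ssd_events=120,
                             ssd_young_fraction=0.0, post_duplication_rewiring=0.02,
                             seed=6)
        truth = generate(p)
        wgd = similarity_distribution(truth.layers.tf, truth.catalog.wgd_pairs,
                                      "regulators-TF", "WGD")
        ssd = similarity_distribution(truth.layers.tf, truth.catalog.ssd_pairs,
                                      "regulators-TF", "SSD")
        assert len(wgd.values) >= 100
        from ohnonet import compare_distributions
        res = compare_distributions(wgd, ssd)
        assert np.median(wgd.values) > np.median(ssd.values)
        assert res.p_value < 0.01
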