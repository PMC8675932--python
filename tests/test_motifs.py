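"""Motif counting: hand-checked examples and brute-force oracle equivalence."""

import numpy as np
import pytest

from conftest import random_multilayer, random_pairs
from ohnonet import (BipartiteLayer, DirectedLayer, Multilayer, UndirectedLayer,
                     brute_force_census, classify_fbl_selfloops, count_bifan,
                     count_co_interaction, count_delta_motifs, count_ffl,
                     count_ffl_bifan, count_lambda_motifs, count_mixed_bifan,
                     count_motif, count_pair_ppi, count_v_motifs)
from ohnonet.motifs import MOTIF_NAMES


def U(*edges):
    return UndirectedLayer.from_edges(edges)


def D(*edges):
    return DirectedLayer.from_edges(edges)


def B(*edges):
    return BipartiteLayer.from_edges(edges)


class TestPairPpi:
    def test_direct_interaction(self):
        mc = count_pair_ppi(U(("A", "B")), [("A", "B")])
        assert (mc.count, mc.denominator) == (1, 1)

    def test_no_edge_but_both_present(self):
        mc = count_pair_ppi(U(("A", "C"), ("B", "C")), [("A", "B")])
        assert (mc.count, mc.denominator) == (0, 1)

    def test_absent_gene_excluded_from_denominator(self):
        mc = count_pair_ppi(U(("A", "C")), [("A", "B")])
        assert (mc.count, mc.denominator) == (0, 0)
        assert mc.fraction is None


class TestCoInteraction:
    def test_single_third_protein(self):
        mc = count_co_interaction(U(("A", "W"), ("B", "W")), [("A", "B")])
        assert mc.count == 1

    def test_two_third_proteins(self):
        mc = count_co_interaction(U(("A", "W"), ("B", "W"), ("A", "V"), ("B", "V")),
                                  [("A", "B")])
        assert mc.count == 2

    def test_direct_edge_is_not_co_interaction(self):
        mc = count_co_interaction(U(("A", "B")), [("A", "B")])
        assert mc.count == 0

    def test_direct_edge_neither_required_nor_forbidden(self):
        with_edge = count_co_interaction(U(("A", "B"), ("A", "W"), ("B", "W")), [("A", "B")])
        without = count_co_interaction(U(("A", "W"), ("B", "W")), [("A", "B")])
        assert with_edge.count == without.count == 1


class TestVMotifs:
    def test_shared_target(self):
        mc = count_v_motifs(D(("A", "G"), ("B", "G")), [("A", "B")])
        assert (mc.count, mc.denominator) == (1, 1)

    def test_two_shared_targets(self):
        mc = count_v_motifs(D(("A", "G1"), ("A", "G2"), ("B", "G1"), ("B", "G2")),
                            [("A", "B")])
        assert mc.count == 2

    def test_pair_member_as_target_excluded(self):
        mc = count_v_motifs(D(("A", "B"), ("B", "B")), [("A", "B")])
        assert mc.count == 0

    def test_non_regulator_pair_ineligible(self):
        mc = count_v_motifs(D(("A", "G"), ("T", "B")), [("A", "B")])
        assert mc.denominator == 0


class TestLambdaAndDelta:
    def test_tf_lambda(self):
        mc = count_lambda_motifs(D(("T", "A"), ("T", "B")), [("A", "B")])
        assert (mc.motif_name, mc.count) == ("lambda_tf", 1)

    def test_mirna_lambda(self):
        mc = count_lambda_motifs(B(("m", "A"), ("m", "B")), [("A", "B")])
        assert (mc.motif_name, mc.count) == ("lambda_mirna", 1)

    def test_two_common_regulators(self):
        mc = count_lambda_motifs(D(("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B")),
                                 [("A", "B")])
        assert mc.count == 2

    def test_delta_requires_ppi_edge(self):
        tf = D(("T", "A"), ("T", "B"))
        assert count_delta_motifs(tf, U(("A", "B")), [("A", "B")]).count == 1
        assert count_delta_motifs(tf, U(("A", "C"), ("B", "C")), [("A", "B")]).count == 0

    def test_delta_carries_lambda_multiplicity(self):
        tf = D(("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B"))
        assert count_delta_motifs(tf, U(("A", "B")), [("A", "B")]).count == 2

    def test_delta_at_most_lambda(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            layers = random_multilayer(rng)
            pairs = random_pairs(rng)
            lam = count_lambda_motifs(layers.tf, pairs).count
            # restrict delta to the same eligible pairs: delta <= lambda holds per pair
            delta = count_delta_motifs(layers.tf, layers.ppi, pairs).count
            assert delta <= lam


class TestFblSelfloops:
    def test_fbl_with_both_self(self):
        cats = classify_fbl_selfloops(
            D(("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")), [("A", "B")])
        assert cats["fbl_both_self"] == [("A", "B")]

    def test_single_self_loop(self):
        cats = classify_fbl_selfloops(D(("A", "A")), [("A", "B")])
        assert cats["one_self"] == [("A", "B")]

    def test_no_edges_is_none(self):
        cats = classify_fbl_selfloops(D(("X", "Y")), [("A", "B")])
        assert cats["none"] == [("A", "B")]

    def test_one_way_self_placement(self):
        assert classify_fbl_selfloops(D(("A", "B"), ("A", "A")), [("A", "B")])[
            "one_way_self_regulator"] == [("A", "B")]
        assert classify_fbl_selfloops(D(("A", "B"), ("B", "B")), [("A", "B")])[
            "one_way_self_target"] == [("A", "B")]

    def test_every_pair_in_exactly_one_category(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            layers = random_multilayer(rng, n_genes=8)
            pairs = random_pairs(rng, n_genes=8, n_pairs=5)
            cats = classify_fbl_selfloops(layers.tf, pairs)
            assigned = [p for members in cats.values() for p in members]
            assert sorted(assigned) == sorted(pairs)


class TestFfl:
    def test_single_orientation(self):
        mc = count_ffl(D(("A", "B"), ("A", "G"), ("B", "G")), [("A", "B")])
        assert mc.count == 1

    def test_both_orientations(self):
        mc = count_ffl(D(("A", "B"), ("B", "A"), ("A", "G"), ("B", "G")), [("A", "B")])
        assert mc.count == 2

    def test_v_is_not_ffl(self):
        mc = count_ffl(D(("A", "G"), ("B", "G")), [("A", "B")])
        assert mc.count == 0


class TestBifanFamily:
    tf_2x2 = [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]

    def test_plain_bifan(self):
        mc = count_bifan(D(*self.tf_2x2), [("A", "B")], [("C", "D")])
        assert mc.count == 1

    def test_internal_edge_migrates_to_ffl_bifan(self):
        tf = D(*self.tf_2x2, ("A", "B"))
        assert count_bifan(tf, [("A", "B")], [("C", "D")]).count == 0
        assert count_ffl_bifan(tf, [("A", "B")], [("C", "D")]).count == 1

    def test_mutual_internal_edges_counted_once(self):
        tf = D(*self.tf_2x2, ("A", "B"), ("B", "A"))
        assert count_ffl_bifan(tf, [("A", "B")], [("C", "D")]).count == 1

    def test_missing_cross_edge(self):
        tf = D(("A", "C"), ("A", "D"), ("B", "C"))
        assert count_bifan(tf, [("A", "B")], [("C", "D")]).count == 0

    def test_no_internal_edge_no_ffl_bifan(self):
        assert count_ffl_bifan(D(*self.tf_2x2), [("A", "B")], [("C", "D")]).count == 0

    def test_shared_gene_pairs_excluded(self):
        tf = D(("A", "B"), ("A", "C"), ("B", "C"))  # would need target pair sharing A or B
        assert count_bifan(tf, [("A", "B")], [("A", "C")]).count == 0

    def test_disjointness_of_bifan_and_ffl_bifan(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            layers = random_multilayer(rng, n_genes=10)
            pairs = random_pairs(rng, n_genes=10, n_pairs=5)
            b = count_bifan(layers.tf, pairs, pairs, log_instances=True)
            fb = count_ffl_bifan(layers.tf, pairs, pairs, log_instances=True)
            assert set(b.instance_log) & set(fb.instance_log) == set()


class TestMixedBifan:
    def test_common_tf_and_mirna(self):
        layers = Multilayer(D(("T", "A"), ("T", "B")), U(("X", "Y")),
                            B(("m", "A"), ("m", "B")))
        assert count_mixed_bifan(layers.tf, layers.mirna, [("A", "B")]).count == 1

    def test_require_ppi_without_edge(self):
        layers = Multilayer(D(("T", "A"), ("T", "B")), U(("A", "X"), ("B", "X")),
                            B(("m", "A"), ("m", "B")))
        mc = count_mixed_bifan(layers.tf, layers.mirna, [("A", "B")],
                               require_ppi=True, ppi=layers.ppi)
        assert mc.count == 0

    def test_product_of_common_regulators(self):
        tf = D(("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B"))
        mi = B(("m1", "A"), ("m1", "B"), ("m2", "A"), ("m2", "B"),
               ("m3", "A"), ("m3", "B"))
        assert count_mixed_bifan(tf, mi, [("A", "B")]).count == 6


class TestOracleEquivalence:
    """Optimized counts equal exhaustive enumeration on random small graphs."""

    @pytest.mark.parametrize("motif", MOTIF_NAMES)
    def test_random_instances(self, motif):
        rng = np.random.default_rng(hash(motif) % 2**31)
        for _ in range(200):
            n = int(rng.integers(5, 15))
            layers = random_multilayer(rng, n_genes=n, n_mirnas=3,
                                       p=float(rng.uniform(0.1, 0.5)))
            pairs = random_pairs(rng, n_genes=n, n_pairs=int(rng.integers(1, 7)))
            fast = count_motif(motif, layers, pairs)
            slow = brute_force_census(layers, pairs, motif)
            assert fast.count == slow.count, (motif, pairs, layers)
            assert fast.denominator == slow.denominator

    def test_bifan_with_distinct_target_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            layers = random_multilayer(rng, n_genes=10, p=0.4)
            reg_pairs = random_pairs(rng, n_genes=10, n_pairs=4)
            tgt_pairs = random_pairs(rng, n_genes=10, n_pairs=4)
            for motif in ("bifan", "ffl_bifan"):
                fast = count_motif(motif, layers, reg_pairs, target_pairs=tgt_pairs)
                slow = brute_force_census(layers, reg_pairs, motif, target_pairs=tgt_pairs)
                assert fast.count == slow.count

    def test_guard_on_large_graphs(self):
        big = Multilayer(D(*[(f"a{i}", f"b{i}") for i in range(300)]),
                         U(("x", "y")), B(("m", "g")))
        with pytest.raises(ValueError, match="guard"):
            brute_force_census(big, [("x", "y")], "V")

    def test_empty_layers_all_zero(self):
        empty = Multilayer(DirectedLayer(frozenset()), UndirectedLayer(frozenset()),
                           BipartiteLayer(frozenset()))
        for motif in MOTIF_NAMES:
            assert brute_force_census(empty, [("A", "B")], motif).count == 0


class TestInvariants:
    def test_monotone_motifs_never_decrease_on_edge_addition(self):
        rng = np.random.default_rng(21)
        monotone = ("V", "lambda_tf", "lambda_mirna", "delta_tf", "ffl",
                    "co_interaction", "mixed_bifan")
        for _ in range(20):
            layers = random_multilayer(rng, n_genes=10, p=0.25)
            pairs = random_pairs(rng, n_genes=10, n_pairs=5)
            genes = sorted({g for g in layers.tf.nodes})
            if len(genes) < 2:
                continue
            u, v = rng.choice(len(genes), size=2, replace=False)
            bigger = Multilayer(
                DirectedLayer(layers.tf.edges | {(genes[u], genes[v])}),
                layers.ppi, layers.mirna)
            for motif in monotone:
                before = count_motif(motif, layers, pairs).count
                after = count_motif(motif, bigger, pairs).count
                assert after >= before, motif

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(33)
        layers = random_multilayer(rng, n_genes=10, p=0.3)
        pairs = random_pairs(rng, n_genes=10, n_pairs=5)
        ren = {g: f"Z{ord(c):03d}{g}" for g in layers.genes() for c in g[:1]}
        relabeled = Multilayer(
            DirectedLayer.from_edges((ren[u], ren[v]) for u, v in layers.tf.edges),
            UndirectedLayer.from_edges((ren[u], ren[v]) for u, v in layers.ppi.edges),
            BipartiteLayer.from_edges((m, ren[g]) for m, g in layers.mirna.edges))
        rpairs = [(ren[a], ren[b]) for a, b in pairs]
        for motif in ("V", "lambda_tf", "co_interaction", "ffl", "bifan"):
            assert count_motif(motif, layers, pairs).count == \
                count_motif(motif, relabeled, rpairs).count
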