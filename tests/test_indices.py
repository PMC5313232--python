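"""Both pairwise indices: the illustrated worked example, edge-class
taxonomy, brute-force oracle equivalence, and symmetry/range/decay
properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g2e.containers import GeneSetCatalog, GenomeGeneContent
from g2e.indices import (
    EdgeClassCounts,
    classify_edges,
    compute_pair_indices,
    functional_association_index,
    gene_set_present,
    gene_set_similarity,
    genome_content_similarity,
    pairwise_index_matrix,
)
from tests.conftest import random_content
from tests.test_mcl import weighted_network


def worked_example():
    """Eight-family gene set where exactly 4 families have the same
    presence/absence state in the two genomes: 3 shared-present, 1
    shared-absent, 4 exclusive to one genome."""
    gene_set = frozenset(f"p{k}" for k in range(1, 9))
    fam_a = frozenset({"p1", "p2", "p3", "p4", "p5"})
    fam_b = frozenset({"p1", "p2", "p3", "p6", "p7"})
    return gene_set, fam_a, fam_b


class TestGeneSetSimilarity:
    def test_worked_example_matching_count_and_per_gene_value(self):
        gene_set, fam_a, fam_b = worked_example()
        sim = gene_set_similarity(gene_set, fam_a, fam_b)
        assert sim * len(gene_set) == pytest.approx(4)
        assert sim == pytest.approx(0.5)

    def test_identical_genomes_give_one(self):
        fams = frozenset({"a", "b"})
        assert gene_set_similarity(frozenset({"a", "b", "z"}), fams, fams) == 1.0

    def test_matches_elementwise_oracle_on_random_inputs(self, rng):
        for _ in range(100):
            universe = [f"f{k}" for k in range(30)]
            gene_set = frozenset(
                rng.choice(universe, size=12, replace=False)
            )
            fam_a = frozenset(f for f in universe if rng.random() < 0.5)
            fam_b = frozenset(f for f in universe if rng.random() < 0.5)
            same = 0
            for f in gene_set:  # element-wise oracle
                in_a, in_b = f in fam_a, f in fam_b
                if in_a == in_b:
                    same += 1
            assert gene_set_similarity(gene_set, fam_a, fam_b) == (
                pytest.approx(same / 12, abs=1e-12)
            )


class TestGeneSetPresent:
    def test_boundary_is_inclusive(self):
        gene_set = frozenset(f"f{k}" for k in range(20))
        assert gene_set_present({"f0"}, gene_set, 0.05)

    def test_absent_when_no_overlap(self):
        gene_set = frozenset(f"f{k}" for k in range(20))
        assert not gene_set_present({"zz"}, gene_set, 0.05)

    def test_matches_fraction_comparison(self, rng):
        for _ in range(100):
            size = int(rng.integers(1, 25))
            gene_set = frozenset(f"f{k}" for k in range(size))
            genome = frozenset(
                f"f{k}" for k in range(size) if rng.random() < 0.3
            )
            frac = len(genome & gene_set) / size
            assert gene_set_present(genome, gene_set, 0.05) == (
                frac >= 0.05
            )


class TestGenomeContentSimilarity:
    def test_identical_genomes_score_one(self, small_catalog):
        content = GenomeGeneContent(
            {
                "g1": frozenset({"f1", "f5"}),
                "g2": frozenset({"f1", "f5"}),
            }
        )
        assert genome_content_similarity(
            "g1", "g2", content, small_catalog
        ) == pytest.approx(1.0)

    def test_undefined_when_no_set_qualifies(self, small_catalog):
        content = GenomeGeneContent(
            {
                "g1": frozenset({"zz1"}),
                "g2": frozenset({"zz2"}),
            }
        )
        assert math.isnan(
            genome_content_similarity("g1", "g2", content, small_catalog)
        )

    def test_unknown_genome_raises(self, small_catalog, small_content):
        with pytest.raises(KeyError):
            genome_content_similarity(
                "gA", "nope", small_content, small_catalog
            )

    def test_matrix_matches_naive_double_loop(self, rng):
        content = random_content(rng, n_genomes=20, n_families=50, p=0.4)
        fams = [f"f{k}" for k in range(50)]
        catalog = GeneSetCatalog(
            {
                f"S{j}": frozenset(fams[j * 8:(j + 1) * 8])
                for j in range(6)
            }
        )
        net = weighted_network([("f0", "f1", 0.5)])
        sim, _ = pairwise_index_matrix(content, catalog, net)
        ids = content.genome_ids
        for i, a in enumerate(ids):  # independent naive implementation
            for j, b in enumerate(ids):
                sims = []
                for members in catalog.sets.values():
                    if len(members) < 4:
                        continue
                    fa, fb = content.families(a), content.families(b)
                    pa = len(fa & members) / len(members) >= 0.05
                    pb = len(fb & members) / len(members) >= 0.05
                    if pa or pb:
                        agree = sum(
                            (f in fa) == (f in fb) for f in members
                        )
                        sims.append(agree / len(members))
                expected = np.mean(sims) if sims else np.nan
                got = sim.values[i, j]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)


class TestClassifyEdges:
    def test_six_classes_cover_and_partition_all_edges(self):
        # one edge of each class in a single network
        net = weighted_network(
            [
                ("a1", "a2", 0.5),   # A-A
                ("b1", "b2", 0.5),   # B-B
                ("a1", "b1", 0.5),   # A-B
                ("c1", "a2", 0.5),   # both-A
                ("c1", "b2", 0.5),   # both-B
                ("c1", "c2", 0.5),   # both-both
                ("a1", "zz", 0.5),   # outside the union: not induced
            ]
        )
        fam_a = {"a1", "a2", "c1", "c2"}
        fam_b = {"b1", "b2", "c1", "c2"}
        c = classify_edges(net, fam_a, fam_b)
        assert (c.aa, c.bb, c.ab, c.both_a, c.both_b, c.both_both) == (
            1, 1, 1, 1, 1, 1
        )
        assert len(EdgeClassCounts.__dataclass_fields__) == 6
        assert c.total() == 6  # every induced edge in exactly one class

    def test_single_cross_edge(self):
        net = weighted_network([("x", "y", 0.9)])
        c = classify_edges(net, {"x"}, {"y"})
        assert c.ab == 1 and c.total() == 1

    def test_identical_genomes_make_all_edges_both_both(self):
        net = weighted_network([("x", "y", 0.9), ("y", "z", 0.2)])
        fams = {"x", "y", "z"}
        c = classify_edges(net, fams, fams)
        assert c.both_both == c.total() == 2

    def test_counts_match_exhaustive_edge_walk(self, rng):
        import networkx as nx

        g = nx.gnp_random_graph(25, 0.2, seed=11)
        edges = [(f"f{u}", f"f{v}", 0.5) for u, v in g.edges]
        net = weighted_network(edges)
        for _ in range(50):
            fam_a = {f"f{k}" for k in range(25) if rng.random() < 0.5}
            fam_b = {f"f{k}" for k in range(25) if rng.random() < 0.5}
            c = classify_edges(net, fam_a, fam_b)
            counts = dict(aa=0, bb=0, ab=0, ba=0, oa=0, ob=0, oo=0)
            induced = 0
            for u, v, _ in edges:  # exhaustive brute-force labeling
                present = fam_a | fam_b
                if u not in present or v not in present:
                    continue
                induced += 1

                def lab(x):
                    if x in fam_a and x in fam_b:
                        return "both"
                    return "a" if x in fam_a else "b"

                lu, lv = sorted([lab(u), lab(v)])
                if (lu, lv) == ("a", "a"):
                    counts["aa"] += 1
                elif (lu, lv) == ("b", "b"):
                    counts["bb"] += 1
                elif (lu, lv) == ("a", "b"):
                    counts["ab"] += 1
                elif (lu, lv) == ("a", "both"):
                    counts["oa"] += 1
                elif (lu, lv) == ("b", "both"):
                    counts["ob"] += 1
                else:
                    counts["oo"] += 1
            assert (c.aa, c.bb, c.ab) == (
                counts["aa"], counts["bb"], counts["ab"]
            )
            assert (c.both_a, c.both_b, c.both_both) == (
                counts["oa"], counts["ob"], counts["oo"]
            )
            assert c.total() == induced


class TestFunctionalAssociation:
    def test_disjoint_genomes_with_only_cross_edges(self):
        net = weighted_network([("x", "y", 0.9), ("u", "v", 0.9)])
        assert functional_association_index(
            net, {"x", "u"}, {"y", "v"}
        ) == pytest.approx(1.0)

    def test_undefined_when_exclusive_families_induce_no_edges(self):
        net = weighted_network([("x", "y", 0.9)])
        assert math.isnan(
            functional_association_index(net, {"x", "y", "a"}, {"x", "y", "b"})
        )

    def test_equals_ratio_of_edge_class_counts(self, rng):
        import networkx as nx

        g = nx.gnp_random_graph(20, 0.3, seed=3)
        net = weighted_network(
            [(f"f{u}", f"f{v}", 0.5) for u, v in g.edges]
        )
        for _ in range(50):
            fam_a = {f"f{k}" for k in range(20) if rng.random() < 0.6}
            fam_b = {f"f{k}" for k in range(20) if rng.random() < 0.6}
            c = classify_edges(net, fam_a, fam_b)
            denom = c.aa + c.ab + c.bb
            got = functional_association_index(net, fam_a, fam_b)
            if denom == 0:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(c.ab / denom, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        import networkx as nx

        g = nx.gnp_random_graph(15, 0.3, seed=8)
        edges = [(f"f{u}", f"f{v}", 0.5) for u, v in g.edges]
        fam_a = {f"f{k}" for k in range(15) if rng.random() < 0.5}
        fam_b = {f"f{k}" for k in range(15) if rng.random() < 0.5}
        mapping = {f"f{k}": f"q{14 - k}" for k in range(15)}
        v1 = functional_association_index(
            weighted_network(edges), fam_a, fam_b
        )
        v2 = functional_association_index(
            weighted_network(
                [(mapping[u], mapping[v], w) for u, v, w in edges]
            ),
            {mapping[f] for f in fam_a},
            {mapping[f] for f in fam_b},
        )
        assert (math.isnan(v1) and math.isnan(v2)) or v1 == v2


class TestPairwiseMatrix:
    def test_identical_genomes_similarity_all_one(self, small_catalog):
        fams = frozenset({"f1", "f2", "f5", "f6"})
        content = GenomeGeneContent({g: fams for g in ("g1", "g2", "g3")})
        net = weighted_network([("f1", "f2", 0.5)])
        sim, _ = pairwise_index_matrix(content, small_catalog, net)
        np.testing.assert_allclose(sim.values, 1.0)

    def test_symmetry_exact(self, rng, small_catalog):
        content = random_content(rng, n_genomes=10, n_families=12)
        net = weighted_network([("f1", "f2", 0.5), ("f3", "f7", 0.8)])
        sim, assoc = pairwise_index_matrix(content, small_catalog, net)
        np.testing.assert_array_equal(sim.values, sim.values.T)
        nan = np.isnan(assoc.values)
        assert (nan == nan.T).all()
        np.testing.assert_array_equal(
            assoc.values[~nan], assoc.values.T[~nan]
        )

    def test_matches_per_pair_calls(self, rng):
        content = random_content(rng, n_genomes=12, n_families=40, p=0.45)
        fams = [f"f{k}" for k in range(40)]
        catalog = GeneSetCatalog(
            {f"S{j}": frozenset(fams[j * 6:(j + 1) * 6]) for j in range(6)}
        )
        import networkx as nx

        g = nx.gnp_random_graph(40, 0.1, seed=5)
        net = weighted_network(
            [(f"f{u}", f"f{v}", 0.5) for u, v in g.edges]
        )
        sim, assoc = pairwise_index_matrix(content, catalog, net)
        ids = content.genome_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pair = compute_pair_indices(
                    ids[i], ids[j], content, catalog, net
                )
                for got, want in (
                    (sim.values[i, j], pair.genome_content_similarity),
                    (assoc.values[i, j], pair.functional_association),
                ):
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)

    def test_association_diagonal_missing(self, rng, small_catalog):
        content = random_content(rng, n_genomes=5, n_families=12)
        net = weighted_network([("f1", "f2", 0.5)])
        _, assoc = pairwise_index_matrix(content, small_catalog, net)
        assert np.isnan(assoc.values.diagonal()).all()


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_monotone_degradation_of_similarity(data):
    """Deleting a shared family from both genomes keeps per-set
    similarity unchanged; deleting it from one genome only never
    increases it."""
    universe = [f"f{k}" for k in range(12)]
    gene_set = frozenset(universe)
    fam_a = frozenset(data.draw(
        st.sets(st.sampled_from(universe), min_size=1)
    ))
    fam_b = frozenset(data.draw(
        st.sets(st.sampled_from(universe), min_size=1)
    ))
    shared = fam_a & fam_b
    base = gene_set_similarity(gene_set, fam_a, fam_b)
    if shared:
        f = sorted(shared)[0]
        assert gene_set_similarity(
            gene_set, fam_a - {f}, fam_b - {f}
        ) == pytest.approx(base)
        assert gene_set_similarity(
            gene_set, fam_a - {f}, fam_b
        ) <= base + 1e-12
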