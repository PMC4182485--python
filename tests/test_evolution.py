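"""Repertoire comparison, p-distances, UPGMA and Fitch parsimony."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from seedatlas import (
    DefinitionMismatchError,
    Repertoire,
    compare_repertoires,
    distance_matrix,
    fitch_gain_loss,
    is_ultrametric,
    load_species_tree,
    pairwise_distance,
    upgma,
)
from seedatlas.evolution import cophenetic_distances
from seedatlas.nomenclature import Seed


def _repertoire(cluster, seqs):
    rep = Repertoire(cluster_id=cluster)
    for s in seqs:
        rep.seeds[s] = Seed(sequence=s, definition="mer7")
    return rep


class TestCompareRepertoires:
    def test_mouse_human_active_sets(self, mouse, human, mouse_calls,
                                     human_calls):
        a = Repertoire.from_calls("m", mouse_calls, mouse.hairpins, arm="3p")
        b = Repertoire.from_calls("h", human_calls, human.hairpins, arm="3p")
        cmp_ = compare_repertoires(a, b)
        assert cmp_.only_a == ["AAGUGCC"]
        assert cmp_.only_b == []
        assert cmp_.shared == ["AAGUGCU", "AGUGCCG", "GUGCCGC"]
        assert cmp_.wobble_bridged == {"AAGUGCC": ["AAGUGCU"]}

    def test_identical_repertoires(self):
        a = _repertoire("a", ["AAGUGCU", "AGUGCCG"])
        b = _repertoire("b", ["AAGUGCU", "AGUGCCG"])
        cmp_ = compare_repertoires(a, b)
        assert cmp_.only_a == [] and cmp_.only_b == []
        assert cmp_.wobble_bridged == {}

    def test_symmetry(self):
        a = _repertoire("a", ["AAGUGCC", "AAGUGCU"])
        b = _repertoire("b", ["AAGUGCU", "GUGCCGC"])
        ab = compare_repertoires(a, b)
        ba = compare_repertoires(b, a)
        assert ab.shared == ba.shared
        assert ab.only_a == ba.only_b and ab.only_b == ba.only_a
        assert ab.wobble_bridged == ba.wobble_bridged

    def test_definition_mismatch(self):
        a = _repertoire("a", ["AAGUGCC"])
        b = Repertoire(cluster_id="b")
        b.seeds["AAGUGC"] = Seed(sequence="AAGUGC", definition="mer6")
        with pytest.raises(DefinitionMismatchError):
            compare_repertoires(a, b)


class TestPairwiseDistance:
    def test_identical(self):
        assert pairwise_distance("ACGUACGU", "ACGUACGU") == 0.0

    def test_single_mismatch(self):
        assert pairwise_distance("ACGU", "AGGU") == 0.25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("", "ACGU")

    def test_against_exhaustive_alignment_oracle(self):
        """Enumerate every global alignment of short strings; the reported
        (cost, columns) pair must be optimal-cost and realizable."""

        def all_alignments(a, b):
            # yields (cost, columns) for every alignment path
            def rec(i, j, cost, cols):
                if i == len(a) and j == len(b):
                    yield cost, cols
                    return
                if i < len(a) and j < len(b):
                    yield from rec(i + 1, j + 1, cost + (a[i] != b[j]),
                                   cols + 1)
                if i < len(a):
                    yield from rec(i + 1, j, cost + 1, cols + 1)
                if j < len(b):
                    yield from rec(i, j + 1, cost + 1, cols + 1)

            return list(rec(0, 0, 0, 0))

        rng = np.random.default_rng(9)
        bases = list("ACGU")
        for _ in range(25):
            a = "".join(rng.choice(bases, size=int(rng.integers(2, 8))))
            b = "".join(rng.choice(bases, size=int(rng.integers(2, 8))))
            paths = all_alignments(a, b)
            min_cost = min(c for c, _ in paths)
            p = pairwise_distance(a, b)
            valid = {c / n for c, n in paths if c == min_cost}
            assert p in valid

    def test_one_indel(self):
        assert pairwise_distance("ACGGU", "ACGU") == pytest.approx(1 / 5)


class TestUpgma:
    def test_identical_sequences_merge_at_zero(self):
        dm = distance_matrix({"a": "ACGU", "b": "ACGU", "c": "ACGU"})
        tree = upgma(dm)
        assert all((e.length or 0) == 0 for e in tree.preorder_edge_iter())

    def test_hand_computed_four_taxa(self):
        labels = list("ABCD")
        dm = pd.DataFrame([[0, 2, 6, 6], [2, 0, 6, 6],
                           [6, 6, 0, 4], [6, 6, 4, 0]],
                          index=labels, columns=labels, dtype=float)
        tree = upgma(dm)
        coph = cophenetic_distances(tree)
        # ultrametric input is reproduced exactly
        assert np.allclose(coph.loc[labels, labels].to_numpy(),
                           dm.to_numpy())
        newick = tree.as_string(schema="newick")
        assert "(A:1.0,B:1.0)" in newick and "(C:2.0,D:2.0)" in newick

    def test_rejects_asymmetric(self):
        dm = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"],
                          columns=["a", "b"], dtype=float)
        with pytest.raises(ValueError):
            upgma(dm)

    def test_ultrametric_and_matches_scipy_reference(self):
        """Independent oracle: scipy average linkage on random matrices
        (compared through cophenetic distances)."""
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(23)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(20):
            pts = rng.random((6, 4))
            m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = pd.DataFrame(m, index=labels, columns=labels)
            tree = upgma(dm)
            assert is_ultrametric(tree)
            ours = cophenetic_distances(tree).loc[labels, labels].to_numpy()
            ref = squareform(cophenet(average(squareform(m))))
            assert np.allclose(ours, ref, atol=1e-9)

    def test_fixture_hairpins_cluster_by_seed_extension(self, mouse, human):
        """The CG-extension hairpins (the pre-miR-371 co-ortholog group)
        form one UPGMA block, separated from the 2-7U hairpins."""
        seqs = {h.id: h.sequence for h in mouse.hairpins + human.hairpins}
        tree = upgma(distance_matrix(seqs))
        tns = tree.taxon_namespace
        cg = {"miR-292", "miR-293", "miR-371"}
        mrca = tree.mrca(taxa=[tns.get_taxon(x) for x in cg])
        below = {l.taxon.label for l in mrca.leaf_iter()}
        assert "miR-294" not in below and "miR-372" not in below


class TestFitch:
    def _toy_tree(self, newick):
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = True
        return t

    def test_constant_character(self):
        t = self._toy_tree("((a,b),(c,d));")
        res = fitch_gain_loss(t, {x: 1 for x in "abcd"})
        assert res.min_changes == 0 and res.events == []

    def test_two_non_sister_leaves_cost_two(self):
        t = self._toy_tree("((a,b),(c,d));")
        res = fitch_gain_loss(t, {"a": 1, "b": 0, "c": 1, "d": 0})
        assert res.min_changes == 2

    def test_epitheria_minus_afrotheria_gain(self):
        """The CG-dependent shifted seeds map to a single gain on the edge
        to the non-Afrotherian Epitheria (Boreoeutheria)."""
        tree = load_species_tree()
        afro = {"ech-tel", "lox-afr", "pro-cap"}
        presence = {l.taxon.label: 0 if (l.taxon.label in afro
                                         or l.taxon.label == "das-nov") else 1
                    for l in tree.leaf_node_iter()}
        res = fitch_gain_loss(tree, presence)
        assert res.min_changes == 1
        assert len(res.events) == 1
        ev = res.events[0]
        assert ev.kind == "gain" and ev.in_all_optima
        assert set(ev.clade) == {"hom-sap", "mus-mus", "ict-tri", "och-pri",
                                 "eri-eur", "myo-luc", "can-fam", "equ-cab",
                                 "bos-tau", "tur-tru"}

    def test_leaf_label_mismatch(self):
        t = self._toy_tree("((a,b),(c,d));")
        with pytest.raises(KeyError):
            fitch_gain_loss(t, {"a": 1, "b": 0, "c": 1})

    def test_matches_exhaustive_oracle_on_random_trees(self):
        """Fitch count equals the exhaustive minimum over all ancestral
        labelings for random <=8-leaf trees and characters."""
        rng = np.random.default_rng(31)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            # random topology by sequential joining
            nodes = [dendropy.Node(taxon=dendropy.Taxon(label=l))
                     for l in labels]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                parent = dendropy.Node()
                parent.add_child(nodes[i])
                parent.add_child(nodes[j])
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
                nodes.append(parent)
            tns = dendropy.TaxonNamespace([l for l in labels])
            tree = dendropy.Tree(taxon_namespace=tns)
            tree.seed_node = nodes[0]
            tree.is_rooted = True
            presence = {l: int(rng.integers(0, 2)) for l in labels}
            res = fitch_gain_loss(tree, presence)

            internals = [x for x in tree.preorder_internal_node_iter()]
            best = None
            for combo in itertools.product((0, 1), repeat=len(internals)):
                assign = dict(zip(internals, combo))
                for leaf in tree.leaf_node_iter():
                    assign[leaf] = presence[leaf.taxon.label]
                cost = sum(assign[x] != assign[x.parent_node]
                           for x in tree.preorder_node_iter()
                           if x.parent_node is not None)
                best = cost if best is None else min(best, cost)
            assert res.min_changes == best
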