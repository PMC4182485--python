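"""Seed-repertoire comparison, UPGMA clustering and Fitch gain/loss
reconstruction.

Repertoires are compared as sets of seed sequences, with an optional
wobble-equivalence report: a seed private to one cluster whose target sites
are nevertheless recognized by a shared seed through the position-8 G:U
wobble does not expand the target repertoire, but it is reported as
*bridged*, never silently merged into the shared set.

Hairpins are clustered by pairwise p-distance under a global alignment
(match 0, mismatch 1, gap 1) followed by average-linkage UPGMA with a
deterministic lexicographic tie-break; the output tree is ultrametric by
construction.  Seed gain/loss histories on a user-supplied species tree are
reconstructed by Fitch small parsimony, with all minimal ancestral labelings
enumerated on small trees so that gains and losses can be placed on edges
with explicit ambiguity flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .design import match_seed_to_target
from .errors import DefinitionMismatchError
from .nomenclature import Seed, revcomp_rna, to_rna


# --------------------------------------------------------------------------
# repertoires
# --------------------------------------------------------------------------

@dataclass
class Repertoire:
    """The set of seeds expressed by one cluster, with provenance.

    ``seeds`` maps seed sequence -> :class:`Seed`; ``provenance`` maps seed
    sequence -> list of (designation name, status) pairs that contributed it.
    """

    cluster_id: str
    seeds: dict[str, Seed] = field(default_factory=dict)
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def definition(self) -> str | None:
        for s in self.seeds.values():
            return s.definition
        return None

    def sequences(self) -> set[str]:
        return set(self.seeds)

    @classmethod
    def from_calls(cls, cluster_id: str, calls, hairpins,
                   definition: str = "mer7",
                   arm: str | None = None) -> "Repertoire":
        from .activity import active_seed_set
        from .nomenclature import derive_seed
        hp = {h.id: h for h in hairpins}
        rep = cls(cluster_id=cluster_id)
        for seed in active_seed_set(calls, hairpins, definition, arm=arm):
            rep.seeds[seed.sequence] = seed
        for call in calls:
            if not call.is_active:
                continue
            if arm is not None and call.designation.arm != arm:
                continue
            s = derive_seed(hp[call.designation.hairpin_id], call.designation,
                            definition)
            rep.provenance.setdefault(s.sequence, []).append(
                (call.designation.name, call.status))
        return rep


@dataclass
class RepertoireComparison:
    shared: list[str]
    only_a: list[str]
    only_b: list[str]
    wobble_bridged: dict[str, list[str]]


def compare_repertoires(a: Repertoire, b: Repertoire,
                        wobble_equiv: bool = True) -> RepertoireComparison:
    """Set algebra on two repertoires' seed sequences.

    ``wobble_bridged`` maps each private seed to the shared seeds that
    recognize its target sites via the position-8 wobble (empty unless
    ``wobble_equiv`` and the definition is 7mer).
    """
    if a.definition and b.definition and a.definition != b.definition:
        raise DefinitionMismatchError(
            f"cannot compare {a.definition} and {b.definition} repertoires"
        )
    sa, sb = a.sequences(), b.sequences()
    shared = sorted(sa & sb)
    only_a = sorted(sa - sb)
    only_b = sorted(sb - sa)
    bridged: dict[str, list[str]] = {}
    if wobble_equiv and (a.definition or b.definition) == "mer7":
        for seed in only_a + only_b:
            window = revcomp_rna(seed)
            hits = [t for t in shared
                    if t != seed and match_seed_to_target(t, window, True)]
            if hits:
                bridged[seed] = hits
    return RepertoireComparison(shared, only_a, only_b, bridged)


# --------------------------------------------------------------------------
# alignment distance
# --------------------------------------------------------------------------

def pairwise_distance(seq_a: str, seq_b: str) -> float:
    """Global-alignment p-distance: (mismatches + gaps) / alignment columns.

    Needleman-Wunsch with unit mismatch and gap costs (no affine term); the
    traceback prefers diagonal over up over left, making the reported
    alignment length deterministic among co-optimal alignments.
    """
    a, b = to_rna(seq_a), to_rna(seq_b)
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    cost = np.zeros((n + 1, m + 1), dtype=np.int64)
    cost[:, 0] = np.arange(n + 1)
    cost[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = cost[i], cost[i - 1]
        for j in range(1, m + 1):
            row[j] = min(prev[j - 1] + (ai != b[j - 1]),
                         prev[j] + 1, row[j - 1] + 1)
    # deterministic traceback: diagonal > up > left
    i, j, ncols = n, m, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and cost[i, j] == cost[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            i, j = i - 1, j - 1
        elif i > 0 and cost[i, j] == cost[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
        ncols += 1
    return float(cost[n, m]) / ncols


def distance_matrix(sequences: Mapping[str, str]) -> pd.DataFrame:
    labels = sorted(sequences)
    dm = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            d = pairwise_distance(sequences[la], sequences[lb])
            dm.loc[la, lb] = dm.loc[lb, la] = d
    return dm


# --------------------------------------------------------------------------
# UPGMA
# --------------------------------------------------------------------------

def upgma(dm: pd.DataFrame) -> dendropy.Tree:
    """Average-linkage UPGMA on a symmetric zero-diagonal distance matrix.

    Equal-distance merges break ties by the lexicographically smallest leaf
    label of each cluster.  The returned tree is rooted and ultrametric.
    """
    mat = dm.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = [str(x) for x in dm.index]

    tns = dendropy.TaxonNamespace(labels)
    clusters: dict[str, dict] = {}
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        clusters[lab] = {"node": node, "height": 0.0, "size": 1}
    dist = {frozenset((x, y)): dm.loc[x, y]
            for i, x in enumerate(labels) for y in labels[i + 1:]}

    while len(clusters) > 1:
        pair = min(dist, key=lambda k: (dist[k],) + tuple(sorted(k)))
        ka, kb = sorted(pair)
        d = dist.pop(pair)
        ca, cb = clusters.pop(ka), clusters.pop(kb)
        height = d / 2.0
        parent = dendropy.Node()
        for child in (ca, cb):
            child["node"].edge.length = height - child["height"]
            parent.add_child(child["node"])
        size = ca["size"] + cb["size"]
        for other in list(clusters):
            da = dist.pop(frozenset((ka, other)))
            db = dist.pop(frozenset((kb, other)))
            dist[frozenset((ka, other))] = \
                (ca["size"] * da + cb["size"] * db) / size
        clusters[ka] = {"node": parent, "height": height, "size": size}

    root = next(iter(clusters.values()))["node"]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def root_to_leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = list(root_to_leaf_depths(tree).values())
    return max(depths) - min(depths) <= tol


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a rooted tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, la in enumerate(labels):
        ta = tree.taxon_namespace.get_taxon(la)
        for lb in labels[i + 1:]:
            tb = tree.taxon_namespace.get_taxon(lb)
            d = pdm.patristic_distance(ta, tb)
            out.loc[la, lb] = out.loc[lb, la] = d
    return out


# --------------------------------------------------------------------------
# Fitch parsimony
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitchEvent:
    """One gain or loss on the edge above the clade with the given leaves.

    ``in_all_optima`` is True when every minimal ancestral labeling places
    an event of this kind on this edge.
    """

    clade: tuple[str, ...]
    kind: str  # "gain" | "loss"
    in_all_optima: bool


@dataclass
class FitchResult:
    min_changes: int
    events: list[FitchEvent]
    n_optima: int | None = None  # None when not enumerated (large trees)


def _leaf_labels(node) -> tuple[str, ...]:
    return tuple(sorted(l.taxon.label for l in node.leaf_iter()))


def fitch_gain_loss(tree: dendropy.Tree,
                    presence: Mapping[str, int],
                    enumerate_leq: int = 16) -> FitchResult:
    """Fitch small parsimony for a binary presence/absence character.

    ``presence`` maps every leaf label to 0/1.  On trees with at most
    ``enumerate_leq`` leaves all minimal ancestral labelings are enumerated
    and each event is flagged ambiguous or certain; on larger trees a single
    minimal labeling (parent-state preference) is reported.
    """
    leaves = [l for l in tree.leaf_node_iter()]
    labels = [l.taxon.label for l in leaves]
    missing = sorted(set(labels) - set(presence))
    extra = sorted(set(presence) - set(labels))
    if missing or extra:
        raise KeyError(
            f"leaf-label mismatch: missing from presence map {missing}, "
            f"not on tree {extra}"
        )

    # bottom-up Fitch pass
    state_sets: dict = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state_sets[node] = {int(presence[node.taxon.label])}
        else:
            sets = [state_sets[c] for c in node.child_nodes()]
            inter = set.intersection(*sets)
            if inter:
                state_sets[node] = inter
            else:
                state_sets[node] = set.union(*sets)
                changes += 1

    internals = [n for n in tree.preorder_internal_node_iter()]
    if len(leaves) <= enumerate_leq:
        leaf_state = {n: next(iter(state_sets[n])) for n in leaves}
        best, optima = None, []
        for combo in product((0, 1), repeat=len(internals)):
            assign = dict(zip(internals, combo))
            assign.update(leaf_state)
            cost = sum(assign[n] != assign[n.parent_node]
                       for n in tree.preorder_node_iter()
                       if n.parent_node is not None)
            if best is None or cost < best:
                best, optima = cost, [assign]
            elif cost == best:
                optima.append(assign)
        assert best == changes, "Fitch count disagrees with enumeration"
        edge_kinds: dict[tuple[str, ...], list] = {}
        for assign in optima:
            for n in tree.preorder_node_iter():
                if n.parent_node is None:
                    continue
                p, c = assign[n.parent_node], assign[n]
                kind = None if p == c else ("gain" if c == 1 else "loss")
                edge_kinds.setdefault(_leaf_labels(n), []).append(kind)
        events = []
        for clade, kinds in sorted(edge_kinds.items()):
            for kind in ("gain", "loss"):
                hits = sum(k == kind for k in kinds)
                if hits:
                    events.append(FitchEvent(clade, kind,
                                             in_all_optima=hits == len(optima)))
        return FitchResult(min_changes=changes, events=events,
                           n_optima=len(optima))

    # large trees: one minimal labeling, preferring the parent's state
    assign = {}
    for node in tree.preorder_node_iter():
        options = state_sets[node]
        if node.parent_node is not None and assign[node.parent_node] in options:
            assign[node] = assign[node.parent_node]
        else:
            assign[node] = min(options)
    events = []
    for n in tree.preorder_node_iter():
        if n.parent_node is None:
            continue
        p, c = assign[n.parent_node], assign[n]
        if p != c:
            events.append(FitchEvent(_leaf_labels(n),
                                     "gain" if c == 1 else "loss",
                                     in_all_optima=False))
    return FitchResult(min_changes=changes, events=sorted(
        events, key=lambda e: e.clade), n_optima=None)


def load_species_tree(path=None) -> dendropy.Tree:
    """Load a Newick species tree; defaults to the packaged placental
    mammal topology (14 species spanning Xenarthra, Afrotheria and
    Boreoeutheria)."""
    if path is None:
        ref = resources.files("seedatlas.data") / "placentalia.nwk"
        data = ref.read_text()
        tree = dendropy.Tree.get(data=data, schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return tree
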