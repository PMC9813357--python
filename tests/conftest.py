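"""Shared fixtures and independent oracles.

The oracle helpers deliberately avoid the package's own bipartition and
patristic-distance code paths: splits are extracted with dendropy's
bipartition encoding and path lengths are accumulated by explicit ancestor
walks, so tree-building results are checked against independent machinery.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from woodbarcode import DistanceMatrix, SampleRecord, SampleTable
from woodbarcode.tree import PhyloTree


# --------------------------------------------------------------------- #
# independent oracles
# --------------------------------------------------------------------- #

def dendropy_splits(ptree: PhyloTree, include_trivial: bool = False):
    """Canonical bipartitions via dendropy's own encoding (oracle path)."""
    dt = ptree.dendropy_tree
    dt.encode_bipartitions()
    leaves = sorted(lf.taxon.label for lf in dt.leaf_node_iter())
    all_leaves = frozenset(leaves)
    smallest = leaves[0]
    n = len(leaves)
    out = set()
    for bip in dt.bipartition_encoding:
        taxa = dt.taxon_namespace.bitmask_taxa_list(bip.leafset_bitmask)
        side = frozenset(t.label for t in taxa) & all_leaves
        if not side or side == all_leaves:
            continue
        if not include_trivial and (len(side) <= 1 or len(side) >= n - 1):
            continue
        canon = all_leaves - side if smallest in side else side
        out.add(canon)
    return out


def walk_patristic(ptree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths by explicit ancestor walks (oracle path)."""
    dt = ptree.dendropy_tree
    depth = {dt.seed_node: 0.0}
    for nd in dt.preorder_node_iter():
        if nd is dt.seed_node:
            continue
        depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    leaves = sorted(dt.leaf_node_iter(), key=lambda l: l.taxon.label)

    def ancestors(nd):
        chain = {}
        while nd is not None:
            chain[nd] = depth[nd]
            nd = nd.parent_node
        return chain

    chains = {lf: ancestors(lf) for lf in leaves}
    ids = [lf.taxon.label for lf in leaves]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        common = chains[leaves[i]].keys() & chains[leaves[j]].keys()
        lca_depth = max(depth[c] for c in common)
        d[i, j] = d[j, i] = depth[leaves[i]] + depth[leaves[j]] - 2 * lca_depth
    return DistanceMatrix(ids, d)


def edge_length_map(ptree: PhyloTree) -> dict:
    """Canonical split (incl. trivial, keyed by the below-side canonical
    form) -> branch length; used to compare reconstructed branch lengths."""
    leaves = frozenset(l.taxon.label for l in ptree.dendropy_tree.leaf_node_iter())
    smallest = min(leaves)
    out = {}
    for side, nd in ptree.edge_sides():
        canon = leaves - side if smallest in side else side
        # degree-2 seed nodes give the same split twice; sum the two halves
        out[canon] = out.get(canon, 0.0) + (nd.edge.length or 0.0)
    return out


def random_unrooted_tree(
    rng: np.random.Generator,
    n_leaves: int,
    min_len: float = 0.01,
    max_len: float = 1.0,
    labels=None,
) -> PhyloTree:
    """Uniform random binary unrooted tree by sequential edge attachment,
    with i.i.d. uniform edge lengths."""
    assert n_leaves >= 3
    if labels is None:
        labels = [f"t{i:02d}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    attachable = []
    for i in range(3):
        ch = tree.seed_node.new_child(taxon=tns.get_taxon(labels[i]))
        attachable.append(ch)
    for i in range(3, n_leaves):
        target = attachable[int(rng.integers(0, len(attachable)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = mid.new_child(taxon=tns.get_taxon(labels[i]))
        attachable.extend([mid, leaf])
    for nd in tree:
        if nd is not tree.seed_node:
            nd.edge.length = float(rng.uniform(min_len, max_len))
    return PhyloTree(tree)


# --------------------------------------------------------------------- #
# fixtures
# --------------------------------------------------------------------- #

@pytest.fixture
def rng():
    return np.random.default_rng(20230104)


def make_table(ref_species: dict, queries=(), genus_of=None) -> SampleTable:
    """ref_species: sample_id -> 'Genus species'; queries: iterable of ids."""
    entries = {}
    for sid, sp in ref_species.items():
        entries[sid] = SampleRecord(sp, "reference", sp.split()[0])
    for q in queries:
        g = genus_of(q) if genus_of else "Genus"
        entries[q] = SampleRecord("unknown", "query", g)
    return SampleTable(entries)


@pytest.fixture
def five_leaf_table():
    return make_table(
        {
            "a1": "Genus alpha",
            "a2": "Genus alpha",
            "b1": "Genus beta",
            "b2": "Genus beta",
            "c1": "Genus gamma",
        },
        queries=["q"],
    )


@pytest.fixture(scope="session")
def bench_small():
    """Tiny benchmark: 3 species x 2 refs, 3 queries, 2 short loci."""
    from woodbarcode import SimulationConfig, make_benchmark

    cfg = SimulationConfig(
        seed=11,
        n_species=3,
        refs_per_species=2,
        n_queries=3,
        loci=(("ITS2", 120), ("matK", 150)),
    )
    return make_benchmark(cfg)


@pytest.fixture(scope="session")
def bench_default():
    """The default study-scale benchmark: 5 species x 3 refs, 10 queries,
    loci of 181/209/280 bp, divergences 0.10/0.005."""
    from woodbarcode import SimulationConfig, make_benchmark

    return make_benchmark(SimulationConfig(seed=42))
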