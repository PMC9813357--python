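"""Unrooted phylogenetic trees with branch lengths and bootstrap supports.

``PhyloTree`` is a thin wrapper around :class:`dendropy.Tree` that adds the
split (bipartition) bookkeeping the identification layer needs:

* every edge induces a bipartition of the leaf set; the *canonical* form of a
  bipartition is the side that does **not** contain the globally smallest
  leaf id (lexicographic order), so two trees over the same leaves can be
  compared as plain sets;
* bootstrap supports are stored per canonical bipartition, as fractions in
  [0, 1], and serialised to Newick as integer-percent internal node labels.

Trees are always treated as unrooted; a degree-2 "root" only appears in the
two-leaf case.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

from .errors import NewickError

__all__ = ["PhyloTree"]


class PhyloTree:
    """An unrooted tree over named leaves.

    Parameters
    ----------
    tree:
        A dendropy tree; leaf taxa must be labelled and unique. The tree is
        forced unrooted.
    supports:
        Optional map from canonical bipartition (``frozenset`` of leaf ids)
        to bootstrap support in [0, 1].
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        supports: Optional[dict[frozenset, float]] = None,
    ) -> None:
        tree.is_rooted = False
        self._tree = tree
        self.supports: dict[frozenset, float] = dict(supports or {})
        #: free-form provenance (e.g. bootstrap replicate accounting)
        self.info: dict = {}

    # ------------------------------------------------------------------ #
    # basic structure
    # ------------------------------------------------------------------ #

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_ids(self) -> list[str]:
        """Sorted leaf labels."""
        return sorted(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def n_edges(self) -> int:
        return sum(1 for nd in self._tree if nd is not self._tree.seed_node)

    def total_path_length(self, a: str, b: str) -> float:
        """Patristic distance between two leaves."""
        pdm = self._tree.phylogenetic_distance_matrix()
        tns = self._tree.taxon_namespace
        return pdm.patristic_distance(
            tns.get_taxon(a), tns.get_taxon(b)
        )

    # ------------------------------------------------------------------ #
    # bipartitions
    # ------------------------------------------------------------------ #

    def canonical(self, side) -> frozenset:
        """Canonical form of one side of a leaf bipartition: the side not
        containing the smallest leaf id."""
        leaves = frozenset(self.leaf_ids)
        side = frozenset(side)
        if min(leaves) in side:
            return leaves - side
        return side

    def _leafsets_below(self) -> dict:
        below: dict = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                below[nd] = frozenset([nd.taxon.label])
            else:
                acc: frozenset = frozenset()
                for ch in nd.child_nodes():
                    acc = acc | below[ch]
                below[nd] = acc
        return below

    def edge_sides(self) -> Iterator[tuple[frozenset, "dendropy.Node"]]:
        """Yield (leafset-below-edge, head node) for every edge, including
        trivial (single-leaf) edges. The complement of each yielded side is
        the other half of the bipartition."""
        below = self._leafsets_below()
        for nd in self._tree.preorder_node_iter():
            if nd is self._tree.seed_node:
                continue
            yield below[nd], nd

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical bipartitions induced by the edges.

        Trivial splits (one leaf vs the rest) are excluded unless requested.
        """
        n = self.n_leaves
        out: set[frozenset] = set()
        leaves = frozenset(self.leaf_ids)
        smallest = min(leaves)
        for side, _ in self.edge_sides():
            if not include_trivial and (len(side) <= 1 or len(side) >= n - 1):
                continue
            canon = leaves - side if smallest in side else side
            out.add(canon)
        return out

    def split_edge_map(self, include_trivial: bool = False) -> dict:
        """Map canonical bipartition -> head node of the inducing edge."""
        n = self.n_leaves
        leaves = frozenset(self.leaf_ids)
        smallest = min(leaves)
        out = {}
        for side, nd in self.edge_sides():
            if not include_trivial and (len(side) <= 1 or len(side) >= n - 1):
                continue
            canon = leaves - side if smallest in side else side
            out[canon] = nd
        return out

    # ------------------------------------------------------------------ #
    # Newick serialisation
    # ------------------------------------------------------------------ #

    def newick(self) -> str:
        """Newick string: branch lengths in fixed 6-decimal format; bootstrap
        supports (if any) as integer-percent internal node labels."""
        work = self._tree.clone(depth=1)
        if self.supports:
            view = PhyloTree(work)
            for canon, nd in view.split_edge_map(include_trivial=False).items():
                if canon in self.supports:
                    nd.label = str(int(round(self.supports[canon] * 100)))
        return work.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".6f",
        ).strip() + "\n"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string; numeric internal-node labels are read back
        as integer-percent bootstrap supports."""
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        tree = cls(dt)
        supports: dict[frozenset, float] = {}
        n = tree.n_leaves
        leaves = frozenset(tree.leaf_ids)
        smallest = min(leaves) if leaves else None
        for side, nd in tree.edge_sides():
            if nd.is_leaf() or nd.label is None:
                continue
            if len(side) <= 1 or len(side) >= n - 1:
                continue
            try:
                val = float(nd.label)
            except ValueError:
                continue
            canon = leaves - side if smallest in side else side
            supports[canon] = val / 100.0
        tree.supports = supports
        return tree

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick())

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves})"
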