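"""Neighbour-joining tree construction (Saitou & Nei agglomeration).

Plain NJ on a complete distance matrix: at each step the pair (i, j)
minimising

    Q(i, j) = (n - 2) * d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined; branch lengths to the new node come from the standard two-point
formulas, and distances to the remaining nodes from the reduction
d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2. The last three nodes are
resolved with the three-point formulas.

Determinism: when several pairs tie on Q, the pair whose clusters have the
lexicographically smallest (representative_i, representative_j) ids is
chosen, where a cluster's representative is its smallest leaf id. Estimated
negative branch lengths are clamped to zero (length only, no transfer to the
sibling edge).
"""

from __future__ import annotations

import logging
from typing import Optional

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .errors import UndefinedDistanceError
from .tree import PhyloTree

__all__ = ["nj"]

logger = logging.getLogger(__name__)


def _clamp(x: float) -> float:
    return x if x > 0.0 else 0.0


def nj(dm: DistanceMatrix, trace: Optional[list] = None) -> PhyloTree:
    """Build an unrooted NJ tree from a complete distance matrix.

    Parameters
    ----------
    dm:
        Distance matrix; must contain no undefined pairs.
    trace:
        Optional list that receives one ``(rep_i, rep_j, length_i, length_j)``
        tuple per join, for debugging.

    Raises
    ------
    UndefinedDistanceError
        If the matrix has undefined entries (drop the affected samples or
        reduce ``min_overlap``), or fewer than two taxa.
    """
    if dm.has_undefined:
        pairs = sorted(dm.undefined_pairs)[:5]
        raise UndefinedDistanceError(
            f"distance matrix has {len(dm.undefined_pairs)} undefined "
            f"pair(s), e.g. {pairs}; drop a sample or adjust min_overlap "
            "before tree building"
        )
    n = len(dm.ids)
    if n < 2:
        raise UndefinedDistanceError("need at least 2 taxa for a tree")

    tns = dendropy.TaxonNamespace(list(dm.ids))
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(sid)) for sid in dm.ids
    ]
    # cluster representative = smallest leaf id, used only for tie-breaking
    reps = list(dm.ids)
    D = dm.values.astype(float).copy()

    if n == 2:
        # two taxa: a single path of total length d, represented with a
        # degree-2 junction splitting the length evenly
        d = float(D[0, 1])
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        nodes[0].edge.length = _clamp(d / 2.0)
        nodes[1].edge.length = _clamp(d / 2.0)
        return PhyloTree(tree)

    n_clamped = 0
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qmin = Q[iu].min()
        ties = [
            (i, j)
            for i, j in zip(*iu)
            if Q[i, j] == qmin
        ]
        i, j = min(ties, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            n_clamped += int(li < 0) + int(lj < 0)
        if trace is not None:
            trace.append((reps[i], reps[j], _clamp(li), _clamp(lj)))

        new = dendropy.Node()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li)
        nodes[j].edge.length = _clamp(lj)

        dk = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dk[keep]])
        D = np.hstack([D, np.append(dk[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # three-point termination
    tree = dendropy.Tree(taxon_namespace=tns)
    center = tree.seed_node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    order = sorted(range(3), key=lambda k: reps[k])
    for k in order:
        if lens[k] < 0:
            n_clamped += 1
        center.add_child(nodes[k])
        nodes[k].edge.length = _clamp(lens[k])
        if trace is not None:
            trace.append((reps[k], "*", _clamp(lens[k]), 0.0))

    if n_clamped:
        logger.info("nj: clamped %d negative branch length(s) to 0", n_clamped)
    out = PhyloTree(tree)
    out.info["clamped_branches"] = n_clamped
    return out
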