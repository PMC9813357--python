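"""Bootstrap support by alignment-column resampling and bipartition counting.

The reference tree is the NJ tree on the full alignment. Each replicate
resamples ``width`` columns with replacement (uniform over all columns of
the analysed matrix by default; optionally stratified within loci for a
supermatrix), rebuilds the K2P distance matrix and NJ tree, and records its
non-trivial bipartitions. The support of each reference-tree edge is the
fraction of *completed* replicates containing its bipartition: replicates
whose resampled matrix has an undefined pair are discarded and logged.

Reproducibility: replicate r draws from an independent, named random stream
seeded by (seed, r), so the replicate set does not depend on execution
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from .distances import DEFAULT_MIN_OVERLAP, k2p_matrix, DistanceMatrix
from .errors import BootstrapError
from .njtree import nj
from .seqio import AlignedLocus, Supermatrix
from .tree import PhyloTree

__all__ = ["BootstrapConfig", "bootstrap_support"]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    """Bootstrap settings; 1000 replicates by default."""

    replicates: int = 1000
    seed: int = 0
    min_overlap: int = DEFAULT_MIN_OVERLAP
    #: resample columns within each locus partition instead of across the
    #: whole matrix (only meaningful for a Supermatrix)
    stratify_by_locus: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _resample_columns(
    rng: np.random.Generator,
    width: int,
    partitions,
) -> np.ndarray:
    if partitions is None:
        return rng.integers(0, width, size=width)
    cols = []
    for s, e in partitions:
        cols.append(rng.integers(s, e, size=e - s))
    return np.concatenate(cols)


def bootstrap_support(
    aln: Union[AlignedLocus, Supermatrix],
    cfg: BootstrapConfig,
) -> PhyloTree:
    """NJ tree with bootstrap supports on its internal edges.

    Raises :class:`BootstrapError` when more than half of the replicates are
    discarded because of undefined resampled distances; the remedy is a
    larger ``min_overlap`` tolerance, longer loci, or fewer gappy samples.
    """
    from .distances import distance_matrix  # local to avoid cycle at import

    ids = aln.ids
    enc = aln.encoded()
    width = enc.shape[1]
    ref_tree = nj(distance_matrix(aln, min_overlap=cfg.min_overlap))
    ref_splits = ref_tree.bipartitions(include_trivial=False)
    counts = {s: 0 for s in ref_splits}

    partitions = None
    if cfg.stratify_by_locus and isinstance(aln, Supermatrix):
        partitions = aln.partitions

    completed = 0
    discarded = 0
    for r in range(cfg.replicates):
        rng = np.random.default_rng([cfg.seed, r])
        cols = _resample_columns(rng, width, partitions)
        d, _ = k2p_matrix(enc[:, cols], min_overlap=cfg.min_overlap)
        off_diag = d[np.triu_indices(len(ids), k=1)]
        if np.isnan(off_diag).any():
            discarded += 1
            continue
        rep_tree = nj(DistanceMatrix(list(ids), d))
        completed += 1
        for s in rep_tree.bipartitions(include_trivial=False):
            if s in counts:
                counts[s] += 1

    if discarded:
        logger.warning(
            "bootstrap: discarded %d of %d replicates (undefined distances)",
            discarded,
            cfg.replicates,
        )
    if discarded > cfg.replicates / 2:
        raise BootstrapError(
            f"{discarded}/{cfg.replicates} bootstrap replicates discarded "
            "due to undefined distances; increase overlap tolerance, use "
            "longer loci, or remove gap-heavy samples"
        )

    supports = {s: counts[s] / completed for s in ref_splits}
    out = PhyloTree(ref_tree.dendropy_tree, supports)
    out.info = {
        "replicates": cfg.replicates,
        "completed": completed,
        "discarded": discarded,
        "seed": cfg.seed,
    }
    return out


def support_table(tree: PhyloTree) -> list[tuple[str, float, float]]:
    """Edge table (bipartition as comma-joined ids, support, length) for
    TSV export."""
    rows = []
    split_map = tree.split_edge_map(include_trivial=False)
    for canon, nd in sorted(split_map.items(), key=lambda kv: sorted(kv[0])):
        sup = tree.supports.get(canon)
        rows.append(
            (
                ",".join(sorted(canon)),
                float("nan") if sup is None else sup,
                nd.edge.length if nd.edge.length is not None else float("nan"),
            )
        )
    return rows
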