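"""Kimura 2-parameter (K2P) pairwise distances with pairwise deletion.

The K2P model distinguishes transitions (A<->G, C<->T, proportion P of
compared sites) from transversions (proportion Q) and estimates the number
of substitutions per site as

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q).

Sites where either sequence carries a gap, N or any IUPAC ambiguity code are
excluded pair by pair ("pairwise deletion"). A pair is *undefined* when
fewer than ``min_overlap`` comparable sites remain, or when a log argument
is non-positive (saturation). Undefined entries are tracked explicitly and
never silently propagated as NaN into downstream maths: tree building
refuses a matrix containing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import AlignmentError, UndefinedDistanceError
from .seqio import AlignedLocus, Supermatrix, encode_alignment

__all__ = [
    "DEFAULT_MIN_OVERLAP",
    "k2p_from_counts",
    "k2p_pair",
    "k2p_variance",
    "k2p_matrix",
    "distance_matrix",
    "DistanceMatrix",
]

#: minimum comparable sites for a defined distance; guards against
#: meaningless estimates on mini-barcodes with heavy missing data
DEFAULT_MIN_OVERLAP: int = 20


def k2p_from_counts(p: float, q: float) -> Optional[float]:
    """K2P distance from transition/transversion proportions, or ``None``
    when the estimator is undefined (saturation)."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # -0.0 -> 0.0


def k2p_variance(p: float, q: float, n: int) -> Optional[float]:
    """Large-sample variance of the K2P distance estimate over *n* sites
    (delta method on the multinomial (P, Q) counts)."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0 or n <= 0:
        return None
    c1 = 1.0 / w1
    c2 = 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    return (c1 * c1 * p + c3 * c3 * q - (c1 * p + c3 * q) ** 2) / n


def _as_encoded(seq: Union[str, np.ndarray]) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode_alignment({"_": seq})[0]


def k2p_pair(
    a: Union[str, np.ndarray],
    b: Union[str, np.ndarray],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[Optional[float], int]:
    """K2P distance between two aligned sequences under pairwise deletion.

    Returns ``(d, overlap)``; ``d`` is ``None`` when the pair is undefined
    (overlap below *min_overlap*, or saturated). Raises
    :class:`AlignmentError` on unequal lengths.
    """
    ea, eb = _as_encoded(a), _as_encoded(b)
    if ea.shape != eb.shape:
        raise AlignmentError(
            f"unequal sequence lengths: {ea.size} vs {eb.size}"
        )
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n < max(min_overlap, 1):
        return None, n
    diff = valid & (ea != eb)
    ts = int((diff & ((ea & 1) == (eb & 1))).sum())
    tv = int(diff.sum()) - ts
    d = k2p_from_counts(ts / n, tv / n)
    return d, n


def k2p_matrix(
    enc: np.ndarray, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs K2P distances on an encoded alignment.

    Returns ``(d, overlap)`` square arrays; undefined entries are NaN in
    ``d``. The diagonal is zero by definition.
    """
    n = enc.shape[0]
    d = np.zeros((n, n), dtype=float)
    ov = np.zeros((n, n), dtype=np.int64)
    valid = enc < 4
    parity = enc & 1
    for i in range(n - 1):
        vi = valid[i]
        both = vi & valid[i + 1 :]
        nn = both.sum(axis=1)
        diff = both & (enc[i] != enc[i + 1 :])
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            p = ts / nn
            q = tv / nn
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            di = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                np.nan,
            )
        di = np.where(nn >= max(min_overlap, 1), di, np.nan)
        d[i, i + 1 :] = di
        d[i + 1 :, i] = di
        ov[i, i + 1 :] = nn
        ov[i + 1 :, i] = nn
        ov[i, i] = int(valid[i].sum())
    if n:
        ov[n - 1, n - 1] = int(valid[n - 1].sum())
    return d, ov


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined-entry tracking.

    ``values`` holds NaN at undefined entries; ``undefined_pairs`` lists
    them as sorted id tuples. ``overlap`` (sites compared per pair) is
    ``None`` when the matrix was loaded from a TSV that does not carry it.
    """

    ids: list[str]
    values: np.ndarray
    overlap: Optional[np.ndarray] = None
    undefined_pairs: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index = {sid: k for k, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> Optional[float]:
        v = self.values[self._index[a], self._index[b]]
        return None if np.isnan(v) else float(v)

    @property
    def has_undefined(self) -> bool:
        return bool(self.undefined_pairs)

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        vals = self.values[np.ix_(idx, idx)]
        ov = None if self.overlap is None else self.overlap[np.ix_(idx, idx)]
        keep = set(ids)
        undef = {p for p in self.undefined_pairs if set(p) <= keep}
        return DistanceMatrix(list(ids), vals, ov, undef)

    # -- TSV round trip ------------------------------------------------- #

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Square TSV: ids in first row and column, 6 decimals, undefined
        cells as 'NA'."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    "NA" if np.isnan(v) else f"{v:.6f}"
                    for v in self.values[i]
                ]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "DistanceMatrix":
        with open(path) as fh:
            ids = fh.readline().rstrip("\n").split("\t")[1:]
            vals = np.full((len(ids), len(ids)), np.nan)
            undef = set()
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                for j, cell in enumerate(parts[1:]):
                    if cell == "NA":
                        if i != j:
                            undef.add(tuple(sorted((ids[i], ids[j]))))
                    else:
                        vals[i, j] = float(cell)
        return cls(ids, vals, None, undef)


def distance_matrix(
    aln: Union[AlignedLocus, Supermatrix],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """Pairwise K2P distance matrix for an alignment or supermatrix.

    Undefined pairs are recorded, not fatal; downstream tree building
    rejects matrices containing them (drop a sample or lower min_overlap).
    """
    ids = aln.ids
    if len(ids) < 2:
        raise UndefinedDistanceError("need at least 2 sequences")
    d, ov = k2p_matrix(aln.encoded(), min_overlap=min_overlap)
    undef = {
        tuple(sorted((ids[i], ids[j])))
        for i, j in zip(*np.nonzero(np.isnan(d)))
        if i < j
    }
    return DistanceMatrix(list(ids), d, ov, undef)
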