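"""Aligned-sequence and metadata I/O, plus multi-locus concatenation.

File formats
------------
* one aligned FASTA per barcode locus (all records the same length);
* a sample table as TSV with header ``sample_id  species  role  genus``
  where role is ``reference`` or ``query``;
* Newick for trees (see :mod:`woodbarcode.tree`);
* a concatenated supermatrix exports as FASTA plus a partitions TSV
  (``locus  start  end``, 1-based closed coordinates).

Residues are normalised to upper case with U mapped to T. The alphabet is
A, C, G, T plus the IUPAC ambiguity codes, N, and the gap character '-'.
Ambiguity codes, N and '-' are all treated as *missing* downstream, which is
what pairwise deletion of sites requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, SampleTableError
from .tree import PhyloTree

__all__ = [
    "AlignedLocus",
    "Supermatrix",
    "SampleRecord",
    "SampleTable",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "concatenate",
    "read_newick",
    "write_newick",
    "encode_alignment",
    "MISSING_CODE",
]

# nucleotide encoding: A,C,G,T -> 0..3 (transitions are 0<->2 and 1<->3,
# i.e. partners share parity); everything ambiguous/gapped -> MISSING_CODE
MISSING_CODE: int = 4

_AMBIGUOUS = set("RYSWKMBDHVN-")
_ALLOWED = set("ACGT") | _AMBIGUOUS

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
for _c in _AMBIGUOUS:
    _ENCODE[ord(_c)] = MISSING_CODE


def _normalise(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in _ALLOWED:
            raise AlignmentError(
                f"record '{record_id}': non-IUPAC character {ch!r} "
                f"at position {pos + 1}"
            )
    return s


def encode_alignment(rows: Mapping[str, str]) -> np.ndarray:
    """Encode aligned rows as a (n_samples, width) uint8 matrix in the
    iteration order of *rows* (A,C,G,T -> 0..3; missing -> 4)."""
    mat = np.frombuffer(
        "".join(rows.values()).encode("ascii"), dtype=np.uint8
    ).reshape(len(rows), -1)
    return _ENCODE[mat]


@dataclass
class AlignedLocus:
    """One locus's aligned sequence matrix, keyed by sample id."""

    name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError(f"locus '{self.name}': no sequences")
        widths = {len(s) for s in self.rows.values()}
        if len(widths) != 1:
            bad = next(
                sid
                for sid, s in self.rows.items()
                if len(s) != len(next(iter(self.rows.values())))
            )
            raise AlignmentError(
                f"locus '{self.name}': unequal sequence lengths "
                f"(offending record '{bad}')"
            )
        if widths == {0}:
            raise AlignmentError(f"locus '{self.name}': zero-width alignment")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.rows

    def subset(self, ids: Iterable[str]) -> "AlignedLocus":
        """Restrict to the given sample ids (kept in the given order)."""
        missing = [i for i in ids if i not in self.rows]
        if missing:
            raise AlignmentError(
                f"locus '{self.name}': unknown sample ids {missing}"
            )
        return AlignedLocus(self.name, {i: self.rows[i] for i in ids})

    def encoded(self) -> np.ndarray:
        return encode_alignment(self.rows)


@dataclass
class Supermatrix:
    """Concatenation of loci; samples missing a locus are gap-filled.

    ``partitions`` holds per-locus half-open column intervals [start, end)
    in the concatenation, in locus order.
    """

    loci: list[str]
    partitions: list[tuple[int, int]]
    rows: dict[str, str]

    @property
    def name(self) -> str:
        return "+".join(self.loci)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.rows

    def encoded(self) -> np.ndarray:
        return encode_alignment(self.rows)

    def write_fasta(self, path: Union[str, Path]) -> None:
        write_aligned_fasta(self.rows, path)

    def write_partitions(self, path: Union[str, Path]) -> None:
        """Partitions TSV with 1-based closed coordinates."""
        with open(path, "w") as fh:
            fh.write("locus\tstart\tend\n")
            for name, (s, e) in zip(self.loci, self.partitions):
                fh.write(f"{name}\t{s + 1}\t{e}\n")


# --------------------------------------------------------------------- #
# sample metadata
# --------------------------------------------------------------------- #

ROLES = ("reference", "query")


@dataclass(frozen=True)
class SampleRecord:
    species: str
    role: str
    genus: str


@dataclass
class SampleTable:
    """Map sample id -> (species label, role, genus).

    Reference samples must carry a real species label; queries are usually
    'unknown'.
    """

    entries: dict[str, SampleRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, rec in self.entries.items():
            if rec.role not in ROLES:
                raise SampleTableError(
                    f"sample '{sid}': role must be one of {ROLES}, "
                    f"got {rec.role!r}"
                )
            if rec.role == "reference" and rec.species == "unknown":
                raise SampleTableError(
                    f"reference sample '{sid}' lacks a species label"
                )

    def __contains__(self, sid: str) -> bool:
        return sid in self.entries

    def __getitem__(self, sid: str) -> SampleRecord:
        return self.entries[sid]

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def references(self) -> list[str]:
        return [s for s, r in self.entries.items() if r.role == "reference"]

    def queries(self) -> list[str]:
        return [s for s, r in self.entries.items() if r.role == "query"]

    def refs_by_species(
        self, restrict_to: Optional[Iterable[str]] = None
    ) -> dict[str, frozenset]:
        """Species -> set of reference sample ids (optionally restricted to
        a leaf set)."""
        keep = None if restrict_to is None else set(restrict_to)
        out: dict[str, set] = {}
        for sid, rec in self.entries.items():
            if rec.role != "reference":
                continue
            if keep is not None and sid not in keep:
                continue
            out.setdefault(rec.species, set()).add(sid)
        return {sp: frozenset(v) for sp, v in out.items()}

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "SampleTable":
        entries: dict[str, SampleRecord] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["sample_id", "species", "role", "genus"]
            if header != expected:
                raise SampleTableError(
                    f"sample table header must be {expected}, got {header}"
                )
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise SampleTableError(
                        f"line {lineno}: expected 4 columns, got {len(parts)}"
                    )
                sid, species, role, genus = parts
                if sid in entries:
                    raise SampleTableError(f"duplicate sample id '{sid}'")
                entries[sid] = SampleRecord(species, role, genus)
        return cls(entries)

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tspecies\trole\tgenus\n")
            for sid, rec in self.entries.items():
                fh.write(f"{sid}\t{rec.species}\t{rec.role}\t{rec.genus}\n")


# --------------------------------------------------------------------- #
# FASTA
# --------------------------------------------------------------------- #

def read_aligned_fasta(
    path: Union[str, Path], locus_name: Optional[str] = None
) -> AlignedLocus:
    """Read one locus's aligned FASTA.

    Sequences are upper-cased and U is mapped to T. Raises
    :class:`AlignmentError` on ragged rows, duplicate ids or residues
    outside the IUPAC alphabet.
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise AlignmentError(
                f"locus '{locus_name}': duplicate sample id '{rec.id}'"
            )
        rows[rec.id] = _normalise(str(rec.seq), rec.id)
    if not rows:
        raise AlignmentError(f"{path}: no FASTA records")
    return AlignedLocus(locus_name, rows)


def write_aligned_fasta(
    rows: Mapping[str, str], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for sid, seq in rows.items():
            fh.write(f">{sid}\n{seq}\n")


# --------------------------------------------------------------------- #
# concatenation
# --------------------------------------------------------------------- #

def concatenate(
    loci: Sequence[Union[AlignedLocus, Supermatrix]],
    samples: Optional[Union[SampleTable, Sequence[str]]] = None,
    missing_char: str = "-",
) -> Supermatrix:
    """Concatenate loci into a supermatrix.

    The sample universe is the sample table (or explicit id list) when
    given, otherwise the union of all locus rows. A sample missing from a
    locus has that partition filled with *missing_char*; a sample present in
    no locus at all is an error. Supermatrix inputs contribute their own
    partitions, so concatenation is associative.
    """
    if not loci:
        raise AlignmentError("no loci to concatenate")

    # flatten to (locus_name, width, rows) blocks
    blocks: list[tuple[str, int, Mapping[str, str]]] = []
    for item in loci:
        if isinstance(item, Supermatrix):
            for name, (s, e) in zip(item.loci, item.partitions):
                blocks.append(
                    (name, e - s, {sid: row[s:e] for sid, row in item.rows.items()})
                )
        else:
            blocks.append((item.name, item.width, item.rows))

    names = [b[0] for b in blocks]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise AlignmentError(f"duplicate locus names: {sorted(dupes)}")

    if samples is None:
        ids: list[str] = []
        seen = set()
        for _, _, rows in blocks:
            for sid in rows:
                if sid not in seen:
                    seen.add(sid)
                    ids.append(sid)
    elif isinstance(samples, SampleTable):
        ids = samples.ids
    else:
        ids = list(samples)

    orphans = [
        sid for sid in ids if not any(sid in rows for _, _, rows in blocks)
    ]
    if orphans:
        raise AlignmentError(
            f"samples present in no locus: {orphans}"
        )

    partitions: list[tuple[int, int]] = []
    offset = 0
    for _, w, _ in blocks:
        partitions.append((offset, offset + w))
        offset += w

    out_rows: dict[str, str] = {}
    for sid in ids:
        parts = []
        for _, w, rows in blocks:
            parts.append(rows.get(sid, missing_char * w))
        out_rows[sid] = "".join(parts)

    return Supermatrix([b[0] for b in blocks], partitions, out_rows)


# --------------------------------------------------------------------- #
# Newick pass-through
# --------------------------------------------------------------------- #

def read_newick(path: Union[str, Path]) -> PhyloTree:
    return PhyloTree.read(path)


def write_newick(tree: PhyloTree, path: Union[str, Path]) -> None:
    tree.write(path)
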