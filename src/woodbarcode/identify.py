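"""Monophyly testing, query assignment and locus-combination evaluation.

This is the scoring layer of the pipeline: given a reference barcode
library and query samples placed on an NJ tree, it decides for each query
whether the tree supports a species-level call, counts how many reference
species form monophyletic clades, and sweeps all locus combinations to rank
them by discrimination success rate (fraction of queries identified to
species level) and monophyletic-clade count.

Assignment rule
---------------
A query is identified to *species* S when some tree edge separates a leaf
set consisting of the query, the complete reference set of S, and possibly
other query leaves (queries are unknowns under test; by default a query
nested inside an otherwise-exclusive species clade neither blocks that
species' monophyly count nor its own assignment). When no species
qualifies, the query is identified to *genus* level if the smallest
separable leaf set around it contains references of exactly one genus;
otherwise it is unidentified.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .bootstrap import BootstrapConfig, bootstrap_support
from .distances import DEFAULT_MIN_OVERLAP, distance_matrix
from .errors import IdentificationError, WoodBarcodeError
from .njtree import nj
from .seqio import AlignedLocus, SampleTable, Supermatrix, concatenate
from .tree import PhyloTree

__all__ = [
    "AssignmentResult",
    "CombinationResult",
    "EvaluationReport",
    "is_monophyletic",
    "count_monophyletic_species",
    "assign_query",
    "evaluate_combinations",
    "identify_product",
]

logger = logging.getLogger(__name__)

SPECIES = "species"
GENUS = "genus"
UNIDENTIFIED = "unidentified"


# --------------------------------------------------------------------- #
# monophyly
# --------------------------------------------------------------------- #

def is_monophyletic(tree: PhyloTree, ids: Iterable[str]) -> bool:
    """True iff *ids* is exactly one side of some edge's bipartition (or a
    single leaf, or the whole leaf set)."""
    ids = frozenset(ids)
    if not ids:
        raise WoodBarcodeError("empty id set")
    leaves = frozenset(tree.leaf_ids)
    unknown = ids - leaves
    if unknown:
        raise WoodBarcodeError(f"ids not in tree: {sorted(unknown)}")
    if len(ids) == 1 or ids == leaves:
        return True
    return tree.canonical(ids) in tree.bipartitions(include_trivial=True)


def count_monophyletic_species(
    tree: PhyloTree,
    samples: SampleTable,
    strict: bool = False,
) -> int:
    """Number of reference species whose leaves form a monophyletic clade.

    Query leaves in the tree do not break a species' monophyly by default
    (they are unknowns under test, not library members): species S counts
    when some edge side contains all of S's references, no reference of any
    other species, and nothing else but queries. With ``strict=True`` the
    side must equal S's reference set exactly. Species represented by a
    single reference always count.
    """
    leaves = set(tree.leaf_ids)
    refs_by_sp = samples.refs_by_species(restrict_to=leaves)
    all_refs = frozenset().union(*refs_by_sp.values()) if refs_by_sp else frozenset()
    sides = [side for side, _ in tree.edge_sides()]
    full = frozenset(leaves)
    sides = sides + [full - s for s in sides]

    count = 0
    for sp, refs in refs_by_sp.items():
        if len(refs) == 1:
            count += 1
            continue
        for side in sides:
            if strict:
                ok = side == refs
            else:
                ok = refs <= side and side & all_refs == refs
            if ok:
                count += 1
                break
    return count


# --------------------------------------------------------------------- #
# query assignment
# --------------------------------------------------------------------- #

@dataclass
class AssignmentResult:
    """Outcome of placing one query on a reference tree."""

    query_id: str
    combination: tuple[str, ...]
    assigned_species: Optional[str]
    level: str  # species | genus | unidentified
    assigned_genus: Optional[str] = None
    support_of_clade: Optional[float] = None

    def __post_init__(self) -> None:
        assert (self.level == SPECIES) == (self.assigned_species is not None)


def assign_query(
    tree: PhyloTree,
    samples: SampleTable,
    query_id: str,
    sister_ok: bool = True,
    min_support: Optional[float] = None,
    combination: tuple[str, ...] = (),
) -> AssignmentResult:
    """Assign one query leaf to species or genus level by monophyly.

    ``sister_ok`` (default) accepts a query immediately sister to an
    exclusive species clade as a species-level call; with ``sister_ok=False``
    the query must break *inside* the clade. ``min_support`` optionally
    requires the separating edge's bootstrap support to reach a threshold
    before a species-level call is made.
    """
    leaves = frozenset(tree.leaf_ids)
    if query_id not in leaves:
        raise IdentificationError(f"query '{query_id}' absent from tree")
    if query_id not in samples or samples[query_id].role != "query":
        raise IdentificationError(f"'{query_id}' is not a query sample")

    refs_by_sp = samples.refs_by_species(restrict_to=leaves)
    all_refs = frozenset().union(*refs_by_sp.values()) if refs_by_sp else frozenset()
    query_ids = {
        sid for sid in leaves if sid in samples and samples[sid].role == "query"
    }
    sp_of_complete = {refs: sp for sp, refs in refs_by_sp.items()}

    raw_sides = [side for side, _ in tree.edge_sides()]
    all_sides = set(raw_sides) | {leaves - s for s in raw_sides}
    sides_with_query = sorted(
        (s for s in all_sides if query_id in s and len(s) >= 2),
        key=lambda s: (len(s), tuple(sorted(s))),
    )

    def support_of(side: frozenset) -> Optional[float]:
        return tree.supports.get(tree.canonical(side))

    # species level: smallest side whose references are exactly one
    # complete species set and whose other members are all queries
    for side in sides_with_query:
        refs_in = side & all_refs
        if refs_in not in sp_of_complete:
            continue
        if not (side - refs_in) <= query_ids:
            continue
        if not sister_ok:
            # "inside" means the bare clade (side minus this query) is not
            # itself separable: the query's attachment broke the pure clade
            if side - {query_id} in all_sides:
                continue
        sup = support_of(side)
        if min_support is not None and sup is not None and sup < min_support:
            continue
        sp = sp_of_complete[refs_in]
        return AssignmentResult(
            query_id=query_id,
            combination=tuple(combination),
            assigned_species=sp,
            level=SPECIES,
            assigned_genus=sp.split()[0],
            support_of_clade=sup,
        )

    # genus level: smallest side around the query whose references are all
    # of one genus (incomplete or mixed species)
    for side in sides_with_query:
        refs_in = side & all_refs
        if not refs_in:
            continue
        if not (side - refs_in) <= query_ids:
            continue
        genera = {samples[r].genus for r in refs_in}
        if len(genera) == 1:
            return AssignmentResult(
                query_id=query_id,
                combination=tuple(combination),
                assigned_species=None,
                level=GENUS,
                assigned_genus=genera.pop(),
                support_of_clade=support_of(side),
            )

    return AssignmentResult(
        query_id=query_id,
        combination=tuple(combination),
        assigned_species=None,
        level=UNIDENTIFIED,
    )


# --------------------------------------------------------------------- #
# combination sweep
# --------------------------------------------------------------------- #

def _format_rate(successes: int, total: int) -> str:
    pct = 0.0 if total == 0 else 100.0 * successes / total
    return f"{round(pct, 2):g}% ({successes}/{total})"


@dataclass
class CombinationResult:
    """Scores for one locus combination (one row of the evaluation table)."""

    combination: tuple[str, ...]
    evaluable: bool
    successes: int
    total: int
    monophyletic_clades: int
    assignments: list[AssignmentResult] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)
    tree: Optional[PhyloTree] = None
    note: str = ""

    @property
    def discrimination_rate(self) -> float:
        return 0.0 if self.total == 0 else self.successes / self.total

    @property
    def rate_text(self) -> str:
        return _format_rate(self.successes, self.total)

    @property
    def label(self) -> str:
        return " + ".join(self.combination)


@dataclass
class EvaluationReport:
    """All combination rows, sorted by size then locus names."""

    rows: list[CombinationResult]

    def row(self, combination: Sequence[str]) -> CombinationResult:
        key = tuple(combination)
        for r in self.rows:
            if r.combination == key:
                return r
        raise KeyError(key)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "combination\trate_percent\tsuccesses\ttotal\t"
                "monophyletic_clades\tevaluable\tnote\n"
            )
            for r in self.rows:
                pct = 0.0 if r.total == 0 else 100.0 * r.successes / r.total
                fh.write(
                    f"{r.label}\t{round(pct, 2):g}\t{r.successes}\t{r.total}\t"
                    f"{r.monophyletic_clades}\t{int(r.evaluable)}\t{r.note}\n"
                )

    def assignments_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "query_id\tcombination\tlevel\tassigned_species\t"
                "assigned_genus\tsupport_of_clade\n"
            )
            for r in self.rows:
                for a in r.assignments:
                    sup = (
                        ""
                        if a.support_of_clade is None
                        else f"{a.support_of_clade:.3f}"
                    )
                    fh.write(
                        f"{a.query_id}\t{' + '.join(a.combination)}\t{a.level}\t"
                        f"{a.assigned_species or ''}\t{a.assigned_genus or ''}\t"
                        f"{sup}\n"
                    )


def _build_tree(
    sub_loci: Sequence[AlignedLocus],
    ids: Sequence[str],
    cfg: Optional[BootstrapConfig],
    min_overlap: int,
):
    """Concatenate -> distances -> NJ (-> bootstrap); returns (tree, dm)."""
    sup = concatenate(sub_loci, ids)
    dm = distance_matrix(sup, min_overlap=min_overlap)
    if dm.has_undefined:
        return None, dm
    if cfg is not None and cfg.replicates > 0:
        return bootstrap_support(sup, cfg), dm
    return nj(dm), dm


def evaluate_combinations(
    loci: Sequence[AlignedLocus],
    samples: SampleTable,
    cfg: Optional[BootstrapConfig] = None,
    max_combo_size: Optional[int] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_support: Optional[float] = None,
    sister_ok: bool = True,
    keep_trees: bool = False,
) -> EvaluationReport:
    """Score every non-empty locus subset of size <= ``max_combo_size``.

    For each combination: concatenate -> K2P distances -> NJ tree (->
    bootstrap when *cfg* is given) -> per-query assignment. The
    discrimination success rate is the fraction of included queries called
    to species level; queries lacking every locus of a combination are
    excluded from that combination's denominator and logged. A combination
    whose matrix has undefined pairs is reported as not evaluable instead of
    aborting the sweep.
    """
    if not loci:
        raise WoodBarcodeError("no loci given")
    names = [loc.name for loc in loci]
    if len(set(names)) != len(names):
        raise WoodBarcodeError(f"duplicate locus names: {names}")
    ref_species = {
        rec.species for rec in samples.entries.values() if rec.role == "reference"
    }
    if len(ref_species) < 2:
        raise WoodBarcodeError("need at least 2 reference species")

    size_cap = len(loci) if max_combo_size is None else max_combo_size
    queries = samples.queries()
    refs = samples.references()

    rows: list[CombinationResult] = []
    for size in range(1, size_cap + 1):
        for combo in itertools.combinations(loci, size):
            combo_names = tuple(loc.name for loc in combo)
            included_q = [q for q in queries if any(q in loc for loc in combo)]
            excluded = [
                (q, "query has no locus in this combination")
                for q in queries
                if q not in included_q
            ]
            for q, reason in excluded:
                logger.info(
                    "combination %s: excluded %s (%s)",
                    "+".join(combo_names),
                    q,
                    reason,
                )
            ids = [
                s
                for s in refs + included_q
                if any(s in loc for loc in combo)
            ]
            sub_loci = [
                AlignedLocus(
                    loc.name,
                    {s: loc.rows[s] for s in ids if s in loc},
                )
                for loc in combo
            ]
            tree, dm = _build_tree(sub_loci, ids, cfg, min_overlap)
            if tree is None:
                rows.append(
                    CombinationResult(
                        combination=combo_names,
                        evaluable=False,
                        successes=0,
                        total=len(included_q),
                        monophyletic_clades=0,
                        excluded=excluded,
                        note=(
                            f"not evaluable: {len(dm.undefined_pairs)} "
                            "undefined distance pair(s)"
                        ),
                    )
                )
                continue
            assignments = [
                assign_query(
                    tree,
                    samples,
                    q,
                    sister_ok=sister_ok,
                    min_support=min_support,
                    combination=combo_names,
                )
                for q in included_q
            ]
            successes = sum(1 for a in assignments if a.level == SPECIES)
            rows.append(
                CombinationResult(
                    combination=combo_names,
                    evaluable=True,
                    successes=successes,
                    total=len(included_q),
                    monophyletic_clades=count_monophyletic_species(tree, samples),
                    assignments=assignments,
                    excluded=excluded,
                    tree=tree if keep_trees else None,
                )
            )

    rows.sort(key=lambda r: (len(r.combination), r.combination))
    return EvaluationReport(rows)


# --------------------------------------------------------------------- #
# per-product identification
# --------------------------------------------------------------------- #

def identify_product(
    query_id: str,
    loci: Sequence[AlignedLocus],
    samples: SampleTable,
    cfg: Optional[BootstrapConfig] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_support: Optional[float] = None,
    sister_ok: bool = True,
) -> AssignmentResult:
    """Identify one product using *all* loci available for it.

    Mirrors real practice where the usable combination differs per product
    (driven by which mini-barcodes amplified): the tree is built from the
    references plus this single query on the loci the query actually has.
    Single-locus identifications are logged as lower-confidence.
    """
    available = [loc for loc in loci if query_id in loc]
    if not available:
        raise IdentificationError(
            f"query '{query_id}' shares no locus with the reference library"
        )
    if len(available) == 1:
        logger.warning(
            "query '%s': single-locus identification (%s), lower confidence",
            query_id,
            available[0].name,
        )
    refs = samples.references()
    ids = [s for s in refs if any(s in loc for loc in available)] + [query_id]
    sub_loci = [
        AlignedLocus(loc.name, {s: loc.rows[s] for s in ids if s in loc})
        for loc in available
    ]
    combo_names = tuple(loc.name for loc in available)
    tree, dm = _build_tree(sub_loci, ids, cfg, min_overlap)
    if tree is None:
        raise IdentificationError(
            f"query '{query_id}': distance matrix has "
            f"{len(dm.undefined_pairs)} undefined pair(s)"
        )
    return assign_query(
        tree,
        samples,
        query_id,
        sister_ok=sister_ok,
        min_support=min_support,
        combination=combo_names,
    )
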