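"""Synthetic mini-barcode reference libraries and query sets.

The generator emulates the data regime of a timber-forensics barcoding
study: a handful of congeneric species, each represented by a few vouchered
reference sequences, short loci (~170-340 bp), low within-species and
higher between-species divergence, and per-query locus dropout standing in
for failed PCR on degraded wood.

Model
-----
* A Yule (pure-birth) species tree is simulated and rescaled so the mean
  root-to-tip path equals half the target interspecific depth (so the
  expected between-species path is about the configured depth).
* Sequences evolve along the tree under a continuous-time Kimura
  2-parameter process: transition rate kappa*beta, each transversion rate
  beta, with beta = 1/(kappa + 2) so a branch length is the expected number
  of substitutions per site. This matches the distance estimator used
  downstream, so estimates are asymptotically unbiased.
* Within-species replicates (references and queries) hang star-like off
  their species tip at the intraspecific depth. No indels are simulated;
  locus dropout models missing data instead.

All randomness flows through named ``numpy`` generator streams derived from
the configuration seed, so identical configurations give byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import dendropy
import numpy as np
import yaml

from .seqio import AlignedLocus, SampleRecord, SampleTable, write_aligned_fasta
from .tree import PhyloTree

__all__ = [
    "SimulationConfig",
    "simulate_species_tree",
    "k2p_site_probs",
    "evolve_branch",
    "evolve_locus",
    "Benchmark",
    "make_benchmark",
    "study_configs",
]

# mini-barcode locus menu: amplicon sizes in the ~170-340 bp regime typical
# of degraded-wood barcoding
DEFAULT_LOCI: tuple[tuple[str, int], ...] = (
    ("ITS2", 181),
    ("matK", 209),
    ("trnL-trnF", 280),
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic genus library.

    Depths are expected substitutions per site; ``kappa`` is the
    transition/transversion *rate* ratio; ``dropout_prob`` applies per query
    and per locus (references never drop out); ``force_locus`` names a locus
    every query is guaranteed to keep.
    """

    seed: int = 0
    genus: str = "Aquilaria"
    n_species: int = 5
    refs_per_species: int = 3
    n_queries: int = 10
    loci: tuple[tuple[str, int], ...] = DEFAULT_LOCI
    kappa: float = 2.0
    interspecific_depth: float = 0.10
    intraspecific_depth: float = 0.005
    dropout_prob: float = 0.0
    force_locus: Optional[str] = None
    #: guaranteed minimum between-species path length (the "barcoding gap");
    #: None resolves to min(10 * intraspecific_depth, interspecific_depth/2)
    min_species_divergence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.intraspecific_depth > self.interspecific_depth:
            raise ValueError(
                "intraspecific depth must not exceed interspecific depth"
            )
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.min_species_divergence is not None and not (
            0.0 <= self.min_species_divergence <= self.interspecific_depth
        ):
            raise ValueError(
                "min_species_divergence must lie in [0, interspecific_depth]"
            )
        self.loci = tuple((str(n), int(w)) for n, w in self.loci)

    @property
    def species_divergence_floor(self) -> float:
        """Effective guaranteed minimum between-species divergence."""
        if self.min_species_divergence is not None:
            return self.min_species_divergence
        return min(
            10.0 * self.intraspecific_depth, self.interspecific_depth / 2.0
        )

    # -- config file round trip ----------------------------------------- #

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            "seed": self.seed,
            "genus": self.genus,
            "n_species": self.n_species,
            "refs_per_species": self.refs_per_species,
            "n_queries": self.n_queries,
            "loci": [[n, w] for n, w in self.loci],
            "kappa": self.kappa,
            "interspecific_depth": self.interspecific_depth,
            "intraspecific_depth": self.intraspecific_depth,
            "dropout_prob": self.dropout_prob,
            "force_locus": self.force_locus,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "loci" in data:
            data["loci"] = tuple((n, int(w)) for n, w in data["loci"])
        return cls(**data)

    def species_names(self) -> list[str]:
        return [f"{self.genus} sp{i + 1}" for i in range(self.n_species)]


# --------------------------------------------------------------------- #
# species tree
# --------------------------------------------------------------------- #

def simulate_species_tree(cfg: SimulationConfig) -> PhyloTree:
    """Ultrametric Yule species tree with a guaranteed barcoding gap.

    The tree is rescaled so every root-to-tip path equals
    ``interspecific_depth / 2`` (between-species paths are then at most the
    interspecific depth). Split times more recent than allowed by
    ``species_divergence_floor`` are clamped to the youngest permitted age,
    so *every* pair of species is separated by at least the floor -- without
    this, a raw Yule draw can place a split below the intraspecific depth,
    producing species that are unidentifiable by construction. Deterministic
    under the seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    names = cfg.species_names()
    n = cfg.n_species

    tns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    # forward simulation: start with 2 lineages at t=0, split a uniformly
    # chosen tip after Exp(k) waiting time; ultrametric by construction
    t = 0.0
    split_time: dict = {root: 0.0}
    tips: list[dendropy.Node] = [root.new_child(), root.new_child()]
    while len(tips) < n:
        t += rng.exponential(1.0 / len(tips))
        k = int(rng.integers(0, len(tips)))
        node = tips.pop(k)
        split_time[node] = t
        tips.extend([node.new_child(), node.new_child()])
    total = t + rng.exponential(1.0 / n)

    # clamp split ages so the most recent species split still leaves a
    # between-species path of at least the divergence floor after scaling
    floor = cfg.species_divergence_floor
    t_max = total * (1.0 - floor / cfg.interspecific_depth)
    for nd in split_time:
        split_time[nd] = min(split_time[nd], t_max)

    scale = (cfg.interspecific_depth / 2.0) / total
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        child_t = split_time.get(nd, total)
        nd.edge.length = (child_t - split_time[nd.parent_node]) * scale

    # taxa assigned to leaves in deterministic traversal order
    for name, leaf in zip(names, tree.leaf_node_iter()):
        leaf.taxon = tns.get_taxon(name)
    return PhyloTree(tree)


# --------------------------------------------------------------------- #
# sequence evolution under K2P
# --------------------------------------------------------------------- #

def k2p_site_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """Per-site substitution probabilities after a branch of length *t*
    (expected substitutions/site): returns (P_transition,
    P_each_transversion, P_unchanged)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = math.exp(-4.0 * beta * t)
    e_ts = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    return p_ts, p_tv, 1.0 - p_ts - 2.0 * p_tv


def evolve_branch(
    parent: np.ndarray,
    t: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve an encoded sequence (codes 0..3) along one branch.

    Transition partner of code c is c XOR 2 (A<->G, C<->T); transversion
    partners are c XOR 1 and c XOR 3.
    """
    if t == 0.0:
        return parent.copy()
    p_ts, p_tv, _ = k2p_site_probs(t, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    child[u < p_ts] ^= 2
    child[(u >= p_ts) & (u < p_ts + p_tv)] ^= 1
    child[(u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)] ^= 3
    return child


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(seq: np.ndarray) -> str:
    return _DECODE[seq].tobytes().decode("ascii")


def evolve_locus(
    tree: PhyloTree,
    locus_name: str,
    length: int,
    kappa: float,
    rng: np.random.Generator,
    tip_samples: Optional[dict[str, list[str]]] = None,
    intraspecific_depth: float = 0.0,
) -> AlignedLocus:
    """Simulate one gap-free aligned locus on a species tree.

    The root sequence is i.i.d. uniform over {A, C, G, T}; each branch
    applies the K2P site process. When ``tip_samples`` maps species names to
    sample ids, each sample is an extra star tip of length
    ``intraspecific_depth`` hanging off its species tip; otherwise one row
    per species is returned.
    """
    dt = tree.dendropy_tree
    seqs: dict = {}
    root = dt.seed_node
    seqs[root] = rng.integers(0, 4, size=length).astype(np.uint8)
    for nd in dt.preorder_node_iter():
        if nd is root:
            continue
        seqs[nd] = evolve_branch(
            seqs[nd.parent_node], nd.edge.length or 0.0, kappa, rng
        )

    rows: dict[str, str] = {}
    for leaf in dt.leaf_node_iter():
        sp = leaf.taxon.label
        if tip_samples is None:
            rows[sp] = _decode(seqs[leaf])
        else:
            for sid in tip_samples.get(sp, ()):
                rows[sid] = _decode(
                    evolve_branch(seqs[leaf], intraspecific_depth, kappa, rng)
                )
    return AlignedLocus(locus_name, rows)


# --------------------------------------------------------------------- #
# benchmark assembly
# --------------------------------------------------------------------- #

@dataclass
class Benchmark:
    """A complete synthetic study: per-locus alignments, sample metadata,
    the truth table for queries, and the generating species tree."""

    loci: list[AlignedLocus]
    samples: SampleTable
    truth: dict[str, str]
    species_tree: PhyloTree
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for loc in self.loci:
            write_aligned_fasta(loc.rows, outdir / f"{loc.name}.fasta")
        self.samples.to_tsv(outdir / "samples.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("query_id\ttrue_species\n")
            for qid, sp in self.truth.items():
                fh.write(f"{qid}\t{sp}\n")
        self.species_tree.write(outdir / "species_tree.nwk")
        if self.config is not None:
            self.config.to_yaml(outdir / "config.yaml")


def make_benchmark(
    cfg: SimulationConfig, outdir: Optional[Union[str, Path]] = None
) -> Benchmark:
    """Generate a full benchmark: reference library + queries with dropout.

    Queries are assigned to species round-robin so every species is probed.
    Fully reproducible under the configuration seed; optionally writes all
    artifacts (FASTA per locus, sample TSV, truth TSV, species tree) to
    *outdir*.
    """
    sp_tree = simulate_species_tree(cfg)
    names = cfg.species_names()
    prefix = cfg.genus[:3].upper()

    ref_ids = {
        sp: [
            f"{prefix}_sp{i + 1}_r{j + 1}"
            for j in range(cfg.refs_per_species)
        ]
        for i, sp in enumerate(names)
    }
    query_ids = [f"{prefix}_Q{k + 1:02d}" for k in range(cfg.n_queries)]
    truth = {
        qid: names[k % cfg.n_species] for k, qid in enumerate(query_ids)
    }
    tip_samples = {
        sp: ref_ids[sp] + [q for q, t in truth.items() if t == sp]
        for sp in names
    }

    loci: list[AlignedLocus] = []
    for idx, (name, width) in enumerate(cfg.loci):
        rng = np.random.default_rng([cfg.seed, 1, idx])
        loci.append(
            evolve_locus(
                sp_tree,
                name,
                width,
                cfg.kappa,
                rng,
                tip_samples=tip_samples,
                intraspecific_depth=cfg.intraspecific_depth,
            )
        )

    # per-query, per-locus dropout (references never drop out)
    rng_drop = np.random.default_rng([cfg.seed, 2])
    for qid in query_ids:
        for loc in loci:
            drop = rng_drop.random() < cfg.dropout_prob
            if drop and loc.name != cfg.force_locus:
                del loc.rows[qid]

    entries: dict[str, SampleRecord] = {}
    for i, sp in enumerate(names):
        for sid in ref_ids[sp]:
            entries[sid] = SampleRecord(sp, "reference", cfg.genus)
    for qid in query_ids:
        entries[qid] = SampleRecord("unknown", "query", cfg.genus)

    bench = Benchmark(loci, SampleTable(entries), truth, sp_tree, cfg)
    if outdir is not None:
        bench.write(outdir)
    return bench


# --------------------------------------------------------------------- #
# the three-genus study setting
# --------------------------------------------------------------------- #

def study_configs(seed: int = 0) -> dict[str, SimulationConfig]:
    """Three genus libraries shaped like a rosewood/agarwood study:
    genus-specific locus menus at mini-barcode lengths, a few species per
    genus, and query counts matching small authentic-sample panels. Queries
    suffer locus dropout except for ITS2, the locus that amplifies most
    reliably from degraded wood."""
    def sub(i: int) -> int:
        return (seed * 1_000_003 + i) % (2**31)

    return {
        "Aquilaria": SimulationConfig(
            seed=sub(1),
            genus="Aquilaria",
            n_species=5,
            n_queries=5,
            loci=(("ITS2", 181), ("matK", 209), ("trnL-trnF", 280)),
            dropout_prob=0.3,
            force_locus="ITS2",
        ),
        "Dalbergia": SimulationConfig(
            seed=sub(2),
            genus="Dalbergia",
            n_species=7,
            n_queries=4,
            loci=(
                ("ITS2", 180),
                ("matK", 300),
                ("trnH-psbA", 334),
                ("trnL", 314),
            ),
            dropout_prob=0.3,
            force_locus="ITS2",
        ),
        "Pterocarpus": SimulationConfig(
            seed=sub(3),
            genus="Pterocarpus",
            n_species=3,
            n_queries=3,
            loci=(
                ("ITS2", 180),
                ("matK", 200),
                ("rbcL", 250),
                ("ndhF-rpl32", 170),
            ),
            dropout_prob=0.3,
            force_locus="ITS2",
        ),
    }
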