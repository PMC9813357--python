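"""Generate a synthetic mini-barcode reference library and query panel.

Builds a 5-species agarwood-style library (3 references per species, 10
queries, three short loci) and writes the aligned FASTAs, sample table and
truth table. The printed counts show the library structure the identification
stages consume.
"""

from pathlib import Path

import woodbarcode as wb

outdir = Path("scratch/benchmark")
cfg = wb.SimulationConfig(seed=42)  # defaults: 5 sp x 3 refs, 10 queries
bench = wb.make_benchmark(cfg, outdir=outdir)

print(f"species tree: {bench.species_tree.newick().strip()}")
for loc in bench.loci:
    print(f"locus {loc.name:10s} width {loc.width:4d} bp, "
          f"{len(loc.ids)} sequences")
print(f"references: {len(bench.samples.references())}, "
      f"queries: {len(bench.samples.queries())}")
print(f"files written to {outdir}/")
# Each query's true species is recorded in truth.tsv; downstream stages
# never see it -- it exists only to score identifications.
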