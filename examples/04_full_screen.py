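"""A complete in-silico DIP-seq screen, end to end.

Simulates a biased naive library with a handful of allosteric hotspot sites,
three rounds of FACS (positive with ligand, negative without, positive with
ligand), junction sequencing of the naive and final pools, then runs the full
analysis pipeline and checks how well enrichment recovered the seeded truth.

Note: this is a reduced-depth version of the package's benchmark settings so
it finishes in well under a minute; see dipseq.workflows.run_selection_benchmark
for the defaults used in validation.
"""

import tempfile

from dipseq.workflows import run_selection_benchmark

bench = run_selection_benchmark(
    seed=0,
    workdir=tempfile.mkdtemp(),
    n_variants=1500,
    depth=200_000,
    n_hotspots=8,
)

print(f"productive codon sites in the library: {bench.n_productive_sites}")
print(f"seeded hotspot sites detected:         {bench.n_hotspots}")
print(f"\nspearman(true dF/F, log2 fold change) = {bench.rank_correlation:.3f}")
print(f"hotspots landing in the top enrichment bin: {bench.top_bin_occupancy:.0%}")

top = bench.enrichment.sort_values("log2fc", ascending=False).head(10)
print("\ntop 10 sites by log2 fold change (dff = seeded ground truth):")
print(
    top[["pos", "base_mean", "log2fc", "padj", "cap", "dff"]]
    .round(3)
    .to_string(index=False)
)
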