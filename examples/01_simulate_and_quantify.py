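"""Simulate a pooled xenograft experiment and quantify barcodes from reads.

Generates a small barcoded pool, materializes FASTQ reads for one organ
sample, assigns reads back to barcodes under the >50%-coverage rule, and
verifies the counts round-trip.
"""

import tempfile

import numpy as np

from metpool import MatchParams, SimConfig, count_barcodes, emit_fastq, simulate_experiment

config = SimConfig(
    n_lines=8, n_mice=2, organs=("brain", "lung"), read_depth=5000,
    n_pre_replicates=2, seed=42,
)
table, cells, truth = simulate_experiment(config)
print(f"simulated {len(table.library)} barcoded lines, {len(table.samples)} samples")

with tempfile.TemporaryDirectory() as tmp:
    paths = emit_fastq(table, tmp, read_length=75, seed=43)
    sample = table.samples[2]  # first organ sample (after 2 pre-injection)
    counted = count_barcodes(
        paths[sample.sample_id], table.library, MatchParams(), sample
    )

print(f"\nsample {sample.sample_id}: {int(counted.counts.sum())} fragments assigned, "
      f"{int(counted.unassigned[0])} unassigned, {int(counted.ambiguous[0])} ambiguous")
print("per-line counts (emitted vs re-counted):")
j = table.samples.index(sample)
for i, bc in enumerate(table.library):
    print(f"  {bc.cell_line:10s} {table.counts[i, j]:6d} {counted.counts[i, 0]:6d}")
match = np.array_equal(counted.counts[:, 0], table.counts[:, j])
print(f"\nround trip exact: {match}")
print("Every emitted fragment carries its line's 26-nt barcode; with no "
      "sequencing errors the matcher recovers the counts bit-exactly.")
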