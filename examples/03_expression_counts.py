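"""Exact-match unique read counting over retrocopies and their parent.

Simulates error-free RNA-seq reads at known per-copy expression from a
synthetic dataset, assigns each read under the 100%-identity unique-mapping
rule and prints the per-reference counts plus the log10(count+1) tissue
matrix.  Reads from regions shared verbatim between two references (e.g. a
newborn copy and the parent mRNA) count as "multi" and are excluded.
"""
import io

import numpy as np

import retrofossil as rf

specs = (
    rf.CopySpec(age_years=0.0, expression=50),    # identical to parent
    rf.CopySpec(age_years=20e6, expression=30),   # diverged -> unique
    rf.CopySpec(age_years=5e6, truncation_5p=400, expression=20),
)
dataset = rf.generate_dataset(rf.GeneratorConfig(seed=11, copies=specs))
references = dataset.references()
expression = {c.copy_id: c.expression for c in dataset.copies}
expression[dataset.parent.id] = 40

rng = np.random.default_rng(5)
records, truth = rf.simulate_reads(references, expression, 100, rng)
fastq = io.StringIO("".join(f"@{r}\n{s}\n+\n{q}\n" for r, s, q in records))

refs = rf.ReferenceSet(references)
meta = [rf.DatasetMeta("ds1", "synthetic", "testis", "germline")]
counts = rf.count_reads({"ds1": fastq}, refs, meta)

print("simulated reads per reference:", truth)
print("\nassigned counts:")
print(counts.T.to_string())
matrix = rf.build_matrix(counts, meta)
print("\nlog10(count + 1) tissue matrix:")
print(matrix.log10.round(3).to_string())

print(
    "\nInterpretation: the newborn copy is indistinguishable from the\n"
    "parent mRNA, so its reads (and the parent's) all land in 'multi';\n"
    "diverged copies keep their full planted read counts."
)
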