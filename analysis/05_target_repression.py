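#!/usr/bin/env python
"""Matched-nontarget repression analysis on the simulated DE table.

Runs the iterated (21x) length-matched nontarget comparison for the miR-1
family on the simulated differential-expression table (planted target shift
-0.3 log2, sigma 0.2), for both the all-targets and top-decile target sets,
and reports mean repression and median Mann-Whitney P.
"""

from pathlib import Path

import pandas as pd

from tdmd_scout.synthetic_data import frame_to_genes
from tdmd_scout.target_repression import report_frame, run_repression, summary_frame

SEED = 2026
results = Path("results")
scratch = Path("scratch/sim")

genes = frame_to_genes(pd.read_csv(scratch / "genes.tsv", sep="\t"))
reports = run_repression(genes, "miR-1", rng_seed=SEED)

report_frame(reports).to_csv(results / "05_repression_iterations.tsv",
                             sep="\t", index=False)
summary = summary_frame(reports)
summary.to_csv(results / "05_repression_summary.tsv", sep="\t", index=False)

print(summary.to_string(index=False))
print("planted shift: -0.3 log2 (scaled per-gene by U(0.5,1.5) weights; "
      "the top decile by context++ score carries the largest effects)")
print(f"tables -> {results}/05_repression_iterations.tsv, "
      "05_repression_summary.tsv")
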