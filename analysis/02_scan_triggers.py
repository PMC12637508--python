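#!/usr/bin/env python
"""De novo trigger scan over the synthetic transcriptome.

Scans every canonical seed match of the 10 synthetic miRNAs across the 200
expressed transcripts, finds each site's best 3'-pairing configuration and
duplex energy, ranks candidates per miRNA, and checks the planted truth:
every planted trigger should rank 1 for its miRNA at exactly its recorded
expected score, with the duplex energy tracking the pairing score.
"""

from pathlib import Path

import pandas as pd

from tdmd_scout.io_formats import candidates_to_frame, write_candidates
from tdmd_scout.synthetic_data import gen_mirna_set, gen_transcriptome
from tdmd_scout.trigger_search import run_denovo_branch

SEED = 2026
CLUSTERS = {"miR-1": ["miR-2"], "miR-3": ["miR-4", "miR-5", "miR-6"]}
results = Path("results")
results.mkdir(exist_ok=True)

mirnas = gen_mirna_set(10, seed=SEED, cluster_spec=CLUSTERS)
regions, truths = gen_transcriptome(
    mirnas, n_transcripts=200, transcript_length=1000, seed=SEED)
candidates = run_denovo_branch(regions, mirnas)
frame = candidates_to_frame(candidates)
frame[frame["rank"] <= 3].to_csv(results / "02_candidates_top3.tsv",
                                 sep="\t", index=False)

top = frame[frame["rank"] == 1].set_index("mirna_id")
hits, margins = 0, []
for t in truths:
    row = top.loc[t.mirna_id]
    ok = (row["transcript_id"] == t.transcript_id
          and row["seed_start"] == t.seed_start
          and row["score"] == t.expected_score)
    hits += ok
    runner_up = frame[(frame["mirna_id"] == t.mirna_id) & (frame["rank"] == 2)]
    if len(runner_up):
        margins.append(row["score"] - float(runner_up.iloc[0]["score"]))

print(f"scanned {len(frame)} candidate sites across {len(regions)} transcripts")
print(f"planted trigger recovered at rank 1 with expected score: "
      f"{hits}/{len(truths)} miRNAs")
print(f"median score margin over the best background site: "
      f"{pd.Series(margins).median():.1f} points")
print(f"top-3 candidate table -> {results / '02_candidates_top3.tsv'}")
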