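#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Emulates the data the trigger-discovery pipeline consumes: a 10-miRNA set
with cluster/partner structure (a 5p/3p pair and a three-member cluster), a
200-transcript (~1 kb) expressed transcriptome carrying one planted TDMD
trigger per miRNA (contiguous 3'-complementarity, the classic trigger
architecture), a multi-species alignment of one trigger locus with a planted
compensatory substitution pair, small-RNA read sets for two wild-type and
two knockout samples with a planted 2.5-fold sensitivity of miR-1, and a
differential-expression table with a planted -0.3 log2 target shift.

Bulky sequence files go to scratch/sim/; small truth summaries to results/.
"""

from pathlib import Path

import pandas as pd

from tdmd_scout.io_formats import write_fasta
from tdmd_scout.synthetic_data import (
    gen_alignment,
    gen_de_table,
    gen_mirna_set,
    gen_reads,
    gen_transcriptome,
    genes_to_frame,
    write_maf,
)

SEED = 2026
CLUSTERS = {"miR-1": ["miR-2"], "miR-3": ["miR-4", "miR-5", "miR-6"]}

scratch = Path("scratch/sim")
results = Path("results")
scratch.mkdir(parents=True, exist_ok=True)
results.mkdir(exist_ok=True)

mirnas = gen_mirna_set(10, seed=SEED, cluster_spec=CLUSTERS)
write_fasta([(m.mirna_id, m.sequence) for m in mirnas], scratch / "mirnas.fa")

regions, truths = gen_transcriptome(
    mirnas, n_transcripts=200, transcript_length=1000, seed=SEED)
write_fasta([(r.transcript_id, r.sequence) for r in regions],
            scratch / "transcriptome.fa")
truth_df = pd.DataFrame(
    [{"mirna_id": t.mirna_id, "transcript_id": t.transcript_id,
      "seed_start": t.seed_start, "site_type": t.site_type,
      "expected_score": t.expected_score} for t in truths])
truth_df.to_csv(results / "01_planted_sites.tsv", sep="\t", index=False)

# alignment of the miR-1 trigger locus: rn6 identical, hg38 carries a
# compensatory pair at miRNA position 17, bosTau9 disrupts the seed core
region = regions[0]
t17 = next(t for t in truths if t.mirna_id == "miR-1")
site_maf = scratch / "site_mir1.maf"
m17_partner = t17.seed_start + 7 - 17  # offset-0 register of position 17
comp = {"hg38": [(m17_partner, "C")], "rn6": [],
        "bosTau9": [(t17.seed_start + 2, "G")]}
write_maf([gen_alignment(region.sequence, comp)], site_maf)
write_maf([gen_alignment(mirnas[0].sequence,
                         {"hg38": [(16, "G")], "rn6": [], "bosTau9": []})],
          scratch / "mirna_mir1.maf")

abund = {m.mirna_id: 1.0 for m in mirnas}
samples = {"wt1": dict(abund), "wt2": dict(abund),
           "ko1": dict(abund), "ko2": dict(abund)}
for s in ("ko1", "ko2"):
    samples[s]["miR-1"] = 2.5  # planted ZSWIM8-loss response
reads = gen_reads(mirnas, samples, n_reads=100_000, seed=SEED)
for sample, rs in reads.items():
    write_fasta([(f"r{i}", r) for i, r in enumerate(rs)],
                scratch / f"reads_{sample}.fa")

genes, truth = gen_de_table(genes_n=2000, delta=-0.3, sigma=0.2,
                            target_fraction=0.125, seed=SEED)
genes_to_frame(genes).to_csv(scratch / "genes.tsv", sep="\t", index=False)

print(f"wrote {len(mirnas)} miRNAs, {len(regions)} transcripts "
      f"({len(truths)} planted triggers), 4 read samples, "
      f"{len(genes)} genes to {scratch}/")
print(f"planted-site truth table -> {results / '01_planted_sites.tsv'}")
print("planted effects: miR-1 cpm ratio 2.5 (KO/WT); "
      f"target shift {truth.planted_repression[1]} log2 on family miR-1")
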