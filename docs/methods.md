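# Methods

## Scope and model

`tdmd-scout` implements the computational side of TDMD trigger discovery:
given mature miRNA sequences and candidate transcript regions (mRNA 3′ UTRs
and lncRNAs), it enumerates canonical seed matches, scores the 3′-pairing
architecture upstream of each site, ranks candidates per miRNA with an
orthogonal duplex-energy column, re-scores sites across species from
multiple alignments, quantifies miRNAs from small-RNA reads, and measures
target de-repression in differential-expression data. Wet-lab stages and
the internals of external tools (read trimming, quantification upstream of
TPM tables, differential-expression estimation) are out of scope; their
outputs are consumed as tables.

## Seed matching

A seed match is an exact target complement of miRNA nucleotides 2–7 (6mer
core). Each core occurrence is classified by its flanks — m8 pairing
(target base WCF-complementary to miRNA nt 8, immediately 5′ of the core on
the target) and a target A across from nt 1 (3′ of the core) — and reported
once with the maximal supported type (8mer > 7mer-m8 ≥ 7mer-A1 > 6mer).
This mirrors TargetScan site accounting and avoids double counting in
ranking. All four canonical types are scanned by default (configurable).
Marginal site classes (offset 6mers, 3′-only sites) and ORF/5′ UTR scanning
are deliberately excluded.

## 3′-pairing score

The score of a pairing configuration (an antiparallel, monotone set of
miRNA-position/target-position pairs, each WCF or G:U) is

    total = match_point · #(WCF pairs at positions > 12)
          + end_bonus · #(WCF pairs at positions L−1, L−2)
          + terminal_wobble_bonus · [G:U at position L]
          − interruption_point · Σ max(miRNA gap, target gap) per break
          − offset_point · max(0, |offset| − offset_free)

with defaults 1.0, 0.5 (per position), 0.5, 1.0, 0.5 and offset_free 3.
Positions 9–12 may pair — maintaining contiguity — but earn nothing.
Interpretive choices, each configurable where the convention is genuinely
open:

- "after nucleotide 12" is read strictly (13..L earn match points);
  `three_prime_start = 9` admits classical 3′-supplementary geometry.
- The end bonus applies independently to each of L−1 and L−2
  (`end_bonus_mode = "per_position"`; `"once"` caps it at a single 0.5).
  Wobbles at those positions earn no bonus, and a WCF pair at L earns a
  match point but no end bonus.
- A 1×1 mismatch is one interrupting column (cost 1, not 2); an n-nt bulge
  costs n. Terminal overhangs on either molecule are free — otherwise the
  maximizer would always trim them and the penalty would be vacuous.
- The offset is signed (target loop − miRNA loop, TargetScan-style) and
  penalized on absolute value; bulged loops on either strand displace the
  helix equivalently.

The search window is the 30 nt immediately 5′ of the target nucleotide
opposite miRNA position 8 (for 6mer/7mer-A1 sites, the hypothetical m8
column); windows at the transcript 5′ end are truncated, not padded.

### Optimal-configuration search

`best_configuration` is a dynamic program over pairable (miRNA position,
window position) cells; a transition between consecutive pairs carries the
interruption cost, and the offset penalty attaches to the chain's first
pair. Under `end_bonus_mode="once"` the DP carries one extra state bit
(bonus claimed). Ties are resolved deterministically — smaller |offset|,
fewer interruption events, then the 5′-most reachable target start — so
output is byte-reproducible; a consequence of the last rule is that
zero-point pairs (positions 9–12, non-terminal wobbles) are appended when
they extend a chain contiguously. Correctness is defined by
`exhaustive_best`, an independent enumerator of all monotone pairings
(guarded to 3′ regions ≤ 10 nt and windows ≤ 14 nt) against which the DP is
tested on 1,000 random instances.

## Duplex energy

The orthogonal ranking metric is the minimum free energy of intermolecular
hybridization between the miRNA 3′ region (positions 9..L) and the same
upstream window the scorer uses. The builtin model is a reduced
nearest-neighbor set: WCF stacking energies at published magnitudes plus
simplified G:U-containing stacks (−1.4 with G:C neighbors, −0.8 with A:U,
−0.5 G:U/G:U), affine bulge (3.8 + 0.5/nt) and interior-loop
(1.7 + 0.5·size + 0.3·asymmetry) costs, duplex initiation +4.09, and a
+0.45 terminal penalty for helix ends closed by AU or GU pairs, all in
kcal/mol and shipped as a packaged TSV. Dangling ends and coaxial stacking
are omitted: the pipeline uses energy for *ranking*, not thermodynamic
fidelity, and the tests only rely on ordering properties (GC > AU
stability, helix-extension monotonicity, anti-correlation with the pairing
score). Energies are reported to 0.01 kcal/mol; "no duplex better than
initiation alone" is an empty TSV cell. A ViennaRNA `RNAduplex` executable,
when present, can be selected as an alternate backend
(`energy_backend: external`) and serves as an independent cross-check of
the builtin ranking in the test suite.

## Trigger search

Two branches share one scoring path. The conserved branch scores externally
provided sites (e.g. TargetScan-style conserved-site tables) without
rescanning; rows with out-of-range coordinates are skipped with a logged
warning. The de novo branch scans all canonical seed matches in expressed
regions. Expression filtering keeps regions whose gene-level mean TPM
across samples is ≥ `min_tpm` (default 1 — the candidate-expression cutoff
is not a published constant, so it is exposed as configuration); genes
absent from the expression table count as unexpressed. Ranking is per
(miRNA, branch) by descending score; duplex energy is an orthogonal column
that optionally breaks exact score ties, followed by transcript id, giving
dense ranks 1..n and deterministic output.

## Conservation

Species-level site sequences and mature miRNAs are projected out of
alignment blocks by slicing the columns covering the reference interval
(including interior insertion columns) and stripping gaps per species.
Mature miRNAs are predicted by this projection of the reference mature
interval — an explicit operationalization of predicting each species'
mature sequence from its genomic locus — with a per-species FASTA override
available; projections whose length deviates from the reference by > 2 nt
are flagged low-confidence. Each species is then re-scored with the
identical pipeline; the species' own seed match nearest the reference
location anchors the window, and `seed_intact` requires a same-or-stronger
site type than the reference (configurable to any canonical type). Species
with fully gapped sites are reported as missing, never silently dropped;
partially deleted sites are scored on the extracted remnant and flagged.
Covariation detection works in alignment-column space: for every
reference-paired miRNA position, species in which *both* the miRNA base and
its partner site base differ from the reference are reported, with
`pairing_preserved` true when the new combination is still WCF or G:U.
MAF rows recorded on the minus strand are reverse-complemented into
reference orientation at read time.

## Small-RNA quantification

Reads are assigned by exact identity of their first 19 nt against the
mature-sequence dictionary; any mismatch within the prefix, or a shorter
read, leaves the read unassigned, and the tail beyond the prefix is
ignored. miRNAs sharing a 19-nt prefix are quantified as one merged
ambiguous group (no fractional splitting — the rule is deterministic and
silent on collisions). Spike-in-matching reads are tallied separately and
excluded, with unassigned reads, from the cpm denominator (counts per
million miRNA-assigned reads). Cluster normalization divides a miRNA's cpm
by the geometric mean of its co-transcribed partners' cpms (a single
partner reduces to a simple ratio, the passenger-strand case) and expresses
each sample as fold change over the mean normalized value of the control
group; samples with any zero partner cpm get an undefined ratio and are
excluded from control means. Sensitivity calling on differential-expression
tables keeps miRNAs with padj ≤ 0.05 and log2FC ≥ 0 by default — documented
configuration, not a claim of equivalence to any particular upstream
statistical filter.

## Target repression

Genes below a mean of 10 TPM across samples are excluded. Two target sets
are analyzed per miRNA family: all predicted targets and the top 10%
(ceiling) by lowest cumulative weighted context++ score, boundary ties
broken by gene id. Each iteration samples a fresh nontarget cohort 1:1
with targets — from the pool of expressed genes *not* predicted targets of
that family — by greedy nearest-neighbor matching on log10 3′ UTR length
without replacement, visiting targets in a seeded random order to avoid
systematic bias. Repression = median(nontarget log2FC) − median(target
log2FC), positive when targets are repressed; significance is a two-sided
Mann–Whitney U (exact by enumeration when min(n, m) ≤ 8 with no ties,
otherwise the normal approximation with tie and continuity corrections,
via scipy). The analysis runs 21 iterations; the report carries mean and SD
of repression, median P, and the iteration closest to the median P as the
representative for plotting. All randomness derives from one seed through
spawned per-iteration substreams.

## Synthetic data

The generators are first-class, tested code and define the study
conditions:

- **miRNA sets**: uniform-random sequences of 21–23 nt with unique 19-nt
  prefixes (a deliberate collision pair on request), with cluster/partner
  annotations emulating a 5p/3p strand pair and a co-transcribed cluster.
- **Transcriptomes**: 200 transcripts × 1 kb at uniform base composition
  (configurable GC), TPM 10, one planted trigger per miRNA — by default a
  contiguous WCF duplex over positions 13..L at offset 0, an 8mer seed —
  at a uniform random position whose full window fits. The emitted window
  realizes exactly the requested architecture: chance background
  configurations that would beat the intended score are removed by a
  deterministic repair loop that remutates the offending window bases. A
  "seed only" site is planted at the transcript 5′ terminus, where no
  upstream window exists and the empty configuration (score 0) is exact:
  for a miRNA whose 3′ region contains A, U and G, every base can pair
  something, so a random 30-nt window admitting *no* chance pairing is not
  generally realizable.
- **Alignments**: per-species planted substitutions (including compensatory
  pairs spanning the miRNA and site blocks) on otherwise identical rows.
- **Reads**: exact full-length mature sequences drawn multinomially from
  per-sample abundance vectors, plus fixed-count spike-in reads (counts,
  not molar amounts).
- **DE tables**: nontarget log2FC ~ N(0, σ); target log2FC ~ N(δ·w, σ)
  with per-gene weights w ~ U(0.5, 1.5) and context++ scores equal to −w
  plus noise, so the lowest-score decile carries the largest planted
  effects (as real top-ranked targets do); 3′ UTR lengths are log-normal
  (median ≈ 800 nt), optionally multiplied for targets to stress the
  length matcher. Defaults: 2,000 genes, δ = −0.3, σ = 0.2.

What passing tests on these data do and do not show: recovery of planted
architectures demonstrates the scorer, ranker, quantifier and repression
statistic are correct and calibrated *under the generative model* — exact
site planting, error-free reads, normal log2FCs, independent genes. Real
data add isomiRs and sequencing error, expression-dependent variance,
correlated genes, and annotation noise, none of which are simulated; the
suite validates the method, not the biology of any particular dataset.

## Problem sizes and numerics

The test suite verifies the optimizer against brute force on 1,000 random
small instances (3′ regions ≤ 10 nt, windows ≤ 14 nt, the oracle's
combinatorial guard), planted-trigger recovery on two replicates of the
200 × 1 kb / 10-miRNA transcriptome, read accounting at 10^5 reads/sample,
and repression calibration over 1,000 simulated null datasets (800 genes,
one iteration each) — sizes chosen to exercise every code path at
desk scale. Scores are small sums of halves and integers, compared exactly;
energies are rounded to 0.01 kcal/mol; cpm sums are checked to 1e−6
relative. Degenerate inputs are defined, not special-cased: empty windows
yield the empty configuration and the no-duplex sentinel, single-iteration
repression reports carry an undefined SD, and all-gap alignment rows are
explicit missing entries.

## Known limitations

- The energy model is a reduced parameterization for ranking; absolute
  ΔG values differ from full Turner-2004/ViennaRNA values (ordering agrees
  in tests).
- Ambiguous 19-nt prefix groups are merged, not apportioned; abundances of
  collided miRNAs are reported jointly.
- Conservation requires the provided alignment to span the full site
  context; ortholog mapping and alignment construction are upstream.
- The repression analysis treats genes as independent; P values inherit
  the Mann–Whitney assumptions and the matched design controls only UTR
  length, not other covariates (expression level is handled by the TPM
  floor).
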