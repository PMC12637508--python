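# tdmd-scout

Discovery and characterization of **target-directed miRNA degradation (TDMD)
trigger sites**.

In canonical miRNA targeting, the miRNA represses its targets. TDMD inverts
that direction: a transcript bearing a seed match *plus extensive
complementarity to the miRNA 3′ region* recruits the ZSWIM8 Cullin-RING E3
ligase pathway and directs degradation of the miRNA itself. `tdmd-scout` is
for researchers hunting such trigger sites in transcriptomes and
characterizing their hallmarks: the 3′-pairing architecture, duplex
thermodynamics, cross-species conservation with compensatory covariation,
strand/cluster-normalized miRNA quantification, and downstream de-repression
of the miRNA's predicted targets.

## The scoring scheme

For every canonical seed match (6mer / 7mer-A1 / 7mer-m8 / 8mer, pairing
miRNA nucleotides 2–7 with optional m8 pairing and a target A1), the 30 nt
immediately upstream of the site are searched for the pairing configuration
with the highest 3′ complementarity, scored in points:

1. each Watson–Crick–Franklin (WCF) pair at a miRNA position > 12 earns
   **+1**;
2. WCF pairing to the penultimate or third-to-last miRNA nucleotide earns an
   additional **+0.5** each;
3. G:U wobbles earn **0**, except **+0.5** for a wobble at the last miRNA
   position;
4. each internal gap or mismatch costs **−1** per interrupting column,
   max(miRNA-side gap, target-side gap);
5. offsets (target-loop minus miRNA-loop length between the seed helix and
   the first 3′ pair) beyond 3 nt cost **−0.5** per extra nucleotide.

The optimal configuration over all monotone (antiparallel) pairings is found
by dynamic programming and verified in the test suite against exhaustive
enumeration. An orthogonal RNA–RNA hybridization minimum free energy
(nearest-neighbor model; optional ViennaRNA `RNAduplex` backend) is reported
per candidate. Candidates are ranked per miRNA by score, filtered for
expression.

Downstream analyses follow the same conventions throughout: small-RNA reads
are assigned to miRNAs by a 19-nt exact prefix (spike-ins excluded from cpm
normalization) and normalized to co-transcribed cluster members; target
de-repression is measured as median(nontarget log2FC) − median(target
log2FC) against 1:1 nontarget cohorts matched on 3′ UTR length, Mann–Whitney
tested, over 21 resampling iterations.

## Worked example

The `analysis/` scripts run the whole pipeline over a synthetic study with
known truth (10 miRNAs, 200 × 1 kb transcriptome with one planted trigger
per miRNA, 4-species alignments, WT/KO small-RNA reads, a DE table with a
planted −0.3 log2 target shift):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_scan_triggers.py
python analysis/03_conservation.py
python analysis/04_quantify_smallrna.py
python analysis/05_target_repression.py
```

Output of `02_scan_triggers.py`:

```
scanned 463 candidate sites across 200 transcripts
planted trigger recovered at rank 1 with expected score: 10/10 miRNAs
median score margin over the best background site: 4.2 points
```

Every planted trigger outranks all background seed matches for its miRNA, at
exactly the score its planted architecture predicts. `03_conservation.py`
shows a planted compensatory substitution (miRNA position 17, C:G → G:C)
preserving the score of 12.0 in human while a seed-core disruption drops cow
to 4.0 with `seed_intact=False`. `04_quantify_smallrna.py` recovers the
planted 2.5-fold knockout response as 2.46 after partner normalization, and
`05_target_repression.py` reports mean repression 0.311 (all targets,
n = 202, median P ≈ 1e−34) and 0.377 for the top decile — the planted
−0.3 log2 shift, stronger in the top-ranked targets, as expected.

The same functionality is scriptable through the `tdmd-scout` CLI
(`scan`, `score-sites`, `conserve` via the library, `quantify`, `normalize`,
`repress`, `simulate`); run `tdmd-scout --help`.

## Layout

- `src/tdmd_scout/` — the library: `io_formats`, `seed_scan`,
  `pairing_score`, `duplex_energy`, `trigger_search`, `conservation`,
  `smallrna_quant`, `target_repression`, `synthetic_data`, `config`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite, including brute-force oracles and planted-truth
  round trips.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
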