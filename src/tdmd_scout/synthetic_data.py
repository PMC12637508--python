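"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here: mature miRNA sets
(with cluster/partner structure emulating a 5p/3p pair or a co-transcribed
miRNA cluster), transcriptomes with trigger sites planted at a requested
pairing architecture, multi-species alignments with planted substitutions
and compensatory pairs, small-RNA read sets drawn from known abundances
with spike-ins, and differential-expression tables with a planted target
shift.  Generators are pure functions of their seed and parameters, and the
planted truth is recorded alongside every emitted file so recovery can be
checked mechanically.

Background sequence composition defaults to uniform 25% per base; planted
windows are embedded at positions that do not overlap other planted
features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentBlock,
    MatureMiRNA,
    TranscriptRegion,
    reverse_complement,
)
from .pairing_score import (
    ScoreParams,
    best_configuration,
    build_configuration,
    zero_offset_target_pos,
)
from .seed_scan import find_seed_matches
from .target_repression import GeneRecord

_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


class PatternError(ValueError):
    """An internally inconsistent planted pairing pattern."""


@dataclass(frozen=True)
class PairingPattern:
    """Requested 3'-pairing architecture for a planted trigger site.

    ``wcf_positions``/``wobble_positions`` are 1-based miRNA positions to
    pair; ``offset`` displaces the whole 3' helix (target loop minus miRNA
    loop); ``target_gaps`` optionally sets the target-side gap length after
    a given miRNA position (default: equal to the miRNA-side gap, i.e.
    symmetric mismatches).
    """

    wcf_positions: tuple[int, ...]
    wobble_positions: tuple[int, ...] = ()
    offset: int = 0
    target_gaps: Mapping[int, int] = field(default_factory=dict)

    def pair_classes(self) -> list[tuple[int, str]]:
        both = set(self.wcf_positions) & set(self.wobble_positions)
        if both:
            raise PatternError(f"positions {sorted(both)} listed as both WCF and GU")
        out = [(p, "WCF") for p in self.wcf_positions]
        out += [(p, "GU") for p in self.wobble_positions]
        return sorted(out)


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    transcript_id: str
    seed_start: int
    site_type: str
    pattern: PairingPattern
    expected_score: float


@dataclass(frozen=True)
class PlantedTruth:
    planted_sites: tuple[PlantedSite, ...] = ()
    planted_sensitivity: tuple[tuple[str, float], ...] = ()
    planted_repression: tuple[str, float, float] | None = None
    rng_seed: int = 0


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(rng.choice(list("ACGU"), size=length, p=p))


def gen_mirna_set(
    n: int,
    length_range: tuple[int, int] = (21, 23),
    cluster_spec: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    collision_pair: bool = False,
    prefix_len: int = 19,
) -> list[MatureMiRNA]:
    """Random mature miRNAs with unique 19-nt prefixes.

    ``cluster_spec`` maps miRNA index names (miR-1, miR-2, ... in emission
    order) to normalization-partner name lists, emulating a passenger-strand
    pair or a co-transcribed cluster.  With ``collision_pair`` the last two
    miRNAs deliberately share a prefix (identical through ``prefix_len``,
    differing after), to exercise ambiguous-group handling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    seqs: list[str] = []
    prefixes: set[str] = set()
    attempts = 0
    while len(seqs) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValueError("cannot satisfy prefix uniqueness at this n/length")
        length = int(rng.integers(lo, hi + 1))
        s = _random_seq(rng, length)
        if s[:prefix_len] in prefixes:
            continue
        prefixes.add(s[:prefix_len])
        seqs.append(s)
    if collision_pair:
        if n < 2:
            raise ValueError("collision_pair needs n >= 2")
        base = seqs[-2]
        twin = base[:prefix_len] + _random_seq(rng, max(len(base) - prefix_len, 2))
        # force a difference after the shared prefix
        if twin[prefix_len:] == base[prefix_len:]:
            alt = "A" if base[prefix_len] != "A" else "C"
            twin = base[:prefix_len] + alt + twin[prefix_len + 1:]
        seqs[-1] = twin
    cluster_spec = cluster_spec or {}
    out = []
    for i, s in enumerate(seqs):
        name = f"miR-{i + 1}"
        out.append(
            MatureMiRNA(
                mirna_id=name,
                sequence=s,
                species="synthetic",
                normalization_partners=tuple(cluster_spec.get(name, ())),
            )
        )
    return out


def _pattern_pairs(
    pattern: PairingPattern, mirna: MatureMiRNA, seed_start: int,
    params: ScoreParams,
) -> list[tuple[int, int, str]]:
    """Resolve a pattern into explicit (miRNA pos, target pos, class) pairs."""
    classes = pattern.pair_classes()
    if not classes:
        return []
    length = len(mirna)
    for p, _ in classes:
        if not params.three_prime_start <= p <= length:
            raise PatternError(
                f"position {p} outside 3' region "
                f"{params.three_prime_start}..{length}"
            )
    m1 = classes[0][0]
    t = zero_offset_target_pos(seed_start, m1) - pattern.offset
    pairs = []
    prev_m = None
    for p, cls in classes:
        if prev_m is not None:
            mgap = p - prev_m - 1
            tgap = pattern.target_gaps.get(prev_m, mgap)
            t -= 1 + tgap
        pairs.append((p, t, cls))
        prev_m = p
    if pairs[-1][1] < 0:
        raise PatternError("pattern extends past the transcript 5' end")
    return pairs


def pattern_expected_score(
    pattern: PairingPattern,
    mirna: MatureMiRNA,
    params: ScoreParams | None = None,
    seed_start: int = 60,
) -> float:
    """Score the intended configuration itself (no search)."""
    params = params or ScoreParams()
    pairs = _pattern_pairs(pattern, mirna, seed_start, params)
    return build_configuration(pairs, mirna, params, seed_start).total_score


def plant_trigger_site(
    mirna: MatureMiRNA,
    pattern: PairingPattern,
    transcript_id: str = "planted",
    transcript_length: int = 300,
    site_position: int | None = None,
    background_gc: float = 0.5,
    seed: int = 0,
    params: ScoreParams | None = None,
    max_resample: int = 200,
) -> tuple[TranscriptRegion, PlantedSite]:
    """Emit a transcript whose upstream window realizes exactly ``pattern``.

    The seed site is an 8mer; the window bases at paired target positions
    are set to the WCF complement (or wobble partner) of their miRNA base,
    the rest is random background.  Backgrounds that by chance admit a
    configuration scoring differently from the intended one are resampled
    (deterministically from ``seed``), so the emitted transcript's best
    score equals the recorded ``expected_score``.
    """
    params = params or ScoreParams()
    rng = np.random.default_rng(seed)
    site_len = 8  # m8 column + 6mer core + A1
    if site_position is not None:
        seed_start = site_position
    elif not pattern.pair_classes():
        # a bare seed site is planted at the transcript 5' terminus: with no
        # upstream window, no chance 3' pairing can accrue and the best
        # configuration is exactly the empty one (score 0)
        seed_start = 1
    else:
        lo = params.window + len(mirna)
        if transcript_length < lo + site_len + 10:
            raise ValueError("transcript too short for the requested window")
        seed_start = int(rng.integers(lo, transcript_length - site_len))
    pairs = _pattern_pairs(pattern, mirna, seed_start, params)
    expected = build_configuration(pairs, mirna, params, seed_start).total_score
    site_type = "8mer"
    core = reverse_complement(mirna.sequence[1:7])
    m8_col = _COMPLEMENT[mirna.nt(8)]

    intended_positions = {t for _p, t, _cls in pairs}

    def build(seq: list[str]) -> TranscriptRegion:
        seq[seed_start - 1] = m8_col
        seq[seed_start:seed_start + 6] = core
        seq[seed_start + 6] = "A"
        for p, t, cls in pairs:
            base = mirna.nt(p)
            seq[t] = _COMPLEMENT[base] if cls == "WCF" else _WOBBLE_PARTNER[base]
        return TranscriptRegion(
            transcript_id=transcript_id, gene_id=transcript_id,
            region_kind="UTR3", sequence="".join(seq), tpm=10.0,
        )

    for _ in range(max_resample):
        seq = list(_random_seq(rng, transcript_length, background_gc))
        region = build(seq)
        # chance complementarity in the background window can beat the
        # intended architecture; repair by remutating the offending bases
        for _repair in range(50):
            match = next(
                (m for m in find_seed_matches(mirna, region)
                 if m.seed_start == seed_start), None,
            )
            if match is None or match.site_type != site_type:
                break
            config = best_configuration(mirna, match, region, params)
            if config.total_score == expected:
                truth = PlantedSite(
                    mirna_id=mirna.mirna_id,
                    transcript_id=transcript_id,
                    seed_start=seed_start,
                    site_type=site_type,
                    pattern=pattern,
                    expected_score=expected,
                )
                return region, truth
            stray = [t for _p, t, _cls in config.pairs
                     if t not in intended_positions]
            if not stray:
                break
            for t in stray:
                seq[t] = str(rng.choice(list("ACGU")))
            region = build(seq)
    raise RuntimeError(
        "could not realize the requested pattern against random background"
    )


def gen_transcriptome(
    mirnas: Sequence[MatureMiRNA],
    n_transcripts: int = 200,
    transcript_length: int = 1000,
    pattern: PairingPattern | None = None,
    background_gc: float = 0.5,
    seed: int = 0,
    params: ScoreParams | None = None,
    tpm: float = 10.0,
) -> tuple[list[TranscriptRegion], list[PlantedSite]]:
    """A transcriptome with one planted trigger per miRNA.

    The first ``len(mirnas)`` transcripts each carry one planted site (by
    default a contiguous WCF duplex over miRNA positions 13..L, offset 0 —
    the classic TDMD architecture); the remainder are pure background.
    """
    params = params or ScoreParams()
    if n_transcripts < len(mirnas):
        raise ValueError("need at least one transcript per miRNA")
    rng = np.random.default_rng(seed)
    regions: list[TranscriptRegion] = []
    truths: list[PlantedSite] = []
    for i, mirna in enumerate(mirnas):
        pat = pattern or PairingPattern(
            wcf_positions=tuple(range(13, len(mirna) + 1))
        )
        sub = int(rng.integers(0, 2**31 - 1))
        region, truth = plant_trigger_site(
            mirna, pat,
            transcript_id=f"tx{i + 1:04d}",
            transcript_length=transcript_length,
            background_gc=background_gc,
            seed=sub,
            params=params,
        )
        regions.append(region.with_tpm(tpm))
        truths.append(truth)
    for i in range(len(mirnas), n_transcripts):
        regions.append(
            TranscriptRegion(
                transcript_id=f"tx{i + 1:04d}",
                gene_id=f"tx{i + 1:04d}",
                region_kind="UTR3",
                sequence=_random_seq(rng, transcript_length, background_gc),
                tpm=tpm,
            )
        )
    return regions, truths


def gen_alignment(
    ref_seq: str,
    species_spec: Mapping[str, Sequence[tuple[int, str]]],
    reference_species: str = "mm10",
    reference_start: int = 0,
    seed: int = 0,
) -> AlignmentBlock:
    """Alignment block with planted per-species substitutions.

    ``species_spec`` maps species name to (reference position, new base)
    substitutions; the reference row is the input sequence unchanged.
    A compensatory pair is planted by substituting both the miRNA-locus
    block and the site-locus block at partnered positions.
    """
    rows = {reference_species: ref_seq}
    for species, subs in species_spec.items():
        row = list(ref_seq)
        for pos, base in subs:
            idx = pos - reference_start
            if not 0 <= idx < len(row):
                raise ValueError(f"{species}: position {pos} outside block")
            row[idx] = base
        rows[species] = "".join(row)
    return AlignmentBlock(
        reference_species=reference_species,
        rows=rows,
        reference_start=reference_start,
    )


def write_maf(blocks: Sequence[AlignmentBlock], path) -> None:
    """Write alignment blocks in MAF dialect (plus strand, RNA alphabet)."""
    with open(path, "w", encoding="ascii") as out:
        out.write("##maf version=1\n")
        for block in blocks:
            out.write("a score=0\n")
            ref = block.reference_species
            order = [ref] + sorted(s for s in block.rows if s != ref)
            for species in order:
                row = block.rows[species]
                size = sum(1 for c in row if c != "-")
                start = block.reference_start if species == ref else 0
                out.write(
                    f"s {species}.chr1 {start} {size} + {len(row)} {row}\n"
                )
            out.write("\n")


def gen_reads(
    mirnas: Sequence[MatureMiRNA],
    abundances: Mapping[str, Mapping[str, float]],
    n_reads: int = 100_000,
    spikeins: Sequence[MatureMiRNA] = (),
    spikein_counts: int = 0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Per-sample read lists drawn multinomially from known abundances.

    ``abundances`` maps sample -> {mirna_id: relative abundance}; reads are
    exact full-length mature sequences, with ``spikein_counts`` spike-in
    reads (cycled over the provided spike-ins) appended per sample.
    """
    rng = np.random.default_rng(seed)
    seq_by_id = {m.mirna_id: m.sequence for m in mirnas}
    out: dict[str, list[str]] = {}
    for sample in sorted(abundances):
        vec = abundances[sample]
        ids = sorted(vec)
        probs = np.array([vec[i] for i in ids], dtype=float)
        if probs.sum() <= 0:
            raise ValueError(f"{sample}: abundances must sum to a positive value")
        probs = probs / probs.sum()
        counts = rng.multinomial(n_reads, probs)
        reads: list[str] = []
        for mid, c in zip(ids, counts):
            reads.extend([seq_by_id[mid]] * int(c))
        for k in range(spikein_counts):
            reads.append(spikeins[k % len(spikeins)].sequence)
        out[sample] = reads
    return out


def gen_de_table(
    genes_n: int = 2000,
    family: str = "miR-1",
    delta: float = -0.3,
    sigma: float = 0.2,
    target_fraction: float = 0.15,
    utr_log10_mean: float = 2.9,
    utr_log10_sd: float = 0.45,
    length_confound: float = 1.0,
    tpm_log10_mean: float = 1.5,
    tpm_log10_sd: float = 0.6,
    seed: int = 0,
) -> tuple[list[GeneRecord], PlantedTruth]:
    """Differential-expression gene table with a planted target shift.

    Nontarget log2fc ~ N(0, sigma); target log2fc ~ N(delta*w, sigma) with
    per-gene weight w ~ U(0.5, 1.5), and context++ scores correlated with w
    (lower score = stronger predicted repression), so the lowest-score
    decile carries the largest planted effect.  ``length_confound``
    multiplies target 3' UTR lengths to stress the length matcher (1 = no
    confounding).
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_targets = int(round(genes_n * target_fraction))
    is_target = np.zeros(genes_n, dtype=bool)
    is_target[rng.choice(genes_n, size=n_targets, replace=False)] = True
    lengths = np.maximum(
        50, (10 ** rng.normal(utr_log10_mean, utr_log10_sd, genes_n)).astype(int)
    )
    lengths = np.where(is_target,
                       np.maximum(50, (lengths * length_confound).astype(int)),
                       lengths)
    tpm = 10 ** rng.normal(tpm_log10_mean, tpm_log10_sd, genes_n)
    weight = rng.uniform(0.5, 1.5, genes_n)
    mu = np.where(is_target, delta * weight, 0.0)
    log2fc = rng.normal(mu, sigma)
    ctx = -weight + rng.normal(0, 0.1, genes_n)
    genes = []
    for i in range(genes_n):
        genes.append(
            GeneRecord(
                gene_id=f"g{i + 1:05d}",
                log2fc=float(log2fc[i]),
                mean_tpm=float(tpm[i]),
                utr3_length=int(lengths[i]),
                predicted_target_of=frozenset({family}) if is_target[i] else frozenset(),
                contextpp_score=float(ctx[i]) if is_target[i] else None,
            )
        )
    truth = PlantedTruth(
        planted_repression=(family, delta, sigma), rng_seed=seed
    )
    return genes, truth


def genes_to_frame(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "log2fc": g.log2fc,
            "mean_tpm": g.mean_tpm,
            "utr3_length": g.utr3_length,
            "target_of": ";".join(sorted(g.predicted_target_of)),
            "contextpp_score": "" if g.contextpp_score is None else g.contextpp_score,
        })
    return pd.DataFrame(rows)


def frame_to_genes(df: pd.DataFrame) -> list[GeneRecord]:
    genes = []
    for row in df.itertuples(index=False):
        families = frozenset(str(row.target_of).split(";")) - {"", "nan"}
        ctx = getattr(row, "contextpp_score", "")
        ctx_val = None if ctx in ("", None) or (isinstance(ctx, float) and math.isnan(ctx)) else float(ctx)
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                log2fc=float(row.log2fc),
                mean_tpm=float(row.mean_tpm),
                utr3_length=int(row.utr3_length),
                predicted_target_of=families,
                contextpp_score=ctx_val,
            )
        )
    return genes
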