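"""Cross-species re-scoring of trigger sites and covariation detection.

Given multiple alignments over a trigger-site locus and over the miRNA
locus, each species' site sequence and mature miRNA are projected out of the
alignment, and the same scoring pipeline is re-run per species.  Sites whose
pairing survives sequence change — especially compensatory double
substitutions that preserve a base pair — are strong evidence of selection
on the pairing architecture itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import AlignmentBlock, MatureMiRNA, TranscriptRegion
from .pairing_score import ScoreParams, best_configuration, pair_class
from .seed_scan import SITE_TYPES, find_seed_matches, SeedMatch

_TYPE_STRENGTH = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}


class CoordinateError(ValueError):
    """A requested reference interval lies outside the alignment block."""


@dataclass(frozen=True)
class SpeciesSite:
    species: str
    site_sequence: str
    mirna_sequence: str | None
    total_score: float | None
    seed_intact: bool
    missing: bool = False
    low_confidence_mirna: bool = False


@dataclass(frozen=True)
class ConservationProfile:
    site_id: str
    reference_species: str
    per_species: tuple[SpeciesSite, ...]
    # reference pairing needed downstream for covariation detection:
    ref_pairs: tuple[tuple[int, int, str], ...] = ()
    ref_site_columns: tuple[int, ...] = ()  # alignment column per site position
    site_block: AlignmentBlock | None = None
    mirna_block: AlignmentBlock | None = None
    mirna_columns: tuple[int, ...] = ()  # alignment column per miRNA position


@dataclass(frozen=True)
class CovariationEvent:
    """Paired substitutions in miRNA and site that change a reference base
    pair into a different (possibly still pairing) combination."""

    mirna_pos: int
    species_set: tuple[str, ...]
    ref_pair: tuple[str, str]
    alt_pair: tuple[str, str]
    pairing_preserved: bool

    def __post_init__(self) -> None:
        if self.ref_pair == self.alt_pair:
            raise ValueError("covariation requires a changed pair")


def _columns_for_interval(block: AlignmentBlock, start: int, end: int) -> list[int]:
    """Alignment columns covering reference positions [start, end), including
    insertion (reference-gap) columns interior to the interval."""
    if start < 0 or end < start:
        raise CoordinateError(f"bad interval [{start}, {end})")
    ref = block.reference_row
    pos = block.reference_start
    first = last = None
    for col, base in enumerate(ref):
        if base == "-":
            continue
        if pos == start:
            first = col
        if pos == end - 1:
            last = col
        pos += 1
    if end == start:
        return []
    if first is None or last is None:
        raise CoordinateError(
            f"interval [{start}, {end}) outside block span "
            f"[{block.reference_start}, {pos})"
        )
    return list(range(first, last + 1))


def extract_species_site(
    block: AlignmentBlock, ref_start: int, ref_end: int
) -> dict[str, str | None]:
    """Per-species ungapped site sequence over a reference interval.

    Species whose row is entirely gapped over the interval map to ``None``
    (explicit missing flag) rather than being omitted.
    """
    cols = _columns_for_interval(block, ref_start, ref_end)
    out: dict[str, str | None] = {}
    for species, row in block.rows.items():
        seq = "".join(row[c] for c in cols).replace("-", "")
        out[species] = seq if seq else None
    return out


def predict_species_mirna(
    block: AlignmentBlock, ref_start: int, ref_end: int
) -> dict[str, tuple[str | None, bool]]:
    """Project the reference mature-miRNA interval onto each species.

    Returns species -> (mature sequence or None, low_confidence) where
    low_confidence flags extractions whose length differs from the reference
    mature by more than 2 nt.
    """
    ref_len = ref_end - ref_start
    sites = extract_species_site(block, ref_start, ref_end)
    out: dict[str, tuple[str | None, bool]] = {}
    for species, seq in sites.items():
        if seq is None:
            out[species] = (None, True)
        else:
            out[species] = (seq, abs(len(seq) - ref_len) > 2)
    return out


def _seed_intact(
    mirna: MatureMiRNA,
    context: str,
    ref_type: str,
    require_same_or_stronger: bool = True,
) -> bool:
    region = TranscriptRegion(
        transcript_id="ctx", gene_id="ctx", region_kind="UTR3",
        sequence=context, tpm=0.0,
    )
    matches = find_seed_matches(mirna, region)
    if not matches:
        return False
    if not require_same_or_stronger:
        return True
    best = max(_TYPE_STRENGTH[m.site_type] for m in matches)
    return best >= _TYPE_STRENGTH[ref_type]


def score_across_species(
    site_id: str,
    site_block: AlignmentBlock,
    site_ref_interval: tuple[int, int],
    mirna_block: AlignmentBlock,
    mirna_ref_interval: tuple[int, int],
    ref_match: SeedMatch,
    ref_region: TranscriptRegion,
    ref_mirna: MatureMiRNA,
    params: ScoreParams | None = None,
    mirna_overrides: Mapping[str, str] | None = None,
    require_same_or_stronger_seed: bool = True,
) -> ConservationProfile:
    """Re-score a trigger site in every aligned species.

    ``site_block`` must span the full site context (upstream window + seed +
    A1 position) in the reference; ``ref_match``/``ref_region`` are the
    reference-species inputs, so the reference row reproduces the reference
    score exactly.  Per-species mature miRNAs come from alignment projection
    unless overridden via ``mirna_overrides``.
    """
    params = params or ScoreParams()
    mirna_overrides = dict(mirna_overrides or {})
    sites = extract_species_site(site_block, *site_ref_interval)
    matures = predict_species_mirna(mirna_block, *mirna_ref_interval)

    rows: list[SpeciesSite] = []
    ref_pairs: tuple = ()
    for species in sorted(site_block.rows):
        site_seq = sites.get(species)
        mir_seq, low_conf = matures.get(species, (None, True))
        if species in mirna_overrides:
            mir_seq, low_conf = mirna_overrides[species], False
        if site_seq is None or mir_seq is None:
            rows.append(SpeciesSite(species, site_seq or "", mir_seq, None,
                                    seed_intact=False, missing=True,
                                    low_confidence_mirna=low_conf))
            continue
        if species == site_block.reference_species:
            mirna = ref_mirna
            region = ref_region
            match = ref_match
        else:
            try:
                mirna = MatureMiRNA(mirna_id=f"{ref_mirna.mirna_id}|{species}",
                                    sequence=mir_seq, species=species)
            except ValueError:
                rows.append(SpeciesSite(species, site_seq, mir_seq, None,
                                        seed_intact=False, missing=True,
                                        low_confidence_mirna=True))
                continue
            region = TranscriptRegion(
                transcript_id=f"{site_id}|{species}", gene_id=site_id,
                region_kind=ref_region.region_kind, sequence=site_seq,
            )
            match = _relocate_match(mirna, region, ref_match)
            if match is None:
                rows.append(SpeciesSite(
                    species, site_seq, mir_seq, 0.0,
                    seed_intact=False, low_confidence_mirna=low_conf))
                continue
        config = best_configuration(mirna, match, region, params)
        intact = _seed_intact(mirna, region.sequence, ref_match.site_type,
                              require_same_or_stronger_seed)
        if species == site_block.reference_species:
            ref_pairs = config.pairs
        rows.append(SpeciesSite(species, region.sequence, mirna.sequence,
                                config.total_score, seed_intact=intact,
                                low_confidence_mirna=low_conf))

    site_cols = _columns_for_interval(site_block, *site_ref_interval)
    mir_cols = _columns_for_interval(mirna_block, *mirna_ref_interval)
    return ConservationProfile(
        site_id=site_id,
        reference_species=site_block.reference_species,
        per_species=tuple(rows),
        ref_pairs=ref_pairs,
        ref_site_columns=tuple(site_cols),
        site_block=site_block,
        mirna_block=mirna_block,
        mirna_columns=tuple(mir_cols),
    )


def _relocate_match(
    mirna: MatureMiRNA, region: TranscriptRegion, ref_match: SeedMatch
) -> SeedMatch | None:
    """Find the species' own seed match closest to the reference location;
    None when the species site has no canonical seed match at all."""
    matches = find_seed_matches(mirna, region)
    if not matches:
        return None
    return min(matches, key=lambda m: abs(m.seed_start - ref_match.seed_start))


def detect_covariation(profile: ConservationProfile) -> list[CovariationEvent]:
    """Species where both the miRNA base and its paired site base differ
    from the reference at a reference-paired position.

    Works in alignment-column space: the site base partnered with miRNA
    position ``p`` is read from the same alignment column in every species,
    so indels elsewhere do not shift the comparison.
    """
    if profile.site_block is None or profile.mirna_block is None:
        return []
    site_block, mirna_block = profile.site_block, profile.mirna_block
    ref_sp = profile.reference_species
    site_start = profile.ref_site_columns[0] if profile.ref_site_columns else 0

    # Map each reference site position (transcript coordinate, within the
    # extracted interval) to its alignment column.
    ref_row = site_block.reference_row
    pos_to_col: dict[int, int] = {}
    pos = site_block.reference_start
    for col, base in enumerate(ref_row):
        if base != "-":
            pos_to_col[pos] = col
            pos += 1
    mir_ref_row = mirna_block.rows[ref_sp]
    mirna_pos_to_col: dict[int, int] = {}
    mpos = 1
    for col in profile.mirna_columns:
        if mir_ref_row[col] != "-":
            mirna_pos_to_col[mpos] = col
            mpos += 1

    events: dict[tuple[int, tuple[str, str], tuple[str, str]], list[str]] = {}
    for mirna_pos, target_pos, _cls in profile.ref_pairs:
        mcol = mirna_pos_to_col.get(mirna_pos)
        tcol = pos_to_col.get(target_pos)
        if mcol is None or tcol is None:
            continue
        ref_m = mir_ref_row[mcol]
        ref_t = ref_row[tcol]
        for species in site_block.rows:
            if species == ref_sp or species not in mirna_block.rows:
                continue
            alt_m = mirna_block.rows[species][mcol]
            alt_t = site_block.rows[species][tcol]
            if alt_m in ("-", "N") or alt_t in ("-", "N"):
                continue
            if alt_m != ref_m and alt_t != ref_t:
                key = (mirna_pos, (ref_m, ref_t), (alt_m, alt_t))
                events.setdefault(key, []).append(species)

    out = []
    for (mirna_pos, ref_pair, alt_pair), species_list in sorted(events.items()):
        out.append(
            CovariationEvent(
                mirna_pos=mirna_pos,
                species_set=tuple(sorted(species_list)),
                ref_pair=ref_pair,
                alt_pair=alt_pair,
                pairing_preserved=pair_class(*alt_pair) is not None,
            )
        )
    return out
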