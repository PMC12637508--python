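"""Candidate-trigger search: the two branches, expression filter, ranking.

The conserved branch scores externally provided (e.g. TargetScan-style
conserved) sites; the de novo branch scans every canonical seed match in
expressed 3' UTRs and lncRNAs.  Both run the identical scoring path —
seed match -> best 3'-pairing configuration -> duplex energy — so a site
present in both receives identical numbers.  Candidates are ranked per
(miRNA, branch) by descending pairing score; duplex energy is carried as an
orthogonal column, with an optional secondary sort to break score ties.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .duplex_energy import EnergyModel, energy_for_candidate
from .io_formats import MatureMiRNA, TranscriptRegion
from .pairing_score import (
    PairingConfiguration,
    ScoreParams,
    best_configuration,
    pairing_oneline,
    site_window,
)
from .seed_scan import SeedMatch, find_seed_matches

logger = logging.getLogger(__name__)

DEFAULT_MIN_TPM = 1.0


@dataclass(frozen=True)
class TriggerCandidate:
    """A seed match with its best 3' configuration, energy and rank."""

    mirna_id: str
    gene_id: str
    match: SeedMatch
    best_config: PairingConfiguration
    duplex_energy: float | None
    tpm: float
    branch: str  # {"conserved", "denovo"}
    rank: int

    @property
    def pairing_oneline(self) -> str:
        return pairing_oneline(self.best_config)


def filter_expression(
    regions: Sequence[TranscriptRegion],
    expression: pd.DataFrame,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> list[TranscriptRegion]:
    """Keep regions whose gene's mean TPM across samples is >= ``min_tpm``.

    Genes absent from the table are treated as unexpressed (TPM 0).
    Returned regions carry their mean TPM.
    """
    means = expression.groupby("gene_id")["tpm"].mean()
    kept = []
    for region in regions:
        tpm = float(means.get(region.gene_id, 0.0))
        if tpm >= min_tpm:
            kept.append(region.with_tpm(tpm))
    return kept


def _rank(
    scored: list[tuple[float, float | None, str, object]],
    energy_tiebreak: bool,
) -> list[int]:
    """Dense 1..n ranks by descending score; ties broken by energy
    (ascending, None last) when requested, then transcript_id."""
    def key(item):
        score, energy, tid, _ = item
        if not energy_tiebreak:
            return (-score, 0.0, tid)
        return (-score, energy if energy is not None else float("inf"), tid)

    order = sorted(range(len(scored)), key=lambda i: key(scored[i]))
    ranks = [0] * len(scored)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def _score_sites(
    sites: Iterable[tuple[MatureMiRNA, SeedMatch, TranscriptRegion]],
    params: ScoreParams,
    model: EnergyModel | None,
    energy_backend: str,
    branch: str,
    energy_tiebreak: bool,
) -> list[TriggerCandidate]:
    per_mirna: dict[str, list] = {}
    for mirna, match, region in sites:
        config = best_configuration(mirna, match, region, params)
        energy = energy_for_candidate(
            mirna, match, region, params, model, backend=energy_backend
        )
        per_mirna.setdefault(mirna.mirna_id, []).append(
            (config.total_score, energy, region.transcript_id,
             (match, region, config))
        )
    out: list[TriggerCandidate] = []
    for mirna_id in sorted(per_mirna):
        scored = per_mirna[mirna_id]
        ranks = _rank(scored, energy_tiebreak)
        for (score, energy, _tid, (match, region, config)), rank in zip(scored, ranks):
            out.append(
                TriggerCandidate(
                    mirna_id=mirna_id,
                    gene_id=region.gene_id,
                    match=match,
                    best_config=config,
                    duplex_energy=energy,
                    tpm=region.tpm,
                    branch=branch,
                    rank=rank,
                )
            )
    out.sort(key=lambda c: (c.mirna_id, c.rank, c.match.transcript_id))
    return out


def run_denovo_branch(
    regions: Sequence[TranscriptRegion],
    mirnas: Sequence[MatureMiRNA],
    params: ScoreParams | None = None,
    expression: pd.DataFrame | None = None,
    min_tpm: float = DEFAULT_MIN_TPM,
    site_types: Sequence[str] | None = None,
    model: EnergyModel | None = None,
    energy_backend: str = "builtin",
    energy_tiebreak: bool = True,
) -> list[TriggerCandidate]:
    """Scan expressed regions for canonical seed matches and rank them."""
    params = params or ScoreParams()
    if expression is not None:
        regions = filter_expression(regions, expression, min_tpm)
    else:
        regions = [r for r in regions if r.tpm >= min_tpm]

    def sites():
        for mirna in mirnas:
            for region in regions:
                kwargs = {"site_types": site_types} if site_types else {}
                for match in find_seed_matches(mirna, region, **kwargs):
                    yield mirna, match, region

    return _score_sites(sites(), params, model, energy_backend, "denovo",
                        energy_tiebreak)


def run_conserved_branch(
    conserved_sites: pd.DataFrame,
    regions: Sequence[TranscriptRegion],
    mirnas: Sequence[MatureMiRNA],
    params: ScoreParams | None = None,
    expression: pd.DataFrame | None = None,
    min_tpm: float = DEFAULT_MIN_TPM,
    model: EnergyModel | None = None,
    energy_backend: str = "builtin",
    energy_tiebreak: bool = True,
) -> list[TriggerCandidate]:
    """Score externally annotated sites (no rescanning).

    ``conserved_sites`` rows carry (mirna_id, transcript_id, seed_start,
    seed_end, site_type).  Sites on transcripts below the expression
    threshold are dropped; rows whose coordinates fall outside their
    transcript are skipped with a logged warning.
    """
    params = params or ScoreParams()
    if expression is not None:
        regions = filter_expression(regions, expression, min_tpm)
    else:
        regions = [r for r in regions if r.tpm >= min_tpm]
    region_by_id = {r.transcript_id: r for r in regions}
    mirna_by_id = {m.mirna_id: m for m in mirnas}

    triples = []
    for row in conserved_sites.itertuples(index=False):
        mirna = mirna_by_id.get(row.mirna_id)
        if mirna is None:
            logger.warning("conserved site for unknown miRNA %s skipped", row.mirna_id)
            continue
        region = region_by_id.get(row.transcript_id)
        if region is None:
            continue  # transcript filtered out or unknown
        seed_start, seed_end = int(row.seed_start), int(row.seed_end)
        if not (0 <= seed_start and seed_end <= len(region.sequence)
                and seed_end - seed_start == 6):
            logger.warning(
                "site %s:%d-%d outside transcript (len %d); row skipped",
                row.transcript_id, seed_start, seed_end, len(region.sequence),
            )
            continue
        seq = region.sequence
        m8_paired = seed_start > 0 and site_matches_m8(mirna, seq, seed_start)
        t1_is_A = seed_end < len(seq) and seq[seed_end] == "A"
        try:
            match = SeedMatch(
                mirna_id=mirna.mirna_id,
                transcript_id=region.transcript_id,
                site_type=_site_type(t1_is_A, m8_paired),
                seed_start=seed_start,
                seed_end=seed_end,
                t1_is_A=t1_is_A,
                m8_paired=m8_paired,
            )
        except ValueError as exc:
            logger.warning("conserved site row invalid (%s); skipped", exc)
            continue
        triples.append((mirna, match, region))
    return _score_sites(triples, params, model, energy_backend, "conserved",
                        energy_tiebreak)


def site_matches_m8(mirna: MatureMiRNA, seq: str, seed_start: int) -> bool:
    from .pairing_score import pair_class

    return pair_class(mirna.nt(8), seq[seed_start - 1]) == "WCF"


def _site_type(t1_is_A: bool, m8_paired: bool) -> str:
    if t1_is_A and m8_paired:
        return "8mer"
    if m8_paired:
        return "7mer-m8"
    if t1_is_A:
        return "7mer-A1"
    return "6mer"
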