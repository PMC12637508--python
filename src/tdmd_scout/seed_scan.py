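"""Canonical seed-match enumeration.

A seed match is target complementarity to miRNA nucleotides 2-7 (the 6mer
core), optionally augmented by pairing to nucleotide 8 (m8) and/or an A in
the target across from nucleotide 1 (A1).  The four canonical site types are
6mer, 7mer-A1, 7mer-m8 and 8mer; each 6mer-core occurrence is reported once
with the maximal type it supports (8mer > 7mer-m8 >= 7mer-A1 > 6mer), which
mirrors TargetScan site accounting and avoids double counting.

Because the duplex is antiparallel, target coordinates run opposite to miRNA
positions: if the 6mer core occupies target [s, s+6), the m8 pair sits at
target position s-1 and the A1 nucleotide at s+6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import MatureMiRNA, TranscriptRegion, reverse_complement

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_WCF = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class SeedMatch:
    """One canonical seed-site occurrence on a transcript region.

    ``seed_start``/``seed_end`` delimit the 6mer core (the target nucleotides
    pairing miRNA nt 2-7), 0-based half-open on the sense strand.
    """

    mirna_id: str
    transcript_id: str
    site_type: str
    seed_start: int
    seed_end: int
    t1_is_A: bool
    m8_paired: bool

    def __post_init__(self) -> None:
        if self.seed_end - self.seed_start != 6:
            raise ValueError("seed core must span exactly 6 nt")
        expected = _classify(self.t1_is_A, self.m8_paired)
        if self.site_type != expected:
            raise ValueError(
                f"site_type {self.site_type!r} inconsistent with "
                f"t1_is_A={self.t1_is_A}, m8_paired={self.m8_paired}"
            )


def _classify(t1_is_A: bool, m8_paired: bool) -> str:
    if t1_is_A and m8_paired:
        return "8mer"
    if m8_paired:
        return "7mer-m8"
    if t1_is_A:
        return "7mer-A1"
    return "6mer"


def seed_site_strings(mirna: MatureMiRNA) -> dict[str, str]:
    """Exact target substrings recognized for each canonical site type.

    6mer = revcomp(nt 2-7); 7mer-m8 = revcomp(nt 2-8); 7mer-A1 = 6mer + "A";
    8mer = 7mer-m8 + "A".
    """
    if len(mirna) < 8:
        raise ValueError(f"{mirna.mirna_id}: miRNA shorter than 8 nt")
    core = reverse_complement(mirna.sequence[1:7])
    with_m8 = reverse_complement(mirna.sequence[1:8])
    return {
        "6mer": core,
        "7mer-m8": with_m8,
        "7mer-A1": core + "A",
        "8mer": with_m8 + "A",
    }


def find_seed_matches(
    mirna: MatureMiRNA,
    region: TranscriptRegion,
    site_types: Sequence[str] = SITE_TYPES,
) -> list[SeedMatch]:
    """All canonical seed matches of ``mirna`` in ``region``, 5'->3' order.

    Every occurrence of the 6mer core is reported exactly once, labeled with
    the maximal supported site type; overlapping occurrences at distinct
    coordinates are all reported.  ``site_types`` restricts which labels are
    emitted (occurrences whose maximal type is excluded are dropped).
    """
    wanted = set(site_types)
    unknown = wanted - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site type(s) {sorted(unknown)}")
    seq = region.sequence
    core = reverse_complement(mirna.sequence[1:7])
    m8_base = mirna.nt(8)
    matches: list[SeedMatch] = []
    start = seq.find(core)
    while start != -1:
        end = start + 6
        m8_paired = start > 0 and (seq[start - 1], m8_base) in _WCF
        t1_is_A = end < len(seq) and seq[end] == "A"
        site_type = _classify(t1_is_A, m8_paired)
        if site_type in wanted:
            matches.append(
                SeedMatch(
                    mirna_id=mirna.mirna_id,
                    transcript_id=region.transcript_id,
                    site_type=site_type,
                    seed_start=start,
                    seed_end=end,
                    t1_is_A=t1_is_A,
                    m8_paired=m8_paired,
                )
            )
        start = seq.find(core, start + 1)
    return matches
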