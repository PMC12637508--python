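import numpy as np
import pytest

from tdmd_scout.io_formats import MatureMiRNA, TranscriptRegion, reverse_complement
from tdmd_scout.pairing_score import ScoreParams
from tdmd_scout.seed_scan import find_seed_matches


@pytest.fixture
def let7() -> MatureMiRNA:
    """A 22-nt let-7a-like mature miRNA used throughout the scoring tests."""
    return MatureMiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def params() -> ScoreParams:
    return ScoreParams()


def make_region(sequence: str, transcript_id: str = "tx1", tpm: float = 10.0) -> TranscriptRegion:
    return TranscriptRegion(
        transcript_id=transcript_id, gene_id=transcript_id,
        region_kind="UTR3", sequence=sequence, tpm=tpm,
    )


def region_with_seed(mirna: MatureMiRNA, upstream: str, downstream: str = "GGG",
                     transcript_id: str = "tx1") -> tuple[TranscriptRegion, int]:
    """Region = upstream + m8 column + 6mer core + A1 + downstream; returns
    (region, seed_start).  The site is always an 8mer."""
    core = reverse_complement(mirna.sequence[1:7])
    m8 = {"A": "U", "U": "A", "G": "C", "C": "G"}[mirna.nt(8)]
    seq = upstream + m8 + core + "A" + downstream
    return make_region(seq, transcript_id), len(upstream) + 1


def seed_match_at(mirna: MatureMiRNA, region: TranscriptRegion, seed_start: int):
    for m in find_seed_matches(mirna, region):
        if m.seed_start == seed_start:
            return m
    raise AssertionError(f"no seed match at {seed_start}")


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
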