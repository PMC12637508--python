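import pytest

from tdmd_scout.conservation import (
    CoordinateError,
    detect_covariation,
    extract_species_site,
    predict_species_mirna,
    score_across_species,
)
from tdmd_scout.io_formats import AlignmentBlock, MatureMiRNA
from tdmd_scout.pairing_score import ScoreParams, best_configuration
from tdmd_scout.seed_scan import find_seed_matches
from tdmd_scout.synthetic_data import PairingPattern, gen_alignment, plant_trigger_site

from .conftest import seed_match_at


def block(rows, ref="mm10", start=0):
    return AlignmentBlock(reference_species=ref, rows=rows, reference_start=start)


class TestExtractSpeciesSite:
    def test_ungapped_extraction(self):
        b = block({"mm10": "ACGUACGU", "hg38": "ACGAACGU"})
        out = extract_species_site(b, 2, 6)
        assert out == {"mm10": "GUAC", "hg38": "GAAC"}

    def test_all_gap_species_flagged_missing(self):
        b = block({"mm10": "ACGU", "hg38": "A--U"})
        out = extract_species_site(b, 1, 3)
        assert out["hg38"] is None

    def test_insertion_lengthens_species_site(self):
        # hg38 carries a 2-nt insertion inside the interval
        b = block({"mm10": "AC--GUAC", "hg38": "ACGGGUAC"})
        out = extract_species_site(b, 1, 4)
        assert out["mm10"] == "CGU"
        assert out["hg38"] == "CGGGU"

    def test_interval_outside_block_rejected(self):
        b = block({"mm10": "ACGU"})
        with pytest.raises(CoordinateError):
            extract_species_site(b, 2, 9)


class TestPredictSpeciesMirna:
    def test_identical_rows_identical_matures(self):
        b = block({"mm10": "ACGUACGUACGU", "hg38": "ACGUACGUACGU"})
        out = predict_species_mirna(b, 0, 12)
        assert out["hg38"] == ("ACGUACGUACGU", False)

    def test_single_substitution_projected(self):
        ref = "UGAGGUAGUAGGUUGUAUAGUU"
        alt = ref[:16] + "G" + ref[17:]
        b = block({"mm10": ref, "hg38": alt})
        out = predict_species_mirna(b, 0, len(ref))
        assert out["hg38"][0] != ref
        assert out["hg38"][0][16] == "G"
        assert out["hg38"][1] is False

    def test_large_deletion_low_confidence(self):
        ref = "UGAGGUAGUAGGUUGUAUAGUU"
        b = block({"mm10": ref, "hg38": ref[:10] + "-" * 5 + ref[15:]})
        out = predict_species_mirna(b, 0, len(ref))
        assert out["hg38"][1] is True


class TestScoreAcrossSpecies:
    def _setup(self, let7, mirna_subs=None, site_subs=None):
        pattern = PairingPattern(tuple(range(13, 23)))
        region, truth = plant_trigger_site(let7, pattern, seed=31)
        match = seed_match_at(let7, region, truth.seed_start)
        site_block = gen_alignment(region.sequence, {
            "hg38": site_subs or [], "rn6": [],
        })
        mir_block = gen_alignment(let7.sequence, {
            "hg38": mirna_subs or [], "rn6": [],
        })
        profile = score_across_species(
            "site", site_block, (0, len(region.sequence)),
            mir_block, (0, len(let7.sequence)),
            match, region, let7,
        )
        return profile, region, match, truth

    def test_identical_species_identical_scores(self, let7):
        profile, *_ = self._setup(let7)
        scores = {s.species: s.total_score for s in profile.per_species}
        assert scores == {"mm10": 11.0, "hg38": 11.0, "rn6": 11.0}

    def test_reference_fidelity(self, let7):
        """The reference row reproduces the trigger_search score exactly."""
        profile, region, match, _ = self._setup(let7)
        direct = best_configuration(let7, match, region).total_score
        ref_row = next(s for s in profile.per_species if s.species == "mm10")
        assert ref_row.total_score == direct

    def test_seed_disruption_flagged_in_one_species(self, let7):
        _, region, match, truth = self._setup(let7)
        # break the seed core in hg38 only: the core pairs nt 2-7, mutate its
        # middle base to the same base as the reference miRNA partner
        core_pos = truth.seed_start + 2
        ref_base = region.sequence[core_pos]
        new_base = "C" if ref_base != "C" else "G"
        profile, *_ = self._setup(let7, site_subs=[(core_pos, new_base)])
        intact = {s.species: s.seed_intact for s in profile.per_species}
        assert intact["hg38"] is False
        assert intact["mm10"] is True and intact["rn6"] is True

    def test_compensatory_pair_preserves_score(self, let7):
        _, region, match, truth = self._setup(let7)
        cfg = best_configuration(let7, match, region)
        mpos, tpos, _ = next(p for p in cfg.pairs if p[0] == 17)
        ref_m = let7.nt(17)
        assert ref_m == "A"  # A:U reference pair -> G:C compensatory
        profile, *_ = self._setup(
            let7, mirna_subs=[(16, "G")], site_subs=[(tpos, "C")])
        scores = {s.species: s.total_score for s in profile.per_species}
        assert scores["hg38"] == scores["mm10"] == 11.0
        events = detect_covariation(profile)
        assert len(events) == 1
        ev = events[0]
        assert ev.mirna_pos == 17 and ev.pairing_preserved is True
        assert ev.species_set == ("hg38",)

    def test_gap_robustness(self, let7):
        """Insertion columns (gaps in the reference) leave the reference
        score unchanged."""
        pattern = PairingPattern(tuple(range(13, 23)))
        region, truth = plant_trigger_site(let7, pattern, seed=32)
        match = seed_match_at(let7, region, truth.seed_start)
        seq = region.sequence
        cut = truth.seed_start - 40
        rows = {
            "mm10": seq[:cut] + "--" + seq[cut:],
            "hg38": seq[:cut] + "GG" + seq[cut:],
        }
        site_block = block(rows)
        mir_block = gen_alignment(let7.sequence, {"hg38": []})
        profile = score_across_species(
            "site", site_block, (0, len(seq)),
            mir_block, (0, len(let7.sequence)),
            match, region, let7,
        )
        ref_row = next(s for s in profile.per_species if s.species == "mm10")
        assert ref_row.total_score == 11.0


class TestDetectCovariation:
    def test_no_substitutions_no_events(self, let7):
        pattern = PairingPattern(tuple(range(13, 23)))
        region, truth = plant_trigger_site(let7, pattern, seed=33)
        match = seed_match_at(let7, region, truth.seed_start)
        site_block = gen_alignment(region.sequence, {"hg38": []})
        mir_block = gen_alignment(let7.sequence, {"hg38": []})
        profile = score_across_species(
            "site", site_block, (0, len(region.sequence)),
            mir_block, (0, len(let7.sequence)), match, region, let7)
        assert detect_covariation(profile) == []

    def test_mirna_only_substitution_is_not_covariation(self, let7):
        pattern = PairingPattern(tuple(range(13, 23)))
        region, truth = plant_trigger_site(let7, pattern, seed=34)
        match = seed_match_at(let7, region, truth.seed_start)
        site_block = gen_alignment(region.sequence, {"hg38": []})
        mir_block = gen_alignment(let7.sequence, {"hg38": [(16, "G")]})
        profile = score_across_species(
            "site", site_block, (0, len(region.sequence)),
            mir_block, (0, len(let7.sequence)), match, region, let7)
        assert detect_covariation(profile) == []
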