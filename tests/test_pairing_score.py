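import numpy as np
import pytest

from tdmd_scout.io_formats import MatureMiRNA, reverse_complement
from tdmd_scout.pairing_score import (
    ScoreParams,
    SizeError,
    best_configuration,
    build_configuration,
    empty_configuration,
    exhaustive_best,
    pairing_string,
    score_configuration,
    site_window,
)
from tdmd_scout.synthetic_data import PairingPattern, pattern_expected_score, plant_trigger_site
from tdmd_scout.seed_scan import find_seed_matches

from .conftest import make_region, random_rna, region_with_seed, seed_match_at


class TestScoreConfiguration:
    """Hand-derived applications of the five-rule point scheme."""

    @pytest.mark.parametrize(
        "pattern, expected_total, expected_parts",
        [
            # contiguous WCF over nt 13-22: 10 matches + end bonuses at 21, 20
            (PairingPattern(tuple(range(13, 23))), 11.0,
             dict(base_points=10.0, end_bonus=1.0)),
            # 1x1 mismatch at position 17
            (PairingPattern(tuple(p for p in range(13, 23) if p != 17)), 9.0,
             dict(base_points=9.0, end_bonus=1.0, interruption_penalty=1.0)),
            # terminal G:U wobble at position 22
            (PairingPattern(tuple(range(13, 22)), wobble_positions=(22,)), 10.5,
             dict(base_points=9.0, end_bonus=1.0, terminal_wobble_bonus=0.5)),
            # offset 5: 0.5 x (5 - 3) penalty
            (PairingPattern(tuple(range(13, 23)), offset=5), 10.0,
             dict(offset_penalty=1.0)),
            # pairs at 9-12 only: contiguity helpers, zero points
            (PairingPattern(tuple(range(9, 13))), 0.0, dict(base_points=0.0)),
        ],
    )
    def test_rule_applications(self, let7, pattern, expected_total, expected_parts):
        total = pattern_expected_score(pattern, let7)
        assert total == expected_total
        from tdmd_scout.synthetic_data import _pattern_pairs
        pairs = _pattern_pairs(pattern, let7, 60, ScoreParams())
        cfg = build_configuration(pairs, let7, ScoreParams(), 60)
        for part, value in expected_parts.items():
            assert getattr(cfg.breakdown, part) == value

    def test_empty_configuration_scores_zero(self, let7):
        cfg = empty_configuration()
        assert cfg.total_score == 0.0
        assert score_configuration(cfg, let7, ScoreParams()).total == 0.0

    def test_breakdown_sums_to_total(self, let7):
        pattern = PairingPattern(tuple(p for p in range(13, 23) if p != 15),
                                 wobble_positions=(12,), offset=4)
        from tdmd_scout.synthetic_data import _pattern_pairs
        pairs = _pattern_pairs(pattern, let7, 60, ScoreParams())
        cfg = build_configuration(pairs, let7, ScoreParams(), 60)
        b = cfg.breakdown
        assert cfg.total_score == pytest.approx(
            b.base_points + b.end_bonus + b.terminal_wobble_bonus
            - b.interruption_penalty - b.offset_penalty
        )

    def test_inconsistent_pair_label_names_position(self, let7):
        region, seed_start = region_with_seed(let7, "A" * 30)
        pairs = [(13, seed_start + 7 - 13, "WCF")]  # A opposite U13? U13:A is WCF
        cfg = build_configuration(pairs, let7, ScoreParams(), seed_start)
        # relabel as GU, contradicting the bases
        bad = build_configuration([(13, seed_start + 7 - 13, "GU")], let7,
                                  ScoreParams(), seed_start)
        with pytest.raises(ValueError, match="13"):
            score_configuration(bad, let7, ScoreParams(), target_seq=region.sequence)
        # correctly labeled passes
        score_configuration(cfg, let7, ScoreParams(), target_seq=region.sequence)

    def test_end_bonus_once_mode(self, let7):
        pattern = PairingPattern(tuple(range(13, 23)))
        once = pattern_expected_score(
            pattern, let7, ScoreParams(end_bonus_mode="once"))
        assert once == 10.5  # single 0.5 bonus instead of two


class TestScoreProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.sets(st.integers(13, 22), min_size=0, max_size=10),
           st.integers(-6, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_breakdown_components_sum_to_total(self, positions, offset):
        """For any pattern of WCF positions and offset, the breakdown
        components sum to the total."""
        from tdmd_scout.io_formats import MatureMiRNA
        from tdmd_scout.synthetic_data import PairingPattern, _pattern_pairs

        mirna = MatureMiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")
        pattern = PairingPattern(tuple(sorted(positions)), offset=offset)
        pairs = _pattern_pairs(pattern, mirna, 80, ScoreParams())
        cfg = build_configuration(pairs, mirna, ScoreParams(), 80)
        b = cfg.breakdown
        assert cfg.total_score == pytest.approx(
            b.base_points + b.end_bonus + b.terminal_wobble_bonus
            - b.interruption_penalty - b.offset_penalty)
        assert cfg.total_score == pytest.approx(
            score_configuration(cfg, mirna, ScoreParams()).total)


class TestBestConfiguration:
    def test_planted_perfect_duplex_recovered(self, let7):
        region, truth = plant_trigger_site(
            let7, PairingPattern(tuple(range(13, 23))), seed=11)
        match = seed_match_at(let7, region, truth.seed_start)
        cfg = best_configuration(let7, match, region)
        assert cfg.total_score == 11.0
        assert cfg.offset == 0
        assert cfg.interruptions == ()

    def test_hopeless_window_returns_empty(self):
        # miRNA 3' region without U: an all-A window admits no pair at all
        m = MatureMiRNA("noU", "UGAGGUAGUAGGGGAGGGAGGG")
        region, seed_start = region_with_seed(m, "A" * 30)
        match = seed_match_at(m, region, seed_start)
        cfg = best_configuration(m, match, region)
        assert cfg.is_empty and cfg.total_score == 0.0

    def test_truncated_window_returns_empty(self, let7):
        region, seed_start = region_with_seed(let7, "")
        # seed at position 1: the upstream window has length 0
        match = seed_match_at(let7, region, seed_start)
        cfg = best_configuration(let7, match, region)
        assert cfg.is_empty

    def test_deterministic_across_runs(self, let7):
        rng = np.random.default_rng(5)
        region = make_region(random_rna(rng, 200))
        matches = find_seed_matches(let7, make_region(
            region.sequence[:100] + "CUACCUCA" + region.sequence[100:]))
        region2 = make_region(region.sequence[:100] + "CUACCUCA" + region.sequence[100:])
        for match in matches:
            a = best_configuration(let7, match, region2)
            b = best_configuration(let7, match, region2)
            assert a == b

    def test_contiguous_extension_never_hurts(self, let7):
        """Growing a helix by one more contiguous WCF pair beyond position
        12 (offset unchanged) never lowers the score."""
        prev = None
        for upto in range(14, 24):
            pattern = PairingPattern(tuple(range(13, upto)))
            score = pattern_expected_score(pattern, let7)
            if prev is not None:
                assert score >= prev
            prev = score


class TestOracleEquivalence:
    def _random_instance(self, rng):
        L = int(rng.integers(16, 19))  # 3' region of 8-10 nt
        mirna = MatureMiRNA("m", random_rna(rng, L))
        W = int(rng.integers(5, 15))
        region, seed_start = region_with_seed(
            mirna, random_rna(rng, W + 1), random_rna(rng, 3))
        params = ScoreParams(window=W)
        return mirna, seed_match_at(mirna, region, seed_start), region, params

    @pytest.mark.parametrize("batch", range(4))
    def test_dp_matches_exhaustive_on_random_instances(self, batch):
        rng = np.random.default_rng(1000 + batch)
        for _ in range(75):
            mirna, match, region, params = self._random_instance(rng)
            a = best_configuration(mirna, match, region, params)
            b = exhaustive_best(mirna, match, region, params)
            assert a.total_score == b.total_score
            if not a.is_empty:
                # both searches apply the same deterministic tie-break
                assert (abs(a.offset), a.n_interruptions, a.pairs[-1][1]) == \
                       (abs(b.offset), b.n_interruptions, b.pairs[-1][1])

    def test_oracle_guard(self, let7):
        region, seed_start = region_with_seed(let7, "A" * 31)
        match = seed_match_at(let7, region, seed_start)
        with pytest.raises(SizeError):
            exhaustive_best(let7, match, region, ScoreParams())

    def test_single_pairable_position(self):
        # 3' region of C's ending in G: only the terminal wobble can pair
        # the lone U in an otherwise all-A window
        m = MatureMiRNA("gend", "UGAGGUAG" + "CCCCCCCCCG")
        # the U sits at the offset-0 register for the terminal position
        region, seed_start = region_with_seed(m, "AA" + "U" + "A" * 9)
        match = seed_match_at(m, region, seed_start)
        params = ScoreParams(window=12)
        b = exhaustive_best(m, match, region, params)
        a = best_configuration(m, match, region, params)
        assert a.total_score == b.total_score == 0.5
        assert a.pairs[0][2] == "GU" and a.pairs[0][0] == len(m)


class TestPairingString:
    def _intended_config(self, let7, pattern, truth, params):
        from tdmd_scout.synthetic_data import _pattern_pairs

        pairs = _pattern_pairs(pattern, let7, truth.seed_start, params)
        return build_configuration(pairs, let7, params, truth.seed_start)

    def test_perfect_duplex_has_ten_bars(self, let7):
        pattern = PairingPattern(tuple(range(13, 23)))
        region, truth = plant_trigger_site(let7, pattern, seed=2)
        match = seed_match_at(let7, region, truth.seed_start)
        cfg = self._intended_config(let7, pattern, truth, ScoreParams())
        window, w0 = site_window(match, region, ScoreParams())
        lines = pairing_string(cfg, let7, window, w0).splitlines()
        assert lines[1].count("|") == 10 and lines[1].count(":") == 0

    def test_terminal_wobble_renders_colon(self, let7):
        pattern = PairingPattern(tuple(range(13, 22)), wobble_positions=(22,))
        region, truth = plant_trigger_site(let7, pattern, seed=3)
        match = seed_match_at(let7, region, truth.seed_start)
        cfg = self._intended_config(let7, pattern, truth, ScoreParams())
        window, w0 = site_window(match, region, ScoreParams())
        mid = pairing_string(cfg, let7, window, w0).splitlines()[1]
        assert mid.count(":") == 1

    def test_empty_configuration_renders_empty_middle(self, let7):
        region, seed_start = region_with_seed(let7, "G" * 30)
        window, w0 = site_window(
            seed_match_at(let7, region, seed_start), region, ScoreParams())
        out = pairing_string(empty_configuration(), let7, window, w0)
        assert out.splitlines()[1] == ""
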