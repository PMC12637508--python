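"""Point-based scoring of miRNA 3'-pairing architecture and optimal search.

TDMD trigger sites couple a canonical seed match with extensive pairing to
the miRNA 3' region.  The scoring scheme quantifies that 3' pairing:

1. each Watson-Crick-Franklin (WCF) pair after miRNA nucleotide 12 earns
   ``match_point`` (default 1);
2. WCF pairing to the penultimate or third-to-last miRNA nucleotide earns an
   additional ``end_bonus`` (default 0.5, per position);
3. G:U wobbles earn nothing, except ``terminal_wobble_bonus`` (default 0.5)
   for a wobble at the last miRNA position;
4. each internal gap or mismatch costs ``interruption_point`` (default 1)
   per interrupting column, i.e. max(miRNA-side gap, target-side gap);
5. offsets beyond ``offset_free`` (default 3) cost ``offset_point``
   (default 0.5) per extra nucleotide.

The search window is the ``window`` (default 30) nucleotides immediately 5'
of the target nucleotide opposite miRNA position 8.  The offset is the
target-side loop length minus the miRNA-side loop length between the seed
helix and the first 3' pair; positive offsets displace the 3' helix toward
the target 5' end.

``best_configuration`` finds the maximal-scoring arrangement by dynamic
programming over (miRNA position, window position) cells; ``exhaustive_best``
is an independent brute-force enumerator used as a test oracle on small
instances.  Ties are broken deterministically: smaller |offset|, then fewer
interruption events, then the 5'-most target start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import MatureMiRNA, TranscriptRegion
from .seed_scan import SeedMatch

WCF_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}


class SizeError(ValueError):
    """Instance exceeds the combinatorial guard of the exhaustive oracle."""


def pair_class(mirna_base: str, target_base: str) -> str | None:
    """"WCF", "GU", or None if the two bases cannot pair."""
    duo = (mirna_base, target_base)
    if duo in WCF_PAIRS:
        return "WCF"
    if duo in GU_PAIRS:
        return "GU"
    return None


@dataclass(frozen=True)
class ScoreParams:
    """Tunable point values of the 3'-pairing scheme (all points >= 0)."""

    match_point: float = 1.0
    end_bonus: float = 0.5
    terminal_wobble_bonus: float = 0.5
    interruption_point: float = 1.0
    offset_free: int = 3
    offset_point: float = 0.5
    window: int = 30
    three_prime_start: int = 9
    end_bonus_mode: str = "per_position"  # or "once"

    def __post_init__(self) -> None:
        for name in ("match_point", "end_bonus", "terminal_wobble_bonus",
                     "interruption_point", "offset_point"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.three_prime_start < 9:
            raise ValueError("three_prime_start must be >= 9")
        if self.end_bonus_mode not in ("per_position", "once"):
            raise ValueError("end_bonus_mode must be 'per_position' or 'once'")


@dataclass(frozen=True)
class ScoreBreakdown:
    base_points: float = 0.0
    end_bonus: float = 0.0
    terminal_wobble_bonus: float = 0.0
    interruption_penalty: float = 0.0
    offset_penalty: float = 0.0

    @property
    def total(self) -> float:
        return (self.base_points + self.end_bonus + self.terminal_wobble_bonus
                - self.interruption_penalty - self.offset_penalty)


@dataclass(frozen=True)
class PairingConfiguration:
    """An explicit miRNA-3'-region-to-window pairing arrangement.

    ``pairs`` is ordered by strictly increasing 1-based miRNA position with
    strictly decreasing 0-based target position (antiparallel strands).
    ``interruptions`` lists (miRNA_gap, target_gap) for each internal break.
    """

    pairs: tuple[tuple[int, int, str], ...]
    offset: int
    interruptions: tuple[tuple[int, int], ...]
    breakdown: ScoreBreakdown
    total_score: float

    def __post_init__(self) -> None:
        last_m, last_t = 0, None
        for m, t, cls in self.pairs:
            if m <= last_m:
                raise ValueError("miRNA positions must strictly increase")
            if last_t is not None and t >= last_t:
                raise ValueError("target positions must strictly decrease")
            if cls not in ("WCF", "GU"):
                raise ValueError(f"unknown pair class {cls!r}")
            last_m, last_t = m, t

    @property
    def is_empty(self) -> bool:
        return not self.pairs

    @property
    def n_interruptions(self) -> int:
        return len(self.interruptions)


EMPTY_BREAKDOWN = ScoreBreakdown()


def empty_configuration() -> PairingConfiguration:
    return PairingConfiguration((), 0, (), EMPTY_BREAKDOWN, 0.0)


def _interruptions(pairs: Sequence[tuple[int, int, str]]) -> tuple[tuple[int, int], ...]:
    events = []
    for (m1, t1, _), (m2, t2, _) in zip(pairs, pairs[1:]):
        mgap, tgap = m2 - m1 - 1, t1 - t2 - 1
        if mgap or tgap:
            events.append((mgap, tgap))
    return tuple(events)


def score_pairs(
    pairs: Sequence[tuple[int, int, str]],
    offset: int,
    mirna: MatureMiRNA,
    params: ScoreParams,
) -> ScoreBreakdown:
    """Apply the five-rule scheme to an explicit pair list.

    Positions 9-12 may pair (maintaining contiguity) but earn no base
    points; wobbles earn nothing except at the terminal position; terminal
    unpaired overhangs are free.
    """
    length = len(mirna)
    base = end = wobble = 0.0
    end_positions = (length - 1, length - 2)
    end_hits = 0
    for m, _t, cls in pairs:
        if cls == "WCF":
            if m > 12:
                base += params.match_point
            if m in end_positions:
                end_hits += 1
        else:  # GU
            if m == length:
                wobble = params.terminal_wobble_bonus
    if params.end_bonus_mode == "per_position":
        end = params.end_bonus * end_hits
    else:
        end = params.end_bonus * (1 if end_hits else 0)
    interruption = params.interruption_point * sum(
        max(mg, tg) for mg, tg in _interruptions(pairs)
    )
    off_pen = 0.0
    if pairs:
        off_pen = params.offset_point * max(0, abs(offset) - params.offset_free)
    return ScoreBreakdown(base, end, wobble, interruption, off_pen)


def score_configuration(
    config: PairingConfiguration,
    mirna: MatureMiRNA,
    params: ScoreParams,
    target_seq: str | None = None,
) -> ScoreBreakdown:
    """Recompute the score breakdown of a configuration.

    When ``target_seq`` (the transcript/window sequence indexed by the
    configuration's target positions) is supplied, each pair label is
    validated against the actual bases; an inconsistent label raises a
    ValueError naming the miRNA position.
    """
    for m, t, cls in config.pairs:
        if not params.three_prime_start <= m <= len(mirna):
            raise ValueError(
                f"miRNA position {m} outside 3' region "
                f"{params.three_prime_start}..{len(mirna)}"
            )
        if target_seq is not None:
            actual = pair_class(mirna.nt(m), target_seq[t])
            if actual != cls:
                raise ValueError(
                    f"pair at miRNA position {m} labeled {cls} but bases "
                    f"{mirna.nt(m)}:{target_seq[t]} form {actual or 'no pair'}"
                )
    return score_pairs(config.pairs, config.offset, mirna, params)


def build_configuration(
    pairs: Sequence[tuple[int, int, str]],
    mirna: MatureMiRNA,
    params: ScoreParams,
    seed_start: int,
) -> PairingConfiguration:
    """Assemble a full configuration (offset, interruptions, breakdown)
    from an explicit pair list anchored at a seed starting at ``seed_start``.
    """
    pairs = tuple(sorted(pairs))
    if not pairs:
        return empty_configuration()
    m1, t1, _ = pairs[0]
    offset = zero_offset_target_pos(seed_start, m1) - t1
    breakdown = score_pairs(pairs, offset, mirna, params)
    return PairingConfiguration(
        pairs, offset, _interruptions(pairs), breakdown, breakdown.total
    )


def zero_offset_target_pos(seed_start: int, mirna_pos: int) -> int:
    """Target position opposite ``mirna_pos`` when the 3' helix is in
    register with the seed helix (offset 0)."""
    return seed_start + 7 - mirna_pos


def site_window(
    match: SeedMatch, region: TranscriptRegion, params: ScoreParams
) -> tuple[str, int]:
    """The upstream search window ``(sequence, start_coordinate)``.

    The window is the ``params.window`` nucleotides immediately 5' of the
    target nucleotide opposite miRNA position 8; matches near the transcript
    5' end get a truncated window.
    """
    end = max(0, match.seed_start - 1)
    start = max(0, end - params.window)
    return region.sequence[start:end], start


# ---------------------------------------------------------------------------
# Optimal-configuration search


def _pair_gain(m: int, cls: str, length: int, params: ScoreParams) -> float:
    """Per-pair score contribution under per-position end-bonus accounting."""
    if cls == "WCF":
        gain = params.match_point if m > 12 else 0.0
        if m in (length - 1, length - 2):
            gain += params.end_bonus
        return gain
    return params.terminal_wobble_bonus if m == length else 0.0


def _wcf_end_hit(m: int, cls: str, length: int) -> int:
    return 1 if cls == "WCF" and m in (length - 1, length - 2) else 0


def best_configuration(
    mirna: MatureMiRNA,
    match: SeedMatch,
    region: TranscriptRegion,
    params: ScoreParams | None = None,
) -> PairingConfiguration:
    """Maximal-scoring 3'-pairing configuration within the upstream window.

    Dynamic program over pairable (miRNA position, window position) cells;
    the offset penalty attaches to the first pair, interruption penalties to
    transitions between consecutive pairs.  Returns the empty configuration
    (score 0) when nothing scores positively.
    """
    params = params or ScoreParams()
    window, w0 = site_window(match, region, params)
    if not window:
        return empty_configuration()
    length = len(mirna)
    seq = mirna.sequence
    start_p = params.three_prime_start
    once_mode = params.end_bonus_mode == "once"

    cells: list[tuple[int, int, str]] = []  # (p, j, cls)
    for p in range(start_p, length + 1):
        mb = seq[p - 1]
        for j, tb in enumerate(window):
            cls = pair_class(mb, tb)
            if cls is not None:
                cells.append((p, j, cls))
    if not cells:
        return empty_configuration()

    def gain(p: int, cls: str, claimed: bool) -> tuple[float, bool]:
        """Score increment for placing pair (p, cls) given whether an end
        bonus was already claimed (relevant only under end_bonus_mode='once');
        returns (increment, claimed-after)."""
        if cls == "GU":
            return (params.terminal_wobble_bonus if p == length else 0.0), claimed
        g = params.match_point if p > 12 else 0.0
        if p in (length - 1, length - 2):
            if not once_mode:
                g += params.end_bonus
            elif not claimed:
                g += params.end_bonus
                claimed = True
        return g, claimed

    # DP over (cell, end-bonus-claimed) states.  Value is the lexicographic
    # key (score, -|offset|, -events); comparison is exact because all future
    # increments depend only on the last cell and the claimed bit.
    n = len(cells)
    n_states = 2 if once_mode else 1
    best_val: list[list[tuple[float, int, int] | None]] = [
        [None] * n for _ in range(n_states)
    ]
    parent: list[list[tuple[int, int] | None]] = [
        [None] * n for _ in range(n_states)
    ]
    for i, (p, j, cls) in enumerate(cells):
        t_abs = w0 + j
        offset = zero_offset_target_pos(match.seed_start, p) - t_abs
        start_pen = params.offset_point * max(0, abs(offset) - params.offset_free)
        g0, claimed0 = gain(p, cls, False)
        b0 = 1 if (once_mode and claimed0) else 0
        start_val = (g0 - start_pen, -abs(offset), 0)
        if best_val[b0][i] is None or start_val > best_val[b0][i]:
            best_val[b0][i] = start_val
            parent[b0][i] = None
        for k in range(i):
            pp, jj, _pcls = cells[k]
            if pp >= p or jj <= j:
                continue
            mgap, tgap = p - pp - 1, jj - j - 1
            cost = params.interruption_point * max(mgap, tgap) if (mgap or tgap) else 0.0
            event = 1 if (mgap or tgap) else 0
            for b in range(n_states):
                pv = best_val[b][k]
                if pv is None:
                    continue
                g, claimed = gain(p, cls, bool(b))
                b2 = 1 if (once_mode and claimed) else 0
                cand = (pv[0] + g - cost, pv[1], pv[2] - event)
                if best_val[b2][i] is None or cand > best_val[b2][i]:
                    best_val[b2][i] = cand
                    parent[b2][i] = (b, k)

    # Pick the best chain end; prefer 5'-most target start (smaller j).
    best_state = None
    best_key = None
    for i, (p, j, cls) in enumerate(cells):
        for b in range(n_states):
            v = best_val[b][i]
            if v is None:
                continue
            key = (v[0], v[1], v[2], -j)
            if best_key is None or key > best_key:
                best_key, best_state = key, (b, i)

    if best_key is None or best_key[0] <= 0:
        return empty_configuration()

    chain = []
    state = best_state
    while state is not None:
        b, i = state
        p, j, cls = cells[i]
        chain.append((p, w0 + j, cls))
        state = parent[b][i]
    chain.reverse()
    return build_configuration(chain, mirna, params, match.seed_start)


def exhaustive_best(
    mirna: MatureMiRNA,
    match: SeedMatch,
    region: TranscriptRegion,
    params: ScoreParams | None = None,
    max_region: int = 10,
    max_window: int = 14,
) -> PairingConfiguration:
    """Brute-force oracle: enumerate every monotone pairing and take the
    argmax under the same tie-break order as :func:`best_configuration`.

    Guarded to miRNA 3' regions of <= ``max_region`` nt and windows of
    <= ``max_window`` nt; larger instances raise :class:`SizeError`.
    """
    params = params or ScoreParams()
    length = len(mirna)
    region_len = length - params.three_prime_start + 1
    window, w0 = site_window(match, region, params)
    if region_len > max_region or len(window) > max_window:
        raise SizeError(
            f"instance ({region_len} nt x {len(window)} nt) exceeds the "
            f"({max_region}, {max_window}) guard"
        )
    if not window:
        return empty_configuration()
    seq = mirna.sequence
    cells = []
    for p in range(params.three_prime_start, length + 1):
        for j, tb in enumerate(window):
            cls = pair_class(seq[p - 1], tb)
            if cls is not None:
                cells.append((p, j, cls))
    end_positions = (length - 1, length - 2)
    once_mode = params.end_bonus_mode == "once"

    best: dict[str, object] = {"key": (0.0, 0, 0, 0), "chain": None}

    def evaluate(chain, score, offset, events, end_hits):
        if once_mode and end_hits > 1:
            score = score - params.end_bonus * (end_hits - 1)
        key = (score, -abs(offset), -events, -chain[-1][1])
        if key > best["key"]:
            best["key"] = key
            best["chain"] = list(chain)

    def extend(start_idx, chain, score, offset, events, end_hits):
        lp, lj, _ = chain[-1]
        for k in range(start_idx, len(cells)):
            p, j, cls = cells[k]
            if p <= lp or j >= lj:
                continue
            mgap, tgap = p - lp - 1, lj - j - 1
            cost = params.interruption_point * max(mgap, tgap) if (mgap or tgap) else 0.0
            ev = events + (1 if (mgap or tgap) else 0)
            sc = score + _pair_gain(p, cls, length, params) - cost
            eh = end_hits + _wcf_end_hit(p, cls, length)
            chain.append((p, j, cls))
            evaluate(chain, sc, offset, ev, eh)
            extend(k + 1, chain, sc, offset, ev, eh)
            chain.pop()

    for idx, (p, j, cls) in enumerate(cells):
        offset = zero_offset_target_pos(match.seed_start, p) - (w0 + j)
        sc = (_pair_gain(p, cls, length, params)
              - params.offset_point * max(0, abs(offset) - params.offset_free))
        eh = _wcf_end_hit(p, cls, length)
        chain = [(p, j, cls)]
        evaluate(chain, sc, offset, 0, eh)
        extend(idx + 1, chain, sc, offset, 0, eh)

    if best["chain"] is None:
        return empty_configuration()
    chain = [(p, w0 + j, cls) for p, j, cls in best["chain"]]
    return build_configuration(chain, mirna, params, match.seed_start)


# ---------------------------------------------------------------------------
# Diagram rendering


def pairing_string(
    config: PairingConfiguration,
    mirna: MatureMiRNA,
    window: str,
    window_start: int = 0,
    three_prime_start: int = 9,
) -> str:
    """Three-line duplex diagram: target 3'->5' on top, pair symbols in the
    middle ("|" = WCF, ":" = G:U wobble), miRNA 5'->3' on the bottom."""
    top: list[str] = []
    mid: list[str] = []
    bot: list[str] = []
    mi = three_prime_start
    tj = window_start + len(window) - 1  # absolute target coordinate

    def emit_unpaired(next_m: int, next_t: int) -> None:
        nonlocal mi, tj
        while mi < next_m and tj > next_t:
            top.append(window[tj - window_start]); mid.append(" ")
            bot.append(mirna.nt(mi)); mi += 1; tj -= 1
        while mi < next_m:
            top.append("-"); mid.append(" "); bot.append(mirna.nt(mi)); mi += 1
        while tj > next_t:
            top.append(window[tj - window_start]); mid.append(" "); bot.append("-"); tj -= 1

    for m, t, cls in config.pairs:
        emit_unpaired(m, t)
        top.append(window[t - window_start])
        mid.append("|" if cls == "WCF" else ":")
        bot.append(mirna.nt(m))
        mi, tj = m + 1, t - 1
    emit_unpaired(len(mirna) + 1, window_start - 1)
    lines = ("".join(top).rstrip(), "".join(mid).rstrip(), "".join(bot).rstrip())
    return "\n".join(lines)


def pairing_oneline(config: PairingConfiguration) -> str:
    """Compact machine-readable pairing encoding for TSV output:
    comma-joined ``<miRNA pos><|or:><target pos>`` tokens; empty when the
    configuration has no 3' pairs."""
    return ",".join(
        f"{m}{'|' if cls == 'WCF' else ':'}{t}" for m, t, cls in config.pairs
    )
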