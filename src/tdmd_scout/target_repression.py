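"""Repression of predicted miRNA targets versus length-matched nontargets.

Losing a TDMD trigger raises the miRNA, which should depress its predicted
targets.  The analysis compares the log2 fold changes of predicted targets
of a miRNA family against a nontarget cohort sampled 1:1 and matched on
3' UTR length (targets tend to have longer UTRs, and UTR length correlates
with expression change, so unmatched cohorts are confounded).  Repression is
summarized as median(nontarget log2fc) − median(target log2fc) — positive
when targets go down — with a Mann–Whitney U test per iteration, repeated
over freshly sampled nontarget cohorts (default 21 iterations) and reported
as the mean repression and median P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_TPM = 10.0
DEFAULT_TOP_FRACTION = 0.10
DEFAULT_ITERATIONS = 21
EXACT_MAX_N = 8  # exact Mann-Whitney p when min(n, m) <= this and no ties


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    log2fc: float
    mean_tpm: float
    utr3_length: int
    predicted_target_of: frozenset[str] = frozenset()
    contextpp_score: float | None = None

    def __post_init__(self) -> None:
        if self.utr3_length <= 0:
            raise ValueError(f"{self.gene_id}: non-positive 3' UTR length")


@dataclass(frozen=True)
class IterationResult:
    iteration: int
    repression: float
    p_value: float
    nontarget_ids: tuple[str, ...]


@dataclass(frozen=True)
class RepressionReport:
    target_set: str  # {"all", "top"}
    iterations: tuple[IterationResult, ...]
    n_targets: int
    n_nontargets: int

    @property
    def mean_repression(self) -> float:
        return float(np.mean([it.repression for it in self.iterations]))

    @property
    def sd_repression(self) -> float | None:
        if len(self.iterations) < 2:
            return None
        return float(np.std([it.repression for it in self.iterations], ddof=1))

    @property
    def median_p(self) -> float:
        return float(np.median([it.p_value for it in self.iterations]))

    @property
    def representative_iteration(self) -> IterationResult:
        """The iteration whose P value is closest to the median P (used for
        the representative cumulative-distribution plot)."""
        med = self.median_p
        return min(self.iterations, key=lambda it: (abs(it.p_value - med), it.iteration))


def filter_expressed(
    genes: Sequence[GeneRecord], min_tpm: float = DEFAULT_MIN_TPM
) -> list[GeneRecord]:
    """Drop genes whose mean TPM across samples is below ``min_tpm``."""
    return [g for g in genes if g.mean_tpm >= min_tpm]


def top_targets(
    targets: Sequence[GeneRecord], fraction: float = DEFAULT_TOP_FRACTION
) -> list[GeneRecord]:
    """The ceil(fraction*n) targets with the lowest (most repressive)
    cumulative weighted context++ scores; boundary ties break by gene_id."""
    missing = [g.gene_id for g in targets if g.contextpp_score is None]
    if missing:
        raise ValueError(f"targets lacking context++ scores: {missing}")
    k = math.ceil(fraction * len(targets))
    ordered = sorted(targets, key=lambda g: (g.contextpp_score, g.gene_id))
    return ordered[:k]


def sample_matched_nontargets(
    targets: Sequence[GeneRecord],
    nontarget_pool: Sequence[GeneRecord],
    rng: np.random.Generator | int,
) -> list[GeneRecord]:
    """One nontarget per target, matched on log10 3' UTR length.

    Greedy nearest-neighbor without replacement; targets are visited in a
    seeded random order so the sample varies across seeds while the matched
    length distribution holds for all of them.
    """
    if len(nontarget_pool) < len(targets):
        raise ValueError(
            f"nontarget pool ({len(nontarget_pool)}) smaller than target "
            f"set ({len(targets)})"
        )
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    pool = sorted(nontarget_pool, key=lambda g: (g.utr3_length, g.gene_id))
    pool_logs = [math.log10(g.utr3_length) for g in pool]
    available = [True] * len(pool)
    order = rng.permutation(len(targets))
    chosen: list[GeneRecord | None] = [None] * len(targets)
    import bisect

    for idx in order:
        tlog = math.log10(targets[idx].utr3_length)
        i = bisect.bisect_left(pool_logs, tlog)
        best_j, best_d = None, None
        lo, hi = i - 1, i
        while True:
            cand = []
            while lo >= 0 and not available[lo]:
                lo -= 1
            while hi < len(pool) and not available[hi]:
                hi += 1
            if lo >= 0:
                cand.append(lo)
            if hi < len(pool):
                cand.append(hi)
            if not cand:
                break
            best_j = min(cand, key=lambda j: (abs(pool_logs[j] - tlog), j))
            break
        if best_j is None:
            raise ValueError("nontarget pool exhausted")
        available[best_j] = False
        chosen[idx] = pool[best_j]
    return [g for g in chosen if g is not None]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (midranks for ties).

    Exact p by enumeration when min(n, m) <= 8 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if min(x.size, y.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def run_repression(
    genes: Sequence[GeneRecord],
    mirna_family: str,
    iterations: int = DEFAULT_ITERATIONS,
    rng_seed: int = 0,
    min_tpm: float = DEFAULT_MIN_TPM,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    min_targets: int = 5,
) -> dict[str, RepressionReport]:
    """Matched-nontarget repression analysis for one miRNA family.

    Returns one report per target set ("all" and "top").  The nontarget
    pool excludes predicted targets of this family only.  All randomness
    derives from ``rng_seed``; per-iteration sub-streams are spawned
    deterministically.
    """
    expressed = filter_expressed(genes, min_tpm)
    targets_all = [g for g in expressed if mirna_family in g.predicted_target_of]
    pool = [g for g in expressed if mirna_family not in g.predicted_target_of]
    if len(targets_all) < min_targets:
        raise ValueError(
            f"only {len(targets_all)} expressed predicted targets of "
            f"{mirna_family!r} (need >= {min_targets})"
        )
    sets = {"all": targets_all, "top": top_targets(targets_all, top_fraction)}
    seed_seq = np.random.SeedSequence(rng_seed)
    streams = seed_seq.spawn(iterations)
    reports: dict[str, RepressionReport] = {}
    for set_name, targets in sets.items():
        rows = []
        t_vals = np.array([g.log2fc for g in targets])
        for it in range(iterations):
            rng = np.random.default_rng(streams[it].spawn(1)[0]
                                        if set_name == "top" else streams[it])
            sample = sample_matched_nontargets(targets, pool, rng)
            nt_vals = np.array([g.log2fc for g in sample])
            repression = float(np.median(nt_vals) - np.median(t_vals))
            _u, p = mann_whitney_u(t_vals, nt_vals)
            rows.append(IterationResult(
                iteration=it + 1,
                repression=repression,
                p_value=p,
                nontarget_ids=tuple(g.gene_id for g in sample),
            ))
        reports[set_name] = RepressionReport(
            target_set=set_name,
            iterations=tuple(rows),
            n_targets=len(targets),
            n_nontargets=len(targets),
        )
    return reports


def report_frame(reports: dict[str, RepressionReport]) -> pd.DataFrame:
    """Per-iteration tidy table across target sets."""
    rows = []
    for set_name, rep in reports.items():
        for it in rep.iterations:
            rows.append({
                "target_set": set_name,
                "iteration": it.iteration,
                "repression": it.repression,
                "p_value": it.p_value,
            })
    return pd.DataFrame(rows, columns=["target_set", "iteration",
                                       "repression", "p_value"])


def summary_frame(reports: dict[str, RepressionReport]) -> pd.DataFrame:
    rows = []
    for set_name, rep in reports.items():
        rows.append({
            "target_set": set_name,
            "n_targets": rep.n_targets,
            "n_nontargets": rep.n_nontargets,
            "iterations": len(rep.iterations),
            "mean_repression": rep.mean_repression,
            "sd_repression": rep.sd_repression,
            "median_p": rep.median_p,
        })
    return pd.DataFrame(rows)
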