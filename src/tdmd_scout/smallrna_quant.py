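"""Small-RNA quantification and cluster normalization.

Reads are assigned to miRNAs by exact identity of their first 19 nt against
a dictionary of mature sequences (no mismatches); spike-in reads are tallied
separately and excluded from depth normalization.  Counts are expressed as
cpm (counts per million miRNA-assigned reads).  To isolate degradation
effects from transcription/processing variability, a miRNA's cpm is
normalized to the geometric mean of co-transcribed partners (a single
partner reduces to a simple ratio), and fold changes are expressed relative
to the mean normalized value of the control group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import MatureMiRNA

DEFAULT_PREFIX_LEN = 19

UNASSIGNED = "__unassigned__"
SPIKEIN = "__spikein__"


@dataclass(frozen=True)
class PrefixIndex:
    """Exact-prefix dictionary: prefix -> assignment group.

    miRNAs sharing a prefix are merged into one ambiguous group whose id is
    the "+"-join of the sorted member ids (no fractional splitting).
    """

    prefix_len: int
    entries: Mapping[str, str]          # prefix -> group id
    groups: Mapping[str, tuple[str, ...]]  # group id -> member mirna_ids
    spikein_prefixes: Mapping[str, str]    # prefix -> spike-in id

    @property
    def ambiguous_groups(self) -> list[str]:
        return [g for g, members in self.groups.items() if len(members) > 1]

    def group_of(self, mirna_id: str) -> str:
        for group, members in self.groups.items():
            if mirna_id in members:
                return group
        raise KeyError(mirna_id)


def build_prefix_index(
    mirnas: Sequence[MatureMiRNA],
    spikeins: Sequence[MatureMiRNA] = (),
    prefix_len: int = DEFAULT_PREFIX_LEN,
) -> PrefixIndex:
    """Build the read-assignment dictionary from mature sequences."""
    short = [m.mirna_id for m in list(mirnas) + list(spikeins)
             if len(m.sequence) < prefix_len]
    if short:
        raise ValueError(
            f"sequence(s) shorter than prefix length {prefix_len}: {short}"
        )
    by_prefix: dict[str, list[str]] = {}
    for m in mirnas:
        by_prefix.setdefault(m.sequence[:prefix_len], []).append(m.mirna_id)
    entries: dict[str, str] = {}
    groups: dict[str, tuple[str, ...]] = {}
    for prefix, ids in by_prefix.items():
        members = tuple(sorted(ids))
        group_id = "+".join(members)
        entries[prefix] = group_id
        groups[group_id] = members
    spike_prefixes = {s.sequence[:prefix_len]: s.mirna_id for s in spikeins}
    return PrefixIndex(prefix_len, entries, groups, spike_prefixes)


def assign_reads(
    reads: Iterable[str], index: PrefixIndex
) -> dict[str, int]:
    """Count reads per assignment group by the exact-prefix rule.

    A read whose first ``prefix_len`` nt equal a dictionary prefix
    increments that group regardless of what follows; any mismatch within
    the prefix, or a read shorter than the prefix, leaves it unassigned.
    Spike-in matches are tallied under ``SPIKEIN`` and excluded from miRNA
    totals.  The returned mapping conserves reads:
    sum(assigned) + counts[UNASSIGNED] + counts[SPIKEIN] == n input reads.
    """
    counts: dict[str, int] = {UNASSIGNED: 0, SPIKEIN: 0}
    plen = index.prefix_len
    entries = index.entries
    spikes = index.spikein_prefixes
    for read in reads:
        if len(read) < plen:
            counts[UNASSIGNED] += 1
            continue
        prefix = read[:plen]
        group = entries.get(prefix)
        if group is not None:
            counts[group] = counts.get(group, 0) + 1
        elif prefix in spikes:
            counts[SPIKEIN] += 1
        else:
            counts[UNASSIGNED] += 1
    return counts


def counts_to_cpm(counts: Mapping[str, int]) -> dict[str, float]:
    """Counts per million miRNA-assigned reads (spike-ins and unassigned
    reads excluded from the denominator)."""
    total = sum(c for g, c in counts.items() if g not in (UNASSIGNED, SPIKEIN))
    if total == 0:
        return {}
    return {
        g: 1e6 * c / total
        for g, c in counts.items()
        if g not in (UNASSIGNED, SPIKEIN)
    }


def quantify_samples(
    sample_reads: Mapping[str, Iterable[str]], index: PrefixIndex
) -> pd.DataFrame:
    """Tidy per-(sample, group) table with raw counts and cpm."""
    rows = []
    for sample in sorted(sample_reads):
        counts = assign_reads(sample_reads[sample], index)
        cpm = counts_to_cpm(counts)
        for group in sorted(counts):
            rows.append({
                "sample_id": sample,
                "group": group,
                "count": counts[group],
                "cpm": cpm.get(group, float("nan")),
            })
    return pd.DataFrame(rows, columns=["sample_id", "group", "count", "cpm"])


@dataclass(frozen=True)
class NormalizedFoldChange:
    mirna_id: str
    sample_id: str
    ratio: float | None   # None when a partner cpm is 0 in that sample
    fold_change: float | None


def cluster_normalize(
    table: pd.DataFrame,
    mirna_id: str,
    partners: Sequence[str],
    control_samples: Sequence[str],
) -> list[NormalizedFoldChange]:
    """Partner-normalized fold change per sample.

    ratio = cpm(miRNA) / geometric mean of partner cpms; fold_change =
    ratio / mean(ratio over control samples).  Samples where any partner cpm
    is zero get an undefined ratio and are excluded from the control mean.
    """
    if not partners:
        raise ValueError("partners must be non-empty")
    cpm = table.pivot_table(index="group", columns="sample_id", values="cpm")
    for name in [mirna_id, *partners]:
        if name not in cpm.index:
            raise KeyError(f"{name!r} absent from the count table")
    samples = list(cpm.columns)
    ratios: dict[str, float | None] = {}
    for sample in samples:
        partner_vals = [cpm.at[p, sample] for p in partners]
        if any(v == 0 or math.isnan(v) for v in partner_vals):
            ratios[sample] = None
            continue
        geo = math.exp(sum(math.log(v) for v in partner_vals) / len(partner_vals))
        ratios[sample] = cpm.at[mirna_id, sample] / geo
    control_vals = [ratios[s] for s in control_samples if ratios.get(s) is not None]
    if not control_vals:
        raise ValueError("no control sample has a defined ratio")
    control_mean = sum(control_vals) / len(control_vals)
    out = []
    for sample in samples:
        r = ratios[sample]
        out.append(
            NormalizedFoldChange(
                mirna_id=mirna_id,
                sample_id=sample,
                ratio=r,
                fold_change=None if r is None else r / control_mean,
            )
        )
    return out


def call_sensitive(
    de_table: pd.DataFrame,
    alpha: float = 0.05,
    min_log2fc: float = 0.0,
) -> list[str]:
    """miRNAs significantly upregulated on loss of the degradation pathway
    (padj <= alpha and log2fc >= min_log2fc; rows lacking padj are skipped)."""
    called = []
    for row in de_table.itertuples(index=False):
        padj = getattr(row, "padj", None)
        if padj is None or (isinstance(padj, float) and math.isnan(padj)):
            continue
        if padj <= alpha and row.log2fc >= min_log2fc:
            called.append(row.mirna_id)
    return sorted(called)
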