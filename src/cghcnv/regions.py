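"""CNV region (CNVR) aggregation across samples and summary statistics.

CNVRs are the connected components of the call-overlap graph: calls from all
samples that share at least one base are chained transitively (A overlaps B
and B overlaps C puts A, B, C in one region even if A and C are disjoint),
and each region's span is the union of its members. Overlap requires >= 1
shared base on the 1-based inclusive scale, so bookended calls
(end + 1 == start) do NOT merge. A region's state is gain, loss, or both
according to its members' states, and its sample frequency counts distinct
contributing samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CNVCall
from .synthetic import GenomeDef

__all__ = ["CNVR", "CnvrSummary", "merge_calls_to_cnvrs", "summarize_cnvrs", "cross_tabulate_by_group", "cnvrs_to_frame"]


@dataclass(frozen=True)
class CNVR:
    chrom: str
    start_bp: int
    end_bp: int
    state: str  # "gain" | "loss" | "both"
    member_calls: tuple[CNVCall, ...]
    n_samples: int

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class CnvrSummary:
    n_cnvrs: int
    n_gain: int
    n_loss: int
    n_both: int
    total_length_bp: int
    mean_length_bp: float
    median_length_bp: float
    min_length_bp: int
    max_length_bp: int
    pct_genome: float
    n_singleton: int


def merge_calls_to_cnvrs(calls: list[CNVCall]) -> list[CNVR]:
    """Chain overlapping calls from all samples into non-overlapping CNVRs.

    On intervals, transitive chaining reduces to a single sorted sweep per
    chromosome: sort by start, extend the open region while the next call
    starts at or before the current union end, emit when a gap appears.
    """
    out: list[CNVR] = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        if c.start_bp > c.end_bp:
            raise ValueError(f"invalid call coordinates [{c.start_bp},{c.end_bp}]")
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in by_chrom:
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start_bp, c.end_bp))
        cluster: list[CNVCall] = []
        end = -1
        for c in chrom_calls:
            if cluster and c.start_bp > end:
                out.append(_make_cnvr(chrom, cluster))
                cluster = []
                end = -1
            cluster.append(c)
            end = max(end, c.end_bp)
        if cluster:
            out.append(_make_cnvr(chrom, cluster))
    out.sort(key=lambda r: (r.chrom, r.start_bp))
    return out


def _make_cnvr(chrom: str, members: list[CNVCall]) -> CNVR:
    states = {m.state for m in members}
    state = "both" if len(states) > 1 else states.pop()
    return CNVR(
        chrom=chrom,
        start_bp=min(m.start_bp for m in members),
        end_bp=max(m.end_bp for m in members),
        state=state,
        member_calls=tuple(members),
        n_samples=len({m.sample_id for m in members}),
    )


def summarize_cnvrs(cnvrs: list[CNVR], genome: GenomeDef) -> CnvrSummary:
    """Count/length statistics over a CNVR set (lengths are end - start + 1)."""
    if not cnvrs:
        return CnvrSummary(0, 0, 0, 0, 0, float("nan"), float("nan"), 0, 0, 0.0, 0)
    lengths = np.array([r.length for r in cnvrs], dtype=np.int64)
    total = int(lengths.sum())
    return CnvrSummary(
        n_cnvrs=len(cnvrs),
        n_gain=sum(r.state == "gain" for r in cnvrs),
        n_loss=sum(r.state == "loss" for r in cnvrs),
        n_both=sum(r.state == "both" for r in cnvrs),
        total_length_bp=total,
        mean_length_bp=float(lengths.mean()),
        median_length_bp=float(np.median(lengths)),
        min_length_bp=int(lengths.min()),
        max_length_bp=int(lengths.max()),
        pct_genome=100.0 * total / genome.total_length,
        n_singleton=sum(r.n_samples == 1 for r in cnvrs),
    )


def cross_tabulate_by_group(
    calls: list[CNVCall],
    sample_to_group: dict[str, str],
    cnvrs: list[CNVR] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-group call counts and, if CNVRs are given, a group presence matrix.

    Every sample must map to exactly one group; groups with zero calls are
    retained as zero rows so the counts always partition the total.
    """
    unmapped = {c.sample_id for c in calls} - set(sample_to_group)
    if unmapped:
        raise KeyError(f"samples without a group: {sorted(unmapped)}")
    groups = list(dict.fromkeys(sample_to_group.values()))
    counts = pd.Series(0, index=pd.Index(groups, name="group"), dtype=int, name="n_calls")
    for c in calls:
        counts[sample_to_group[c.sample_id]] += 1
    if cnvrs is None:
        presence = pd.DataFrame(columns=groups)
    else:
        rows = []
        for r in cnvrs:
            member_groups = {sample_to_group[m.sample_id] for m in r.member_calls}
            rows.append([g in member_groups for g in groups])
        presence = pd.DataFrame(
            rows,
            columns=groups,
            index=[f"{r.chrom}:{r.start_bp}-{r.end_bp}" for r in cnvrs],
        )
    return counts, presence


def cnvrs_to_frame(cnvrs: list[CNVR]) -> pd.DataFrame:
    """Tabulate CNVRs (1-based inclusive start/end) with ids CNVR00001..."""
    return pd.DataFrame(
        [
            (r.chrom, r.start_bp, r.end_bp, f"CNVR{i + 1:05d}", r.state, r.n_samples)
            for i, r in enumerate(cnvrs)
        ],
        columns=["chrom", "start", "end", "id", "state", "n_samples"],
    )


def format_summary_report(summary: CnvrSummary, label: str = "this run") -> str:
    """Human-readable report with the usual survey columns: count, range,
    median, mean, total length, percent of genome, singleton count."""
    if summary.n_cnvrs == 0:
        return f"CNVR summary ({label}): no regions (mean/median undefined)\n"
    kb = 1e3
    mb = 1e6
    return (
        f"CNVR summary ({label})\n"
        f"  count          : {summary.n_cnvrs} "
        f"(gain {summary.n_gain}, loss {summary.n_loss}, both {summary.n_both})\n"
        f"  range (kb)     : {summary.min_length_bp / kb:.2f} - {summary.max_length_bp / kb:.2f}\n"
        f"  median (kb)    : {summary.median_length_bp / kb:.1f}\n"
        f"  mean (kb)      : {summary.mean_length_bp / kb:.1f}\n"
        f"  total (Mb)     : {summary.total_length_bp / mb:.2f}\n"
        f"  % of genome    : {summary.pct_genome:.2f}\n"
        f"  singletons     : {summary.n_singleton}\n"
    )
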