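"""High-confidence CNV calling from segmented log2-ratio profiles.

The calling rule is the published high-confidence filter: a segment is a
candidate CNV iff it spans five or more probes AND its mean log2 ratio shifts
from baseline by strictly more than +/- 0.3 ("greater than" is taken
literally, so a mean of exactly 0.3 is not called). Baseline is 0 on the
median-centered scale. Probes on uncertain chromosomal loci (the assembly's
random/unplaced contigs, the E22C19W28_E50C23 and E64 linkage groups, and the
W chromosome) are removed before analysis.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import Segment
from .synthetic import ProbeLayout

__all__ = ["CallingParameters", "CNVCall", "DEFAULT_EXCLUDED_PATTERNS", "filter_probes", "call_cnvs", "calls_to_frame"]

#: chromosome-name patterns removed before calling (fnmatch syntax,
#: case-insensitive): random/unplaced contigs, the two uncertain linkage
#: groups, and the W sex chromosome.
DEFAULT_EXCLUDED_PATTERNS = (
    "chr*_random",
    "chrUn*",
    "chrE22C19W28_E50C23",
    "chrE64",
    "chrW",
)


@dataclass(frozen=True)
class CallingParameters:
    min_probes: int = 5
    log2_threshold: float = 0.3
    excluded_chrom_patterns: tuple[str, ...] = DEFAULT_EXCLUDED_PATTERNS

    def __post_init__(self):
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.log2_threshold <= 0:
            raise ValueError("log2_threshold must be > 0")


@dataclass(frozen=True)
class CNVCall:
    """One sample's filtered variant segment, 1-based inclusive coordinates."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_probes: int
    mean_log2: float
    state: str  # "gain" | "loss"

    def __post_init__(self):
        if self.state not in ("gain", "loss"):
            raise ValueError("state must be 'gain' or 'loss'")

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


def filter_probes(layout: ProbeLayout, params: CallingParameters) -> ProbeLayout:
    """Drop probes whose chromosome matches any excluded pattern; keep order."""
    if not params.excluded_chrom_patterns:
        return layout
    keep = ~layout.probes["chrom"].map(
        lambda c: any(
            fnmatch.fnmatch(c.lower(), pat.lower()) for pat in params.excluded_chrom_patterns
        )
    )
    return ProbeLayout(layout.probes[keep.to_numpy()].reset_index(drop=True))


def call_cnvs(
    segments: list[Segment], params: CallingParameters, sample_id: str
) -> list[CNVCall]:
    """Apply the >= min_probes AND |mean| > threshold filter to one sample."""
    calls = []
    for seg in segments:
        if seg.n_probes >= params.min_probes and abs(seg.mean_log2) > params.log2_threshold:
            calls.append(
                CNVCall(
                    sample_id=sample_id,
                    chrom=seg.chrom,
                    start_bp=seg.start_bp,
                    end_bp=seg.end_bp,
                    n_probes=seg.n_probes,
                    mean_log2=seg.mean_log2,
                    state="gain" if seg.mean_log2 > 0 else "loss",
                )
            )
    return calls


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    """Tabulate calls (1-based inclusive start/end)."""
    return pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.start_bp, c.end_bp, c.n_probes, c.mean_log2, c.state)
            for c in calls
        ],
        columns=["sample_id", "chrom", "start", "end", "n_probes", "mean_log2", "state"],
    )
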