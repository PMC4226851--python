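"""Probe liftover, interval overlap annotation, and local term enrichment.

Interval frames throughout are pandas DataFrames with columns
``chrom, start, end, id`` on the package's internal 1-based inclusive scale
(BED readers in :mod:`cghcnv.io` convert on the way in). The overlap standard
is the field's minimal one: two intervals on the same chromosome overlap iff
they share at least one base, so [100, 200] and [200, 300] overlap by 1 bp.

Term enrichment replaces a web-service lookup with the standard one-sided
hypergeometric upper-tail test per term plus Benjamini-Hochberg adjustment,
computed locally from a user-supplied gene->term map; the EASE-style variant
(decrement the observed count by one before taking the tail) is available as
a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .synthetic import ProbeLayout

__all__ = [
    "LiftoverMap",
    "OverlapReport",
    "remap_probes",
    "intersect_regions",
    "annotate_genes",
    "filter_qtls_by_ci",
    "enrich_terms",
    "normalize_chrom",
]

logger = logging.getLogger(__name__)

#: maximum QTL confidence-interval width retained by the CI filter (strict <).
MAX_QTL_CI_BP = 10_000_000


def normalize_chrom(name: str, add_prefix: bool = True) -> str:
    """Exact-text chromosome matching after optional 'chr' prefix normalization."""
    if add_prefix and not name.lower().startswith("chr"):
        return "chr" + name
    return name


# ---------------------------------------------------------------------------
# liftover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiftoverMap:
    """Table-driven probe_id -> (new_chrom, new_position) assembly conversion.

    Probes absent from the table are unmapped (they fail to convert to the
    new assembly and are dropped from remapped layouts).
    """

    entries: dict[str, tuple[str, int]]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LiftoverMap":
        if frame["probe_id"].duplicated().any():
            raise ValueError("liftover map has duplicate probe_ids")
        return cls(
            {
                r.probe_id: (r.chrom, int(r.position))
                for r in frame.itertuples(index=False)
            }
        )


def remap_probes(layout: ProbeLayout, lift: LiftoverMap) -> tuple[ProbeLayout, int]:
    """Carry mapped probes to their new coordinates; drop and count the rest.

    Two probes landing on the identical new position keep the first (in input
    order) and warn. Re-calling CNVs on the remapped layout is the caller's
    job. Returns (remapped layout, number of probes dropped as unmapped).
    """
    rows = []
    dropped = 0
    for r in layout.probes.itertuples(index=False):
        hit = lift.entries.get(r.probe_id)
        if hit is None:
            dropped += 1
        else:
            rows.append((r.probe_id, hit[0], hit[1]))
    frame = pd.DataFrame(rows, columns=["probe_id", "chrom", "position"])
    dup = frame.duplicated(subset=["chrom", "position"], keep="first")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} probes mapped to an already-occupied position; keeping first",
            stacklevel=2,
        )
        frame = frame[~dup]
    frame = frame.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)
    return ProbeLayout(frame), dropped


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapReport:
    """All query-subject interval pairs overlapping by >= min_overlap_bp."""

    pairs: pd.DataFrame  # query_id, subject_id, overlap_bp
    n_query: int
    n_query_overlapped: int
    pct_query_overlapped: float
    total_overlap_bp: int


def _overlap_pairs(query: pd.DataFrame, subject: pd.DataFrame, min_overlap_bp: int):
    pairs = []
    subj_by_chrom = dict(tuple(subject.groupby("chrom", sort=False)))
    for chrom, qgrp in query.groupby("chrom", sort=False):
        sgrp = subj_by_chrom.get(chrom)
        if sgrp is None or sgrp.empty:
            continue
        qs = qgrp["start"].to_numpy()[:, None]
        qe = qgrp["end"].to_numpy()[:, None]
        ss = sgrp["start"].to_numpy()[None, :]
        se = sgrp["end"].to_numpy()[None, :]
        ov = np.minimum(qe, se) - np.maximum(qs, ss) + 1
        qi, si = np.nonzero(ov >= min_overlap_bp)
        qid = qgrp["id"].to_numpy()
        sid = sgrp["id"].to_numpy()
        for a, b in zip(qi, si):
            pairs.append((qid[a], sid[b], int(ov[a, b])))
    return pairs


def intersect_regions(
    query: pd.DataFrame, subject: pd.DataFrame, min_overlap_bp: int = 1
) -> OverlapReport:
    """Report every query-subject pair sharing >= min_overlap_bp bases.

    A query overlapping two subjects yields two pairs but counts once in
    ``n_query_overlapped``; the reported percentage's denominator is the
    number of query regions.
    """
    for frame, label in ((query, "query"), (subject, "subject")):
        if len(frame) and (frame["start"] > frame["end"]).any():
            raise ValueError(f"invalid {label} intervals (start > end)")
    pairs = _overlap_pairs(query, subject, min_overlap_bp)
    frame = pd.DataFrame(pairs, columns=["query_id", "subject_id", "overlap_bp"])
    n_hit = frame["query_id"].nunique()
    return OverlapReport(
        pairs=frame,
        n_query=len(query),
        n_query_overlapped=int(n_hit),
        pct_query_overlapped=100.0 * n_hit / len(query) if len(query) else 0.0,
        total_overlap_bp=int(frame["overlap_bp"].sum()) if len(frame) else 0,
    )


def annotate_genes(cnvrs: pd.DataFrame, genes: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-CNVR gene lists flagged complete (gene inside CNVR) or partial.

    A gene is *complete* iff its whole span lies within the CNVR, *partial*
    iff it shares >= 1 bp but extends outside. A gene overlapping two CNVRs
    appears in both rows but counts once in the global distinct-gene count.
    Returns (pair table with columns cnvr_id, gene_id, overlap_bp, mode;
    distinct gene count).
    """
    report = intersect_regions(cnvrs, genes, min_overlap_bp=1)
    if report.pairs.empty:
        out = report.pairs.assign(mode=pd.Series(dtype=str))
        out.columns = ["cnvr_id", "gene_id", "overlap_bp", "mode"]
        return out, 0
    gene_len = genes.set_index("id").assign(length=lambda d: d["end"] - d["start"] + 1)["length"]
    pairs = report.pairs.rename(columns={"query_id": "cnvr_id", "subject_id": "gene_id"})
    pairs["mode"] = np.where(
        pairs["overlap_bp"].to_numpy() == gene_len.loc[pairs["gene_id"]].to_numpy(),
        "complete",
        "partial",
    )
    return pairs, int(pairs["gene_id"].nunique())


def filter_qtls_by_ci(qtls: pd.DataFrame, max_ci_bp: int = MAX_QTL_CI_BP) -> pd.DataFrame:
    """Retain QTLs whose confidence-interval width is strictly below the bound.

    QTLs with a missing CI width are excluded with a warning — a QTL whose
    localization is unknown cannot pass a localization filter.
    """
    if "ci_bp" not in qtls.columns:
        raise KeyError("QTL frame must carry a 'ci_bp' confidence-interval width column")
    missing = qtls["ci_bp"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} QTLs lack a CI width and were excluded", stacklevel=2
        )
    keep = (~missing) & (qtls["ci_bp"] < max_ci_bp)
    return qtls[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------

def enrich_terms(
    gene_set: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    ease: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term, BH-adjusted.

    For a term annotating K of the N background genes with k hits in the
    n-gene query set, p = P[X >= k] for X ~ Hypergeom(N, K, n). ``ease=True``
    applies the EASE-score convention (tail at k - 1), a conservative variant
    popularized by DAVID. Terms with k = 0 are omitted. Columns: term, k, n,
    K, N, p_value, adjusted_p.
    """
    if not background:
        raise ValueError("background gene set is empty")
    extra = gene_set - background
    if extra:
        raise ValueError(f"gene_set not contained in background: {sorted(extra)[:5]}")
    N = len(background)
    n = len(gene_set)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & background
        K = len(members)
        k = len(members & gene_set)
        if k == 0:
            continue
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_value"])
    if len(result):
        result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
    return result
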