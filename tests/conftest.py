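import numpy as np
import pandas as pd
import pytest

from cghcnv import GenomeDef, ProbeLayout, generate_probe_layout


@pytest.fixture
def small_genome():
    return GenomeDef((("chr1", 1_000_000), ("chr2", 500_000)))


@pytest.fixture
def small_layout(small_genome):
    return generate_probe_layout(small_genome, 600, seed=11)


@pytest.fixture
def grid_layout():
    """Deterministic 100-probe layout on one chromosome, every 1000 bp."""
    frame = pd.DataFrame(
        {
            "probe_id": [f"P{i:03d}" for i in range(100)],
            "chrom": "chr1",
            "position": np.arange(100) * 1000 + 500,
        }
    )
    return ProbeLayout(frame)


def bitmap_union_length(intervals, size):
    """Per-base oracle: total covered bases of 1-based inclusive intervals."""
    bitmap = np.zeros(size + 2, dtype=bool)
    for start, end in intervals:
        bitmap[start : end + 1] = True
    return int(bitmap.sum())


def bitmap_overlap_pairs(query, subject, min_overlap=1, size=100_000):
    """Per-base oracle for interval intersection on one chromosome.

    query/subject: list of (id, start, end). Returns {(qid, sid): overlap_bp}.
    """
    out = {}
    for qid, qs, qe in query:
        qmap = np.zeros(size + 2, dtype=bool)
        qmap[qs : qe + 1] = True
        for sid, ss, se in subject:
            smap = np.zeros(size + 2, dtype=bool)
            smap[ss : se + 1] = True
            ov = int((qmap & smap).sum())
            if ov >= min_overlap:
                out[(qid, sid)] = ov
    return out
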