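"""File formats and coordinate-convention conversion.

Internally every interval is 1-based inclusive; BED files on disk are 0-based
half-open, so internal [100, 200] is written as BED (99, 200) and BED (0, 1)
reads back as internal [1, 1] (lengths are preserved: BED end - start equals
inclusive end - start + 1). All writers prepend '#' header lines naming the
tool version, a config hash, and the seed, so any output can be traced to the
run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import CNVCall
from .regions import CNVR
from .segmentation import Segment
from .synthetic import ProbeLayout

__all__ = [
    "run_header",
    "config_hash",
    "write_bed",
    "read_bed",
    "convert_coordinates",
    "write_profile",
    "read_profile_frame",
    "write_layout_bed",
    "write_segments",
    "write_calls_bed",
    "write_calls_vcf",
    "write_cnvrs_bed",
    "read_liftover_map",
]


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_header(seed: int | None = None, cfg_hash: str = "none") -> list[str]:
    lines = [f"# cghcnv {__version__}", f"# config_hash={cfg_hash}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def _write_table(path, frame: pd.DataFrame, header_lines: list[str], sep="\t", columns_line=True):
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        if columns_line:
            fh.write("# columns: " + sep.join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep=sep, header=False, index=False)


def write_bed(path, frame: pd.DataFrame, header_lines: list[str] = ()):
    """Write an internal 1-based inclusive interval frame as BED.

    The frame must start with columns chrom, start, end; extra columns pass
    through as BED columns 4+.
    """
    out = frame.copy()
    out["start"] = out["start"] - 1
    _write_table(path, out, list(header_lines))


def read_bed(path, extra_names: list[str] = ()) -> pd.DataFrame:
    """Read BED into the internal 1-based inclusive convention.

    ``extra_names`` names columns 4+ (e.g. ["id"] or ["id", "ci_bp"]).
    Negative or inverted coordinates raise with the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid BED interval ({start}, {end})")
            rows.append([chrom, start + 1, end] + parts[3 : 3 + len(extra_names)])
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"] + list(extra_names))
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    if "ci_bp" in frame.columns:
        frame["ci_bp"] = pd.to_numeric(frame["ci_bp"], errors="coerce")
    return frame


def convert_coordinates(in_path, out_path, direction: str):
    """Convert a tab-delimited interval file between conventions.

    ``to_bed``: columns chrom, start, end (1-based inclusive) -> BED.
    ``from_bed``: BED -> 1-based inclusive. Round-tripping is the identity.
    Malformed, negative, or inverted intervals raise with the line number.
    """
    if direction not in ("to_bed", "from_bed"):
        raise ValueError("direction must be 'to_bed' or 'from_bed'")
    with open(in_path) as fh, open(out_path, "w") as out:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                out.write(line)
                continue
            parts = stripped.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{in_path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{in_path}:{lineno}: non-integer coordinates") from exc
            if direction == "to_bed":
                if start < 1 or end < start:
                    raise ValueError(f"{in_path}:{lineno}: invalid interval [{start}, {end}]")
                parts[1], parts[2] = str(start - 1), str(end)
            else:
                if start < 0 or end <= start:
                    raise ValueError(f"{in_path}:{lineno}: invalid BED interval ({start}, {end})")
                parts[1], parts[2] = str(start + 1), str(end)
            out.write("\t".join(parts) + "\n")


def write_profile(path, profile, header_lines: list[str] = ()):
    _write_table(path, profile.to_frame(), list(header_lines))


def read_profile_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", comment="#", names=["probe_id", "chrom", "position", "log2_ratio"]
    )
    return frame


def write_layout_bed(path, layout: ProbeLayout, header_lines: list[str] = ()):
    """Probe layout as BED of single-base intervals with probe_id in column 4."""
    frame = pd.DataFrame(
        {
            "chrom": layout.probes["chrom"],
            "start": layout.probes["position"],
            "end": layout.probes["position"],
            "id": layout.probes["probe_id"],
        }
    )
    write_bed(path, frame, header_lines)


def write_segments(path, segments: list[Segment], sample_id: str, header_lines: list[str] = ()):
    frame = pd.DataFrame(
        [
            (sample_id, s.chrom, s.start_bp, s.end_bp, s.n_probes, s.mean_log2)
            for s in segments
        ],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_probes", "mean_log2"],
    )
    _write_table(path, frame, list(header_lines))


def write_calls_bed(path, calls: list[CNVCall], header_lines: list[str] = ()):
    frame = pd.DataFrame(
        [
            (c.chrom, c.start_bp, c.end_bp, f"{c.sample_id}|{c.state}", f"{c.mean_log2:.4f}", c.n_probes)
            for c in calls
        ],
        columns=["chrom", "start", "end", "name", "score", "n_probes"],
    )
    write_bed(path, frame, header_lines)


def write_calls_vcf(path, calls: list[CNVCall], header_lines: list[str] = ()):
    """Minimal structural-variant VCF: one DUP/DEL record per call."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cghcnv-{__version__}\n")
        for line in header_lines:
            fh.write("##comment=" + line.lstrip("# ") + "\n")
        fh.write('##ALT=<ID=DUP,Description="Copy number gain">\n')
        fh.write('##ALT=<ID=DEL,Description="Copy number loss">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=NPROBES,Number=1,Type=Integer,Description="Supporting probes">\n')
        fh.write('##INFO=<ID=MEANLOG2,Number=1,Type=Float,Description="Segment mean log2 ratio">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">\n')
        for chrom in dict.fromkeys(c.chrom for c in calls):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(sorted(calls, key=lambda c: (c.chrom, c.start_bp)), start=1):
            svtype = "DUP" if c.state == "gain" else "DEL"
            info = (
                f"SVTYPE={svtype};END={c.end_bp};NPROBES={c.n_probes};"
                f"MEANLOG2={c.mean_log2:.4f};SAMPLE={c.sample_id}"
            )
            fh.write(
                f"{c.chrom}\t{c.start_bp}\tCNV{i:05d}\tN\t<{svtype}>\t.\tPASS\t{info}\n"
            )


def write_cnvrs_bed(path, cnvrs: list[CNVR], header_lines: list[str] = ()):
    frame = pd.DataFrame(
        [
            (r.chrom, r.start_bp, r.end_bp, f"CNVR{i + 1:05d}", r.state, r.n_samples)
            for i, r in enumerate(cnvrs)
        ],
        columns=["chrom", "start", "end", "id", "state", "n_samples"],
    )
    write_bed(path, frame, header_lines)


def read_liftover_map(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", names=["probe_id", "chrom", "position"]
    )
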