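"""Synthetic aCGH data with known ground truth.

Emulates a NimbleGen-style whole-genome tiling array: a probe layout over a
small set of chromosomes, per-sample log2(test/reference) ratio profiles with
planted copy-number events, stand-in gene/QTL annotation tracks, probe
liftover maps, and qPCR Ct tables generated from an exponential-amplification
standard-curve model. Every generator is driven by one explicit seed so that
identical inputs produce byte-identical outputs.

The measurement model is diploid dosage: a probe inside an event with
``test_copies`` copies against ``ref_copies`` reference copies has expected
log2 ratio ``log2(test_copies / ref_copies)`` (+0.585 for 3 vs 2, -1.0 for
1 vs 2), zero elsewhere, plus i.i.d. Gaussian probe noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeDef",
    "ProbeLayout",
    "Log2RatioProfile",
    "PlantedEvent",
    "GroundTruthManifest",
    "QpcrModel",
    "generate_probe_layout",
    "plant_events",
    "random_events",
    "simulate_profile",
    "simulate_annotations",
    "simulate_qpcr",
]

#: log2 ratio emitted for homozygous deletions (test_copies == 0); arrays
#: saturate, so a finite floor replaces -inf and keeps downstream sums finite.
DELETION_FLOOR_LOG2 = -4.0

#: default per-probe Gaussian noise, log2-ratio units (package default; the
#: platform's actual noise level is not published).
DEFAULT_NOISE_SD = 0.15


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosomes with lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(ln <= 0 for _, ln in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosomes", tuple((str(c), int(l)) for c, l in self.chromosomes))

    @property
    def total_length(self) -> int:
        return sum(ln for _, ln in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, ln in self.chromosomes:
            if name == chrom:
                return ln
        raise KeyError(chrom)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]


@dataclass(frozen=True)
class ProbeLayout:
    """Ordered array probes: ``probes`` has columns probe_id, chrom, position.

    Positions are 1-based; probes are sorted by (chrom, position) with chrom
    order taken from the frame itself, and positions are unique within a
    chromosome.
    """

    probes: pd.DataFrame

    def __post_init__(self):
        req = ["probe_id", "chrom", "position"]
        if list(self.probes.columns[:3]) != req:
            raise ValueError(f"probe frame must start with columns {req}")
        for chrom, grp in self.probes.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"probes on {chrom} not sorted/unique by position")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))

    def median_spacing(self) -> float:
        gaps = np.concatenate(
            [
                np.diff(grp["position"].to_numpy())
                for _, grp in self.probes.groupby("chrom", sort=False)
                if len(grp) > 1
            ]
            or [np.array([])]
        )
        if gaps.size == 0:
            return float("nan")
        return float(np.median(gaps))


@dataclass(frozen=True)
class Log2RatioProfile:
    """Per-probe log2(test/reference) values aligned to a :class:`ProbeLayout`."""

    sample_id: str
    layout: ProbeLayout
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.layout),):
            raise ValueError("values must align 1:1 with layout probes")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        out = self.layout.probes[["probe_id", "chrom", "position"]].copy()
        out["log2_ratio"] = self.values
        return out


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth copy-number event, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    test_copies: int
    ref_copies: int = 2

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.test_copies < 0 or self.ref_copies < 1:
            raise ValueError("test_copies >= 0 and ref_copies >= 1 required")

    @property
    def expected_log2(self) -> float:
        if self.test_copies == 0:
            return DELETION_FLOOR_LOG2
        return float(np.log2(self.test_copies / self.ref_copies))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GroundTruthManifest:
    """Planted events per sample plus the probe indices each event covers.

    ``probe_indices`` maps (sample_id, event index) to the integer positions
    (into ``layout.probes``) of the probes inside the event; an event covering
    zero probes is undiscoverable by the array and flagged as such.
    """

    events: dict[str, list[PlantedEvent]]
    noise_sd: float
    seed: int
    probe_indices: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def undiscoverable(self, sample_id: str) -> list[int]:
        return [
            i
            for i, _ in enumerate(self.events[sample_id])
            if len(self.probe_indices[(sample_id, i)]) == 0
        ]

    def to_json(self) -> str:
        payload = {"noise_sd": self.noise_sd, "seed": self.seed}
        payload["samples"] = {
            sid: [
                {
                    "chrom": ev.chrom,
                    "start": ev.start,
                    "end": ev.end,
                    "test_copies": ev.test_copies,
                    "ref_copies": ev.ref_copies,
                    "n_probes": int(len(self.probe_indices[(sid, i)])),
                    "discoverable": bool(len(self.probe_indices[(sid, i)])),
                }
                for i, ev in enumerate(evs)
            ]
            for sid, evs in self.events.items()
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class QpcrModel:
    """Exponential-amplification qPCR simulator.

    ``efficiency`` is the per-cycle amplification fraction in (0, 1]; at 1.0
    a doubling of input lowers Ct by exactly one cycle. ``ct_at_1ng`` anchors
    the curve; Ct for quantity q (ng) is
    ``ct_at_1ng - log10(q) / log10(1 + efficiency)`` plus Gaussian cycle noise.
    """

    efficiency: float = 1.0
    ct_at_1ng: float = 30.0
    ct_noise_sd: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("efficiency must be in (0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def expected_ct(self, quantity_ng) -> np.ndarray:
        q = np.asarray(quantity_ng, dtype=float)
        if np.any(q <= 0):
            raise ValueError("quantities must be positive")
        return self.ct_at_1ng - np.log10(q) / np.log10(1.0 + self.efficiency)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_probe_layout(genome: GenomeDef, n_probes: int, seed: int) -> ProbeLayout:
    """Place ``n_probes`` across the genome, proportional to chromosome length.

    Positions come from a uniform per-chromosome grid jittered per probe and
    drawn without replacement, which reproduces a target median inter-probe
    spacing of (total genome length / n_probes) without modelling real probe
    design.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not genome.chromosomes:
        raise ValueError("genome is empty")
    if n_probes > genome.total_length:
        raise ValueError("more probes requested than base pairs in the genome")

    rng = np.random.default_rng(seed)
    total = genome.total_length
    # largest-remainder allocation proportional to length
    raw = np.array([ln / total * n_probes for _, ln in genome.chromosomes])
    counts = np.floor(raw).astype(int)
    rem = n_probes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    # a chromosome cannot hold more probes than base pairs
    for i, (_, ln) in enumerate(genome.chromosomes):
        if counts[i] > ln:
            raise ValueError("probe count exceeds chromosome length")

    rows = []
    probe_no = 0
    for (chrom, ln), k in zip(genome.chromosomes, counts):
        if k == 0:
            continue
        step = ln / k
        centers = (np.arange(k) + 0.5) * step
        jitter = rng.normal(0.0, step / 8.0, size=k)
        pos = np.clip(np.round(centers + jitter), 1, ln).astype(np.int64)
        pos = np.sort(pos)
        # enforce strictly increasing positions (without-replacement draw)
        for i in range(1, k):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        if pos[-1] > ln:  # pushed past the end by de-duplication: walk back
            pos = np.minimum(pos, ln)
            for i in range(k - 2, -1, -1):
                if pos[i] >= pos[i + 1]:
                    pos[i] = pos[i + 1] - 1
        for p in pos:
            probe_no += 1
            rows.append((f"PROBE{probe_no:06d}", chrom, int(p)))

    frame = pd.DataFrame(rows, columns=["probe_id", "chrom", "position"])
    return ProbeLayout(frame)


def plant_events(
    layout: ProbeLayout,
    spec: dict[str, list[PlantedEvent]],
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> GroundTruthManifest:
    """Record planted events per sample and the probe indices each covers.

    Events within one sample must not overlap (the copy number of a shared
    base would be ambiguous); events covering no probe are kept but flagged
    undiscoverable.
    """
    chrom_arr = layout.probes["chrom"].to_numpy()
    pos_arr = layout.probes["position"].to_numpy()
    chrom_lims: dict[str, int] = {}

    manifest = GroundTruthManifest(events={}, noise_sd=float(noise_sd), seed=int(seed))
    for sample_id, events in spec.items():
        by_chrom: dict[str, list[PlantedEvent]] = {}
        for ev in events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping events in sample {sample_id} on {chrom}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )
        manifest.events[sample_id] = list(events)
        for i, ev in enumerate(events):
            mask = (chrom_arr == ev.chrom) & (pos_arr >= ev.start) & (pos_arr <= ev.end)
            manifest.probe_indices[(sample_id, i)] = np.flatnonzero(mask)
    return manifest


def random_events(
    layout: ProbeLayout,
    n_events: int,
    rng: np.random.Generator,
    min_probes: int = 6,
    max_probes: int = 12,
    copy_choices: tuple[int, ...] = (1, 3),
    gap_probes: int = 10,
) -> list[PlantedEvent]:
    """Draw non-overlapping events aligned to runs of consecutive probes.

    Each event spans ``min_probes``..``max_probes`` consecutive probes on one
    chromosome and its bp interval runs from the first to the last probe
    position, so that every event is discoverable by construction. Events are
    separated by at least ``gap_probes`` probes. ``copy_choices`` cycles
    through the requested test copy numbers (default alternates single-copy
    loss and single-copy gain on a diploid reference).
    """
    probes = layout.probes
    events: list[PlantedEvent] = []
    # candidate (chrom, start_idx within chrom, chrom_size) slots
    groups = {c: g.reset_index(drop=True) for c, g in probes.groupby("chrom", sort=False)}
    attempts = 0
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in groups}
    while len(events) < n_events and attempts < n_events * 200:
        attempts += 1
        chrom = rng.choice(list(groups))
        grp = groups[chrom]
        span = int(rng.integers(min_probes, max_probes + 1))
        if len(grp) < span:
            continue
        i0 = int(rng.integers(0, len(grp) - span + 1))
        i1 = i0 + span - 1
        if any(i0 <= b + gap_probes and i1 >= a - gap_probes for a, b in used[chrom]):
            continue
        used[chrom].append((i0, i1))
        copies = copy_choices[len(events) % len(copy_choices)]
        events.append(
            PlantedEvent(
                chrom=chrom,
                start=int(grp["position"].iloc[i0]),
                end=int(grp["position"].iloc[i1]),
                test_copies=copies,
            )
        )
    if len(events) < n_events:
        raise RuntimeError("could not place the requested number of events")
    return events


def simulate_profile(
    layout: ProbeLayout,
    manifest: GroundTruthManifest,
    sample_id: str,
    deletion_floor: float = DELETION_FLOOR_LOG2,
) -> Log2RatioProfile:
    """Simulate one sample's log2-ratio profile from its planted events.

    Probe value = log2(test/ref copies) inside events (a finite floor for
    homozygous deletions), 0 elsewhere, plus Gaussian noise of the manifest's
    noise_sd. Noise is seeded per sample so profiles are reproducible and
    samples are independent.
    """
    if sample_id not in manifest.events:
        raise KeyError(f"sample {sample_id!r} not in manifest")
    values = np.zeros(len(layout))
    for i, ev in enumerate(manifest.events[sample_id]):
        idx = manifest.probe_indices[(sample_id, i)]
        if ev.test_copies == 0:
            values[idx] = deletion_floor
        else:
            values[idx] = np.log2(ev.test_copies / ev.ref_copies)
    if manifest.noise_sd > 0:
        # independent per-sample stream derived from (seed, sample_id)
        sub = np.random.default_rng([manifest.seed, _stable_hash(sample_id)])
        values = values + sub.normal(0.0, manifest.noise_sd, size=len(layout))
    return Log2RatioProfile(sample_id=sample_id, layout=layout, values=values)


def _stable_hash(text: str) -> int:
    h = 2166136261
    for b in text.encode():
        h = ((h ^ b) * 16777619) % (1 << 31)
    return h


def simulate_annotations(
    genome: GenomeDef,
    n_genes: int,
    n_qtls: int,
    seed: int,
    gene_length_range: tuple[int, int] = (2_000, 50_000),
    qtl_ci_below: tuple[int, int] = (1_000_000, 9_000_000),
    qtl_ci_above: tuple[int, int] = (11_000_000, 30_000_000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stand-in gene and QTL tracks (1-based inclusive interval frames).

    Genes are non-degenerate intervals with unique IDs. QTLs carry a
    confidence-interval width column ``ci_bp`` drawn half below and half above
    10 Mb so the CI < 10 Mb filter has something to do.
    """
    if n_genes < 0 or n_qtls < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = np.array([ln for _, ln in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()

    def draw_intervals(n: int, min_len: int, max_len: int) -> list[tuple[str, int, int]]:
        out = []
        for _ in range(n):
            ci = rng.choice(len(lengths), p=probs)
            chrom, ln = genome.chromosomes[ci]
            size = int(rng.integers(min_len, min(max_len, ln) + 1))
            start = int(rng.integers(1, max(2, ln - size + 2)))
            out.append((chrom, start, min(start + size - 1, ln)))
        return out

    genes = pd.DataFrame(
        draw_intervals(n_genes, *gene_length_range), columns=["chrom", "start", "end"]
    )
    genes.insert(0, "id", [f"GENE{i + 1:05d}" for i in range(n_genes)])
    genes = genes[["chrom", "start", "end", "id"]]

    qtls = pd.DataFrame(
        draw_intervals(n_qtls, 50_000, 2_000_000), columns=["chrom", "start", "end"]
    )
    qtls.insert(0, "id", [f"QTL{i + 1:05d}" for i in range(n_qtls)])
    qtls = qtls[["chrom", "start", "end", "id"]]
    half = n_qtls // 2
    ci = np.concatenate(
        [
            rng.integers(qtl_ci_below[0], qtl_ci_below[1] + 1, size=half),
            rng.integers(qtl_ci_above[0], qtl_ci_above[1] + 1, size=n_qtls - half),
        ]
    ).astype(np.int64)
    rng.shuffle(ci)
    qtls["ci_bp"] = ci if n_qtls else np.array([], dtype=np.int64)
    return genes, qtls


def simulate_qpcr(
    model: QpcrModel,
    quantities: list[float],
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a dilution-series Ct table (columns quantity_ng, replicate, ct)."""
    q = np.asarray(quantities, dtype=float)
    if np.any(q <= 0):
        raise ValueError("quantities must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for quantity in q:
        base = float(model.expected_ct(quantity))
        for rep in range(1, replicates + 1):
            ct = base + (rng.normal(0.0, model.ct_noise_sd) if model.ct_noise_sd > 0 else 0.0)
            rows.append((float(quantity), rep, float(ct)))
    return pd.DataFrame(rows, columns=["quantity_ng", "replicate", "ct"])
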