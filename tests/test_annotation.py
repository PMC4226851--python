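"""Liftover, interval overlap reports, QTL CI filter, term enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from cghcnv import (
    CallingParameters,
    LiftoverMap,
    annotate_genes,
    call_cnvs,
    enrich_terms,
    filter_qtls_by_ci,
    intersect_regions,
    remap_probes,
)
from cghcnv.segmentation import normalize_profile, segment_profile
from cghcnv.synthetic import Log2RatioProfile, PlantedEvent, plant_events, simulate_profile
from conftest import bitmap_overlap_pairs


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])


class TestRemapProbes:
    def test_identity_map(self, grid_layout):
        lift = LiftoverMap(
            {r.probe_id: (r.chrom, int(r.position)) for r in grid_layout.probes.itertuples()}
        )
        out, dropped = remap_probes(grid_layout, lift)
        assert dropped == 0
        pd.testing.assert_frame_equal(
            out.probes.reset_index(drop=True), grid_layout.probes
        )

    def test_partial_map_drops_and_counts(self, grid_layout):
        ids = grid_layout.probes["probe_id"].tolist()
        lift = LiftoverMap(
            {
                pid: ("chr1", int(pos))
                for pid, pos in zip(ids[:75], grid_layout.probes["position"][:75])
            }
        )
        out, dropped = remap_probes(grid_layout, lift)
        assert len(out) == 75 and dropped == 25

    def test_position_collision_keeps_first_with_warning(self, grid_layout):
        entries = {
            r.probe_id: (r.chrom, int(r.position)) for r in grid_layout.probes.itertuples()
        }
        entries["P001"] = entries["P000"]  # collide
        with pytest.warns(UserWarning, match="already-occupied"):
            out, _ = remap_probes(grid_layout, LiftoverMap(entries))
        assert len(out) == 99
        assert "P000" in set(out.probes["probe_id"])

    def test_uniform_shift_moves_recalled_cnv_boundaries(self, grid_layout):
        # plant one event, call it, remap all probes +1 kb, recall: bounds shift +1 kb
        ev = PlantedEvent("chr1", 20_500, 30_500, test_copies=1)
        man = plant_events(grid_layout, {"s": [ev]}, seed=1, noise_sd=0.0)
        prof = simulate_profile(grid_layout, man, "s")
        segs = segment_profile(prof, penalty=0.5)
        calls = call_cnvs(segs, CallingParameters(), "s")
        shifted_frame = grid_layout.probes.copy()
        lift = LiftoverMap(
            {
                r.probe_id: (r.chrom, int(r.position) + 1000)
                for r in shifted_frame.itertuples()
            }
        )
        shifted, _ = remap_probes(grid_layout, lift)
        prof2 = Log2RatioProfile("s", shifted, prof.values)
        calls2 = call_cnvs(segment_profile(prof2, penalty=0.5), CallingParameters(), "s")
        assert len(calls) == len(calls2) == 1
        assert calls2[0].start_bp == calls[0].start_bp + 1000
        assert calls2[0].end_bp == calls[0].end_bp + 1000


class TestIntersectRegions:
    def test_one_bp_touch_reported(self):
        rep = intersect_regions(
            frame([("chr1", 100, 200, "q")]), frame([("chr1", 200, 300, "s")])
        )
        assert rep.pairs.iloc[0]["overlap_bp"] == 1
        assert rep.n_query_overlapped == 1

    def test_disjoint_not_reported(self):
        rep = intersect_regions(
            frame([("chr1", 100, 200, "q")]), frame([("chr1", 201, 300, "s")])
        )
        assert rep.pairs.empty and rep.n_query_overlapped == 0

    def test_query_counts_once_across_two_subjects(self):
        rep = intersect_regions(
            frame([("chr1", 100, 500, "q")]),
            frame([("chr1", 50, 150, "s1"), ("chr1", 400, 600, "s2")]),
        )
        assert len(rep.pairs) == 2 and rep.n_query_overlapped == 1

    def test_matches_bitmap_oracle_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(6):
            q = [
                ("q%d" % i, int(rng.integers(1, 9_000)), 0) for i in range(50)
            ]
            q = [(i, s, s + int(rng.integers(0, 500))) for i, s, _ in q]
            s = [
                ("s%d" % i, int(rng.integers(1, 9_000)), 0) for i in range(50)
            ]
            s = [(i, a, a + int(rng.integers(0, 500))) for i, a, _ in s]
            rep = intersect_regions(
                frame([("chr1", a, b, i) for i, a, b in q]),
                frame([("chr1", a, b, i) for i, a, b in s]),
            )
            got = {
                (r.query_id, r.subject_id): r.overlap_bp
                for r in rep.pairs.itertuples(index=False)
            }
            assert got == bitmap_overlap_pairs(q, s, size=10_000)

    def test_symmetry_of_total_overlap(self):
        rng = np.random.default_rng(8)
        a = frame(
            [("chr1", int(s), int(s) + int(rng.integers(1, 300)), f"a{i}")
             for i, s in enumerate(rng.integers(1, 5_000, 30))]
        )
        b = frame(
            [("chr1", int(s), int(s) + int(rng.integers(1, 300)), f"b{i}")
             for i, s in enumerate(rng.integers(1, 5_000, 30))]
        )
        assert (
            intersect_regions(a, b).total_overlap_bp
            == intersect_regions(b, a).total_overlap_bp
        )

    def test_different_chromosomes_never_overlap(self):
        rep = intersect_regions(
            frame([("chr1", 1, 1000, "q")]), frame([("chr2", 1, 1000, "s")])
        )
        assert rep.pairs.empty


class TestAnnotateGenes:
    def test_complete_vs_partial(self):
        cnvrs = frame([("chr1", 100, 200, "R1")])
        genes = frame([("chr1", 120, 180, "G1"), ("chr1", 50, 150, "G2")])
        pairs, n = annotate_genes(cnvrs, genes)
        modes = pairs.set_index("gene_id")["mode"]
        assert modes["G1"] == "complete" and modes["G2"] == "partial"
        assert n == 2

    def test_gene_spanning_two_cnvrs_counted_once(self):
        cnvrs = frame([("chr1", 100, 200, "R1"), ("chr1", 300, 400, "R2")])
        genes = frame([("chr1", 150, 350, "G1")])
        pairs, n = annotate_genes(cnvrs, genes)
        assert sorted(pairs["cnvr_id"]) == ["R1", "R2"]
        assert n == 1

    def test_no_genes(self):
        pairs, n = annotate_genes(frame([("chr1", 1, 10, "R")]), frame([]))
        assert pairs.empty and n == 0


class TestQtlCiFilter:
    def test_strict_10mb_boundary(self):
        qtls = frame(
            [("chr1", 1, 100, "keep"), ("chr1", 1, 100, "drop"), ("chr1", 1, 100, "big")]
        )
        qtls["ci_bp"] = [9_999_999, 10_000_000, 25_000_000]
        kept = filter_qtls_by_ci(qtls)
        assert kept["id"].tolist() == ["keep"]

    def test_missing_ci_excluded_with_warning(self):
        qtls = frame([("chr1", 1, 100, "a"), ("chr1", 1, 100, "b")])
        qtls["ci_bp"] = [5_000_000, np.nan]
        with pytest.warns(UserWarning, match="lack a CI width"):
            kept = filter_qtls_by_ci(qtls)
        assert kept["id"].tolist() == ["a"]

    def test_all_above_bound_gives_empty(self):
        qtls = frame([("chr1", 1, 100, "a")])
        qtls["ci_bp"] = [12_000_000]
        assert len(filter_qtls_by_ci(qtls)) == 0


def hypergeom_tail(k, n, K, N):
    """Brute-force upper-tail P[X >= k] by direct enumeration."""
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestEnrichTerms:
    def test_p_matches_enumeration(self):
        background = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        term_map = {"T": {f"g{i}" for i in range(5)}}  # all 5 term genes in set
        res = enrich_terms(gene_set, background, term_map)
        assert res.iloc[0]["p_value"] == pytest.approx(hypergeom_tail(5, 10, 5, 100))

    def test_enumeration_grid(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            N = int(rng.integers(10, 51))
            background = {f"g{i}" for i in range(N)}
            n = int(rng.integers(2, N))
            gene_set = set(rng.choice(sorted(background), size=n, replace=False))
            K = int(rng.integers(1, N))
            term_genes = set(rng.choice(sorted(background), size=K, replace=False))
            res = enrich_terms(gene_set, background, {"T": term_genes})
            k = len(term_genes & gene_set)
            if k == 0:
                assert res.empty
            else:
                assert res.iloc[0]["p_value"] == pytest.approx(
                    hypergeom_tail(k, n, K, N), abs=1e-12
                )

    def test_term_in_all_background_p_is_one(self):
        background = {f"g{i}" for i in range(20)}
        res = enrich_terms({"g0", "g1"}, background, {"T": set(background)})
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_single_term_bh_identity(self):
        background = {f"g{i}" for i in range(30)}
        res = enrich_terms({"g0", "g1", "g2"}, background, {"T": {"g0", "g1"}})
        assert res.iloc[0]["adjusted_p"] == pytest.approx(res.iloc[0]["p_value"])

    def test_bh_stepup_monotone_and_geq_p(self):
        rng = np.random.default_rng(4)
        background = {f"g{i}" for i in range(40)}
        gene_set = {f"g{i}" for i in range(12)}
        term_map = {
            f"T{j}": set(rng.choice(sorted(background), size=int(rng.integers(2, 20)), replace=False))
            for j in range(15)
        }
        res = enrich_terms(gene_set, background, term_map).sort_values("p_value")
        assert (res["adjusted_p"].to_numpy() >= res["p_value"].to_numpy() - 1e-15).all()
        assert (np.diff(res["adjusted_p"].to_numpy()) >= -1e-15).all()

    def test_ease_variant_is_more_conservative(self):
        background = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(8)}
        term_map = {"T": {f"g{i}" for i in range(4)}}
        plain = enrich_terms(gene_set, background, term_map).iloc[0]["p_value"]
        ease = enrich_terms(gene_set, background, term_map, ease=True).iloc[0]["p_value"]
        assert ease > plain

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            enrich_terms(set(), set(), {})
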