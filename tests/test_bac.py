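"""BAC locus calling, edge verification and cross-mapping."""

import numpy as np
import pytest

from neosexqc.alignio import placements_from_arrays
from neosexqc.bac import (
    BacLocusParams,
    call_bac_locus,
    cross_map_fraction,
    verify_edges,
)
from neosexqc.scenarios import bac_spec, sexlink_spec
from neosexqc.synthetic import generate_genome, simulate_bac_set

LENGTHS = {"chr": 3_000_000}


def coverage_placements(regions, lengths=LENGTHS, read_len=100):
    """Reads tiling (scaffold, start, end, depth) regions at uniform depth."""
    refs, starts = [], []
    names = list(lengths)
    for scaf, s, e, depth in regions:
        n = int(depth * (e - s) / read_len)
        pos = np.linspace(s, e - read_len, n).astype(np.int64)
        starts.append(pos)
        refs.append(np.full(n, names.index(scaf), np.int32))
    ref = np.concatenate(refs)
    start = np.concatenate(starts)
    return placements_from_arrays(lengths, ref, start, start + read_len)


class TestCallBacLocus:
    def test_single_deep_region_is_unique(self):
        pl = coverage_placements([("chr", 500_000, 600_000, 180)])
        res = call_bac_locus(pl, "b1")
        assert res.status == "unique"
        locus = res.loci[0]
        assert abs(locus.start - 500_000) <= 1000 and abs(locus.end - 600_000) <= 1000
        assert locus.mean_depth == pytest.approx(180, rel=0.05)

    def test_half_of_max_drops_cross_contamination(self):
        pl = coverage_placements([
            ("chr", 100_000, 200_000, 200),
            ("chr", 1_500_000, 1_560_000, 60),  # 60 < 0.5 * 200
        ])
        res = call_bac_locus(pl, "b2")
        assert res.status == "unique"
        assert any(e["step"] == "half_of_max" for e in res.filter_log)

    def test_merge_within_250kb_then_remerge_at_5kb(self):
        # two 30-kb runs 100 kb apart merge into one locus
        pl = coverage_placements([
            ("chr", 100_000, 130_000, 120),
            ("chr", 230_000, 260_000, 120),
        ])
        res = call_bac_locus(pl, "b3")
        assert res.status == "unique"
        assert (res.loci[0].start, res.loci[0].end) == (100_000, 260_000)
        # three runs whose 250-kb merge spans 400 kb re-merge at 5 kb
        pl = coverage_placements([
            ("chr", 100_000, 160_000, 120),
            ("chr", 300_000, 360_000, 120),
            ("chr", 440_000, 500_000, 120),
        ])
        res = call_bac_locus(pl, "b4")
        assert res.status == "multiple"
        assert len(res.loci) == 3
        assert any(e["step"] == "remerge" for e in res.filter_log)

    def test_short_region_is_unplaced(self):
        pl = coverage_placements([("chr", 500_000, 515_000, 300)])
        res = call_bac_locus(pl, "b5")
        assert res.status == "unplaced"
        assert any(e["step"] == "min_length" for e in res.filter_log)

    def test_no_deep_window_is_unplaced(self):
        pl = coverage_placements([("chr", 500_000, 600_000, 10)])
        res = call_bac_locus(pl, "b6")
        assert res.status == "unplaced" and res.loci == []

    def test_prefilter_failure_is_logged_distinctly(self):
        pl = coverage_placements([("chr", 0, 10_000, 5)])
        res = call_bac_locus(pl, "b7", total_reads=100_000)
        assert res.status == "filtered"
        assert res.filter_log[0]["step"] == "coverage_prefilter"

    def test_half_of_max_rule_is_depth_scale_invariant(self):
        regions = [("chr", 100_000, 200_000, 200), ("chr", 1_500_000, 1_560_000, 80)]
        base = call_bac_locus(coverage_placements(regions), "b8")
        scaled = call_bac_locus(
            coverage_placements([(s, a, b, d * 3) for s, a, b, d in regions]), "b8"
        )
        assert [l.scaffold for l in base.loci] == [l.scaffold for l in scaled.loci]
        assert base.status == scaled.status

    def test_filter_replay_is_idempotent(self):
        pl = coverage_placements([
            ("chr", 100_000, 200_000, 200),
            ("chr", 1_500_000, 1_540_000, 60),
        ])
        first = call_bac_locus(pl, "b9")
        second = call_bac_locus(pl, "b9")
        assert [vars(l) for l in first.loci] == [vars(l) for l in second.loci]
        assert first.filter_log == second.filter_log


class TestVerifyEdges:
    def test_edges_from_simulated_vector_mates(self):
        spec = bac_spec(2, n=4, chimera_fraction=0.0)
        genome, truth = generate_genome(spec)
        bacs, _ = simulate_bac_set(genome, truth, spec)
        for b in bacs:
            apl = b.assembly_placements()
            res = call_bac_locus(apl, b.bac_id)
            res = verify_edges(b.vector_placements(), apl, res, b.vector_length)
            assert res.start_edge_support and res.end_edge_support
            assert res.start_edge_count >= 3 and res.end_edge_count >= 3

    def test_no_vector_reads_means_no_support(self):
        pl = coverage_placements([("chr", 500_000, 600_000, 180)])
        res = call_bac_locus(pl, "b1")
        empty = placements_from_arrays(
            {"vec": 8000}, np.empty(0, np.int32), np.empty(0, np.int64),
            np.empty(0, np.int64),
            qname=np.empty(0, np.int64), mate=np.empty(0, np.int8),
        )
        pl.qname = np.arange(len(pl)) // 2
        pl.mate = (np.arange(len(pl)) % 2 + 1).astype(np.int8)
        res = verify_edges(empty, pl, res, 8000)
        assert res.start_edge_support is False and res.end_edge_support is False

    def test_unplaced_clone_keeps_null_edge_fields(self):
        pl = coverage_placements([("chr", 500_000, 600_000, 10)])
        res = call_bac_locus(pl, "b1")
        res = verify_edges(pl, pl, res, 8000)
        assert res.start_edge_support is None and res.end_edge_support is None

    def test_matches_bruteforce_mate_lookup(self, rng):
        # oracle: dict-based mate lookup over explicit read pairs
        spec = bac_spec(5, n=3, chimera_fraction=0.0)
        genome, truth = generate_genome(spec)
        bacs, _ = simulate_bac_set(genome, truth, spec)
        for b in bacs:
            apl = b.assembly_placements()
            vpl = b.vector_placements()
            res = call_bac_locus(apl, b.bac_id)
            res = verify_edges(vpl, apl, res, b.vector_length)
            locus = res.loci[0]
            asm_by_key = {
                (int(q), int(m)): (int(s), int(e))
                for q, m, s, e in zip(apl.qname, apl.mate, apl.start, apl.end)
            }
            counts = {"left": [0, 0], "right": [0, 0]}
            for q, m, s, e in zip(vpl.qname, vpl.mate, vpl.start, vpl.end):
                grp = None
                if s < 4000:
                    grp = 0
                elif e > b.vector_length - 4000:
                    grp = 1
                if grp is None:
                    continue
                mate = asm_by_key.get((int(q), 3 - int(m)))
                if mate is None:
                    continue
                if abs(mate[0] - locus.start) <= 10_000:
                    counts["left"][grp] += 1
                if abs(mate[1] - locus.end) <= 10_000:
                    counts["right"][grp] += 1
            expect = max(counts["left"][0] + counts["right"][1],
                         counts["right"][0] + counts["left"][1])
            assert res.start_edge_count + res.end_edge_count == expect


@pytest.fixture(scope="module")
def neo_pair():
    genome, truth = generate_genome(sexlink_spec(1))
    rng = np.random.default_rng(42)
    native = ("neoX", 100_000, 140_000)
    homolog = ("neoY", 100_000, 140_000)
    seq = genome["neoX"][100_000:140_000]
    reads = []
    for s in rng.integers(0, len(seq) - 350 + 1, 1500):
        reads += [seq[s : s + 100], seq[s + 250 : s + 350]]
    return genome, native, homolog, reads


class TestCrossMap:
    def test_little_cross_mapping_before_masking(self, neo_pair):
        genome, native, homolog, reads = neo_pair
        rep = cross_map_fraction(reads, genome, native, homolog)
        assert rep.homolog_fraction_unmasked < 0.05

    def test_masking_native_locus_moves_reads_to_homolog(self, neo_pair):
        genome, native, homolog, reads = neo_pair
        rep = cross_map_fraction(reads, genome, native, homolog)
        assert rep.homolog_fraction_masked > 0.5
        assert rep.homolog_fraction_masked >= rep.homolog_fraction_unmasked
        assert rep.mismatch_rate_on_homolog == pytest.approx(0.015, abs=0.005)

    def test_identical_homologs_split_about_evenly(self, neo_pair):
        genome, native, homolog, reads = neo_pair
        g2 = dict(genome)
        g2["neoY"] = genome["neoX"]
        rep = cross_map_fraction(reads, g2, native, homolog)
        assert rep.homolog_fraction_unmasked == pytest.approx(0.5, abs=0.05)

    def test_overlapping_intervals_are_rejected(self, neo_pair):
        genome, _, _, reads = neo_pair
        with pytest.raises(ValueError, match="overlap"):
            cross_map_fraction(reads[:10], genome,
                               ("neoX", 0, 1000), ("neoX", 500, 1500))
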