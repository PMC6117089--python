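"""Generator contracts: planted truth, copy-number model, determinism."""

import numpy as np
import pytest

from neosexqc.alignio import write_fasta
from neosexqc.scenarios import UNIT_21, chip_spec, sexlink_spec
from neosexqc.simspec import (
    BacPlan,
    ChipPlan,
    HomologPlan,
    ReadPlan,
    SatellitePlant,
    ScaffoldPlan,
    SimSpec,
    SimSpecError,
)
from neosexqc.synthetic import (
    generate_genome,
    simulate_bac_set,
    simulate_chip_counts,
    simulate_sexed_reads,
)


def plain_spec(seed=0, **kw):
    defaults = dict(
        scaffolds=[
            ScaffoldPlan("auto", 1_000_000, "autosomal"),
            ScaffoldPlan("chrX", 1_000_000, "X"),
            ScaffoldPlan("chrY", 500_000, "Y"),
        ],
        seed=seed,
    )
    defaults.update(kw)
    return SimSpec(**defaults)


class TestGenerateGenome:
    def test_lengths_and_linkage_follow_the_plan(self):
        genome, truth = generate_genome(plain_spec())
        assert {k: len(v) for k, v in genome.items()} == {
            "auto": 1_000_000, "chrX": 1_000_000, "chrY": 500_000,
        }
        assert truth.linkage == {"auto": "autosomal", "chrX": "X", "chrY": "Y"}

    def test_satellite_truth_interval_is_copies_times_unit(self):
        spec = plain_spec(satellites=[SatellitePlant("auto", 1000, UNIT_21, 500)])
        _, truth = generate_genome(spec)
        t = truth.satellites[0]
        assert (t.start, t.end) == (1000, 1000 + 10_500)

    def test_homolog_pair_identity_matches_requested_divergence(self):
        spec = SimSpec(
            scaffolds=[ScaffoldPlan("neoX", 1_000_000, "neoX"),
                       ScaffoldPlan("neoY", 1_000_000, "neoY")],
            homologs=[HomologPlan("neoX", "neoY", 0.015)],
            seed=5,
        )
        genome, truth = generate_genome(spec)
        # recount identity directly from the emitted sequences
        a = np.frombuffer(genome["neoX"].encode(), np.uint8)
        b = np.frombuffer(genome["neoY"].encode(), np.uint8)
        identity = float((a == b).mean())
        assert identity == pytest.approx(0.985, abs=0.002)
        assert truth.homolog_identity["neoX|neoY"] == pytest.approx(identity, abs=1e-9)

    def test_out_of_bounds_plant_is_rejected_naming_the_record(self):
        spec = plain_spec(satellites=[SatellitePlant("chrY", 499_000, UNIT_21, 500)])
        with pytest.raises(SimSpecError, match="chrY"):
            generate_genome(spec)

    def test_overlapping_plants_in_one_category_are_rejected(self):
        spec = plain_spec(
            satellites=[SatellitePlant("auto", 1000, UNIT_21, 500),
                        SatellitePlant("auto", 2000, UNIT_21, 500)]
        )
        with pytest.raises(SimSpecError, match="overlapping"):
            generate_genome(spec)

    def test_identical_seed_gives_byte_identical_fasta(self, tmp_path):
        paths = []
        for i in range(2):
            genome, _ = generate_genome(sexlink_spec(3))
            p = tmp_path / f"g{i}.fa"
            write_fasta(str(p), genome)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestSexedReads:
    def test_female_reads_never_touch_y_scaffolds(self):
        spec = plain_spec(reads=ReadPlan(haploid_depth=5))
        genome, truth = generate_genome(spec)
        rs = simulate_sexed_reads(genome, truth, spec, "female")
        y_idx = rs.placements.ref_names.index("chrY")
        assert (rs.placements.ref == y_idx).sum() == 0

    def test_male_x_depth_is_half_of_autosomal(self):
        spec = plain_spec(reads=ReadPlan(haploid_depth=10))
        genome, truth = generate_genome(spec)
        rs = simulate_sexed_reads(genome, truth, spec, "male")
        pl = rs.placements
        by = {}
        for name in ("auto", "chrX"):
            i = pl.ref_names.index(name)
            sel = pl.ref == i
            by[name] = float((pl.end[sel] - pl.start[sel]).sum() / pl.length_of(name))
        assert by["chrX"] / by["auto"] == pytest.approx(0.5, rel=0.05)

    def test_total_bases_match_copy_weighted_depth_within_one_percent(self):
        spec = plain_spec(reads=ReadPlan(haploid_depth=20))
        genome, truth = generate_genome(spec)
        rs = simulate_sexed_reads(genome, truth, spec, "male")
        total = float(rs.placements.lengths.sum())
        weighted = 2 * 1_000_000 + 1 * 1_000_000 + 1 * 500_000
        assert total / weighted == pytest.approx(20.0, rel=0.01)

    def test_depth_calibration_per_linkage_class(self):
        # realized mean depth per class within 3% of copy-number expectation
        for seed in range(1, 6):
            spec = plain_spec(seed=seed, reads=ReadPlan(haploid_depth=20))
            genome, truth = generate_genome(spec)
            for sex, copies in (("male", {"auto": 2, "chrX": 1, "chrY": 1}),
                                ("female", {"auto": 2, "chrX": 2, "chrY": 0})):
                pl = simulate_sexed_reads(genome, truth, spec, sex).placements
                for name, c in copies.items():
                    i = pl.ref_names.index(name)
                    sel = pl.ref == i
                    depth = float((pl.end[sel] - pl.start[sel]).sum() / pl.length_of(name))
                    assert depth == pytest.approx(20.0 * c, rel=0.03, abs=0.1)

    def test_unknown_sex_is_rejected(self):
        spec = plain_spec()
        genome, truth = generate_genome(spec)
        with pytest.raises(ValueError, match="sex"):
            simulate_sexed_reads(genome, truth, spec, "unknown")

    def test_mates_share_an_id_stem(self):
        spec = plain_spec(reads=ReadPlan(haploid_depth=0.1))
        genome, truth = generate_genome(spec)
        rs = simulate_sexed_reads(genome, truth, spec, "male")
        ids = rs.ids()
        for r1, r2 in zip(ids[0::2], ids[1::2]):
            assert r1[:-2] == r2[:-2]
            assert r1.endswith("/1") and r2.endswith("/2")


class TestBacSimulation:
    def bac_spec_small(self, seed=1, chimera=0.0, n=6):
        return SimSpec(
            scaffolds=[ScaffoldPlan("a", 400_000), ScaffoldPlan("b", 400_000)],
            bac=BacPlan(n=n, insert_min=80_000, insert_max=120_000,
                        chimera_fraction=chimera, depth=100.0),
            seed=seed,
        )

    def test_nonchimeric_bacs_have_one_source_interval_in_range(self):
        spec = self.bac_spec_small()
        genome, truth = generate_genome(spec)
        bacs, _ = simulate_bac_set(genome, truth, spec)
        for b in bacs:
            assert not b.chimeric
            assert len(b.intervals) == 1
            _, s, e = b.intervals[0]
            assert 80_000 <= e - s <= 120_000

    def test_chimeric_bacs_record_two_intervals(self):
        spec = self.bac_spec_small(chimera=0.5)
        genome, truth = generate_genome(spec)
        bacs, _ = simulate_bac_set(genome, truth, spec)
        chim = [b for b in bacs if b.chimeric]
        assert len(chim) == 3  # round(0.5 * 6)
        for b in chim:
            assert len(b.intervals) == 2

    def test_junction_straddling_pairs_exist_at_high_depth(self):
        # >= 1 pair with one read in the vector near each junction and its
        # mate on the assembly, for every clone (fragment model guarantee)
        for seed in (1, 2, 3):
            spec = self.bac_spec_small(seed=seed)
            genome, truth = generate_genome(spec)
            bacs, _ = simulate_bac_set(genome, truth, spec)
            for b in bacs:
                dom = b.domain
                pair_dom = dom.reshape(-1, 2)
                mixed = ((pair_dom == 0).any(axis=1)) & ((pair_dom == 1).any(axis=1))
                assert mixed.sum() >= 2
                # both vector ends represented among mixed pairs
                vec_reads = np.flatnonzero(dom == 0)
                near_start = b.circle_start[vec_reads] < 4000
                near_end = b.circle_start[vec_reads] + b.read_length > b.vector_length - 4000
                assert near_start.any() and near_end.any()

    def test_read_sequences_come_from_the_circle(self):
        spec = self.bac_spec_small(n=2)
        genome, truth = generate_genome(spec)
        bacs, vector_seq = simulate_bac_set(genome, truth, spec)
        b = bacs[0]
        seqs = b.read_sequences(genome, vector_seq)
        asm = np.flatnonzero(b.domain == 1)[:20]
        for i in asm:
            scaf = b.scaffold_lengths and list(b.scaffold_lengths)[b.asm_ref[i]]
            frag = genome[scaf][b.asm_start[i] : b.asm_start[i] + b.read_length]
            assert seqs[i] == frag


class TestChipCounts:
    def test_window_partition_covers_every_base_once(self):
        spec = chip_spec(1)
        genome, truth = generate_genome(spec)
        chip, inp = simulate_chip_counts(genome, truth, spec)
        assert (chip[["scaffold", "start", "end"]] == inp[["scaffold", "start", "end"]]).all().all()
        covered = int((chip["end"] - chip["start"]).sum())
        assert covered == sum(len(s) for s in genome.values())
        assert chip.groupby("scaffold")["start"].is_monotonic_increasing.all()

    def test_no_planted_effect_gives_unit_ratio(self):
        spec = chip_spec(2, depletion_log2=0.0)
        spec.chip.enrichment_log2 = 0.0
        genome, truth = generate_genome(spec)
        chip, inp = simulate_chip_counts(genome, truth, spec)
        ratio = chip["count"].sum() / inp["count"].sum()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_planted_pericentromere_effect_recovered(self):
        spec = chip_spec(3)
        spec.chip.enrichment_log2 = 2.0
        genome, truth = generate_genome(spec)
        chip, inp = simulate_chip_counts(genome, truth, spec)
        eff = truth.chip_effects["effect"].to_numpy()
        sel = eff == 2.0
        obs = np.log2(chip["count"].to_numpy()[sel] / inp["count"].to_numpy()[sel])
        assert float(obs.mean()) == pytest.approx(2.0, abs=0.1)

    def test_negative_background_rate_rejected(self):
        spec = chip_spec(1)
        spec.chip.background_rate = -5
        with pytest.raises(SimSpecError):
            generate_genome(spec)


def test_simspec_json_round_trip():
    spec = chip_spec(9)
    restored = SimSpec.from_json(spec.to_json())
    assert restored == spec
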