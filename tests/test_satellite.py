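"""Tandem detection, report I/O, 90/90 collapsing and AT periodicity."""

import numpy as np
import pytest

from neosexqc.alignio import revcomp
from neosexqc.satellite import (
    SatelliteError,
    at_indicator,
    canonical_unit,
    collapse_motifs,
    detect_tandem_arrays,
    detect_tandem_arrays_genome,
    export_tandem_report,
    import_tandem_report,
    motif_match,
    periodicity_from_indicator,
    periodicity_profile,
    quantify_abundance,
)
from neosexqc.scenarios import (
    UNIT_21,
    UNIT_21_OTHER,
    collapse_fixture,
    phased_99_unit,
    satellite_spec,
)
from neosexqc.synthetic import generate_genome, random_sequence


# --- brute-force alignment oracle (independent of edlib) -------------------


def _nw_matrix(a: str, b: str) -> np.ndarray:
    av = np.frombuffer(a.encode(), np.uint8)
    bv = np.frombuffer(b.encode(), np.uint8)
    n, m = len(av), len(bv)
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[0] = np.arange(m + 1)
    D[:, 0] = np.arange(n + 1)
    idx = np.arange(m + 1)
    for i in range(1, n + 1):
        cand = np.minimum(D[i - 1, :-1] + (av[i - 1] != bv), D[i - 1, 1:] + 1)
        c = np.concatenate([[i], cand])
        D[i] = np.minimum.accumulate(c - idx) + idx
    return D


def oracle_identity(a: str, b: str) -> tuple[float, float]:
    """Global-alignment identity/coverage by explicit DP traceback."""
    D = _nw_matrix(a, b)
    i, j = len(a), len(b)
    eq = x = gaps = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i][j] == D[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
            eq += a[i - 1] == b[j - 1]
            x += a[i - 1] != b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and D[i][j] == D[i - 1][j] + 1:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    cols = eq + x + gaps
    identity = eq / cols if cols else 0.0
    coverage = min((eq + x) / len(a), (eq + x) / len(b)) if a and b else 0.0
    return identity, coverage


def oracle_same_family(a: str, b: str, identity=0.90, coverage=0.90,
                       max_multimer=8) -> bool:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    for k in range(1, max_multimer + 1):
        if abs(k * len(short) - len(long_)) > 0.25 * len(long_):
            continue
        expanded = short * k
        for seq in (expanded, revcomp(expanded)):
            for r in range(len(long_)):
                rot = long_[r:] + long_[:r]
                ident, cov = oracle_identity(seq, rot)
                if ident >= identity and cov >= coverage:
                    return True
    return False


def oracle_partition(motifs: list[str]) -> list[set[int]]:
    n = len(motifs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if oracle_same_family(motifs[i], motifs[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=min)


def family_partition(families) -> list[set[int]]:
    return sorted(({m["index"] for m in f.members} for f in families), key=min)


# --- detection --------------------------------------------------------------


class TestDetect:
    def test_exact_tandem(self):
        arrays = detect_tandem_arrays("ACGTA" * 100)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.unit_length == 5
        assert a.copy_number == pytest.approx(100, abs=1)
        assert canonical_unit(a.consensus) == canonical_unit("ACGTA")

    def test_random_sequence_has_no_arrays(self):
        hits = 0
        for seed in range(40):
            seq = random_sequence(np.random.default_rng(seed), 10_000)
            hits += bool(detect_tandem_arrays(seq))
        assert hits <= 2  # >= 95% of seeds clean

    def test_degraded_99bp_array_recovers_unit_and_consensus(self):
        from neosexqc.simspec import SatellitePlant, ScaffoldPlan, SimSpec

        unit = phased_99_unit()
        spec = SimSpec(
            scaffolds=[ScaffoldPlan("s", 60_000)],
            satellites=[SatellitePlant("s", 10_000, unit, 200, per_copy_sub=2)],
            seed=3,
        )
        genome, truth = generate_genome(spec)
        arrays = detect_tandem_arrays(genome["s"], "s")
        assert len(arrays) == 1
        a = arrays[0]
        assert a.unit_length == 99
        mism = sum(
            c1 != c2 for c1, c2 in zip(canonical_unit(a.consensus), canonical_unit(unit))
        )
        assert mism <= 1

    def test_planted_arrays_located_within_bounds(self):
        spec = satellite_spec(2)
        genome, truth = generate_genome(spec)
        arrays = detect_tandem_arrays_genome(genome)
        planted = [(t.start, t.end) for t in truth.satellites
                   if len(t.attrs["unit"]) <= 120]
        assert len(arrays) == len(planted)
        for a, (s, e) in zip(sorted(arrays, key=lambda x: x.start), sorted(planted)):
            assert abs(a.start - s) <= a.unit_length
            assert abs(a.end - e) <= a.unit_length


class TestReportIO:
    def test_coordinates_convert_to_half_open(self, tmp_path):
        p = tmp_path / "r.dat"
        p.write_text(
            "Sequence: scaf1\nParameters: 2 7 7 80 10 50 500\n"
            "1 105 21 5.0 21 95 0 90 25 25 25 25 1.9 "
            "AGGTCCTTAAGCATGGACTGC AGGTCCTTAAGCATGGACTGC\n"
        )
        arrays = import_tandem_report(str(p))
        assert len(arrays) == 1
        assert (arrays[0].start, arrays[0].end) == (0, 105)
        assert arrays[0].scaffold == "scaf1"

    def test_empty_report(self, tmp_path):
        p = tmp_path / "empty.dat"
        p.write_text("")
        assert import_tandem_report(str(p)) == []

    def test_malformed_record_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("Sequence: s\n1 105 21\n")
        with pytest.raises(SatelliteError, match="bad.dat:2"):
            import_tandem_report(str(p))

    def test_round_trip_of_detected_arrays(self, tmp_path):
        arrays = detect_tandem_arrays("ACGTA" * 100, scaffold="s")
        p = tmp_path / "rt.dat"
        export_tandem_report(str(p), arrays)
        back = import_tandem_report(str(p))
        assert len(back) == len(arrays)
        for a, b in zip(arrays, back):
            assert (a.scaffold, a.start, a.end, a.unit_length) == \
                   (b.scaffold, b.start, b.end, b.unit_length)
            assert a.consensus == b.consensus


class TestCollapse:
    def test_identical_and_rotated_motifs_collapse(self):
        rot = UNIT_21[7:] + UNIT_21[:7]
        fams = collapse_motifs([UNIT_21, UNIT_21, rot])
        assert len(fams) == 1

    def test_higher_order_tetramer_joins_with_k4(self):
        motifs, _ = collapse_fixture()
        fams = collapse_motifs(motifs)
        hor_member = next(
            m for f in fams for m in f.members if m["index"] == 4
        )
        assert hor_member["k"] == 4

    def test_unrelated_motifs_stay_apart(self):
        assert motif_match(UNIT_21, UNIT_21_OTHER) is None
        fams = collapse_motifs([UNIT_21, UNIT_21_OTHER])
        assert len(fams) == 2

    def test_partition_matches_bruteforce_oracle_on_fixture(self):
        motifs, _ = collapse_fixture()
        assert family_partition(collapse_motifs(motifs)) == oracle_partition(motifs)

    def test_partition_matches_oracle_on_random_motif_sets(self, rng):
        for trial in range(5):
            motifs = []
            base = random_sequence(rng, int(rng.integers(15, 30)))
            motifs.append(base)
            r = int(rng.integers(1, len(base)))
            motifs.append(base[r:] + base[:r])  # rotation
            motifs.append(revcomp(base))  # strand
            motifs.append(random_sequence(rng, int(rng.integers(15, 30))))
            motifs.append(random_sequence(rng, int(rng.integers(30, 60))))
            assert family_partition(collapse_motifs(motifs)) == oracle_partition(motifs)

    def test_rotation_and_strand_invariance_of_grouping(self, rng):
        motifs, _ = collapse_fixture()
        base = family_partition(collapse_motifs(motifs))
        shuffled = []
        for m in motifs:
            r = int(rng.integers(0, len(m)))
            m2 = m[r:] + m[:r]
            if rng.random() < 0.5:
                m2 = revcomp(m2)
            shuffled.append(m2)
        assert family_partition(collapse_motifs(shuffled)) == base


class TestAbundance:
    def test_no_planted_satellites_means_zero_totals(self):
        genome = {"s": random_sequence(np.random.default_rng(1), 50_000)}
        fams = collapse_motifs([UNIT_21])
        totals, track = quantify_abundance(genome, fams)
        assert totals == {fams[0].family_id: 0}
        assert (track[fams[0].family_id] == 0).all()

    def test_planted_array_total_within_five_percent(self):
        spec = satellite_spec(4)
        genome, truth = generate_genome(spec)
        fams = collapse_motifs([UNIT_21, phased_99_unit()])
        totals, _ = quantify_abundance(genome, fams)
        by_len = {len(f.canonical): totals[f.family_id] for f in fams}
        assert by_len[21] == pytest.approx(21_000, rel=0.05)
        assert by_len[99] == pytest.approx(29_700, rel=0.05)

    def test_totals_rank_follows_planted_abundance(self):
        spec = satellite_spec(5)
        genome, truth = generate_genome(spec)
        fams = collapse_motifs([UNIT_21, phased_99_unit()])
        totals, _ = quantify_abundance(genome, fams)
        ranked = sorted(fams, key=lambda f: -totals[f.family_id])
        assert len(ranked[0].canonical) == 99  # 29.7 kb > 21 kb planted


class TestPeriodicity:
    def test_constructed_unit_forces_peak_at_ten(self):
        rng = np.random.default_rng(0)
        unit = ["G"] * 100
        for i in range(1, 100):
            unit[i] = "GCGC"[i % 4] if i % 10 > 1 else unit[i]
        for pos in range(0, 100, 10):
            unit[pos], unit[pos + 1] = "A", "A"
        prof = periodicity_profile("".join(unit))
        assert prof.peak_lag == 10
        assert prof.prominence > 3

    def test_generator_phased_unit_peaks_at_ten(self):
        prof = periodicity_profile(phased_99_unit())
        assert prof.peak_lag == 10
        assert prof.prominence > 3

    def test_array_scale_signal_and_permutation_null(self):
        x = at_indicator(phased_99_unit() * 300, circular=False)
        prof = periodicity_from_indicator(x, circular=False)
        assert prof.peak_lag == 10 and prof.prominence > 3
        rng = np.random.default_rng(0)
        bad = sum(
            periodicity_from_indicator(rng.permutation(x), circular=False).prominence
            >= 1.5
            for _ in range(200)
        )
        assert bad <= 10  # < 1.5 in >= 95% of permutations

    def test_prominence_grows_with_phased_fraction(self):
        # calibration: more phased units -> stronger lag-10 score
        rng = np.random.default_rng(8)
        unit = phased_99_unit()
        scores = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            n_units = 120
            seq = "".join(
                unit if rng.random() < frac else random_sequence(rng, 99)
                for _ in range(n_units)
            )
            x = at_indicator(seq, circular=False)
            scores.append(periodicity_from_indicator(x, circular=False).scores[10])
        assert all(b >= a - 0.1 for a, b in zip(scores, scores[1:]))
        assert scores[-1] > scores[0]

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(SatelliteError):
            periodicity_profile("ACG")
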