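"""Canonical synthetic study conditions.

Each builder pins the genome geometry, plant set and sequencing plan of
one validation scenario, so tests and the reproduction script exercise
identical conditions.  Sizes follow the structures the procedures
target: a 5-Mb six-scaffold genome with one neo-sex pair for sex
linkage, 150-kb/80-kb duplications for conflict resolution, 50 BACs of
80-120 kb at 100x, centromere-scale satellite blocks for the chromatin
contrast, and a three-scaffold species pair with one male-limited
scaffold for Y ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simspec import (
    BacPlan,
    ChipPlan,
    DuplicationPlant,
    HomologPlan,
    ReadPlan,
    SatellitePlant,
    ScaffoldPlan,
    SimSpec,
    TelomerePlant,
)
from .synthetic import (
    TELOMERE_ELEMENT,
    generate_genome,
    higher_order_unit,
    make_phased_at_unit,
    random_sequence,
)

#: 21-bp centromere-core motif used across scenarios (arbitrary, fixed).
UNIT_21 = "AGGTCCTTAAGCATGGACTGC"
#: Unrelated 21-bp motif (for family-separation checks).
UNIT_21_OTHER = "CATTGAACGGTTCAGACCTAG"


def sexlink_spec(seed: int) -> SimSpec:
    """5-Mb genome: two autosomes, X, Y and a neo-X/neo-Y pair at 1.5%
    divergence; sexed paired-end reads at 20x haploid depth."""
    return SimSpec(
        scaffolds=[
            ScaffoldPlan("auto1", 1_250_000, "autosomal"),
            ScaffoldPlan("auto2", 1_250_000, "autosomal"),
            ScaffoldPlan("chrX", 1_000_000, "X"),
            ScaffoldPlan("chrY", 500_000, "Y"),
            ScaffoldPlan("neoX", 500_000, "neoX"),
            ScaffoldPlan("neoY", 500_000, "neoY"),
        ],
        homologs=[HomologPlan("neoX", "neoY", 0.015)],
        reads=ReadPlan(haploid_depth=20.0),
        seed=seed,
    )


def phased_99_unit(seed: int = 7) -> str:
    return make_phased_at_unit(99, 10, rng=np.random.default_rng(seed))


def satellite_spec(seed: int) -> SimSpec:
    """Two scaffolds with planted telomere/centromere structure.

    ``chrE`` carries telomeric arrays at both ends, a 21-bp satellite
    block, a 99-bp phased-AT satellite block and an internal
    telomere-element block near the satellite region (a fusion relic);
    ``chrB`` is capped on the left end only.
    """
    unit99 = phased_99_unit()
    return SimSpec(
        scaffolds=[
            ScaffoldPlan("chrE", 800_000, "autosomal"),
            ScaffoldPlan("chrB", 600_000, "autosomal"),
        ],
        satellites=[
            SatellitePlant("chrE", 300_000, UNIT_21, 1000),  # 21 kb
            SatellitePlant("chrE", 330_000, unit99, 300, phased_at=True),  # 29.7 kb
            SatellitePlant("chrE", 400_000, TELOMERE_ELEMENT, 20),  # internal block
        ],
        telomeres=[
            TelomerePlant("chrE", "left", 8_000),
            TelomerePlant("chrE", "right", 8_000),
            TelomerePlant("chrB", "left", 8_000),
        ],
        seed=seed,
    )


def dup_spec(seed: int) -> SimSpec:
    """Three duplication plants: 150-kb erroneous, 150-kb true, 80-kb
    erroneous (the last below the >100-kb reporting floor)."""
    return SimSpec(
        scaffolds=[
            ScaffoldPlan("scafA", 1_500_000, "autosomal"),
            ScaffoldPlan("scafB", 1_500_000, "autosomal"),
        ],
        duplications=[
            DuplicationPlant("scafA", 200_000, "scafB", 200_000, 150_000, "erroneous"),
            DuplicationPlant("scafA", 600_000, "scafB", 600_000, 150_000, "true"),
            DuplicationPlant("scafA", 1_000_000, "scafB", 1_000_000, 80_000, "erroneous"),
        ],
        reads=ReadPlan(haploid_depth=20.0),
        seed=seed,
    )


def bac_spec(seed: int, n: int = 50, chimera_fraction: float = 0.05) -> SimSpec:
    return SimSpec(
        scaffolds=[
            ScaffoldPlan("bacA", 2_000_000, "autosomal"),
            ScaffoldPlan("bacB", 2_000_000, "autosomal"),
        ],
        bac=BacPlan(n=n, chimera_fraction=chimera_fraction, depth=100.0),
        seed=seed,
    )


def chip_spec(seed: int, depletion_log2: float = -0.5) -> SimSpec:
    """Centromere-scale geometry for the H3K9me3 contrast: a 630-kb
    satellite block inside a 1.6-Mb pericentromere (>= 50 windows per
    group at 10 kb) and >= 500 expected counts per window."""
    return SimSpec(
        scaffolds=[ScaffoldPlan("chrM", 4_000_000, "autosomal")],
        satellites=[SatellitePlant("chrM", 1_700_000, UNIT_21, 30_000)],  # 630 kb
        chip=ChipPlan(
            background_rate=800.0,
            depletion_log2=depletion_log2,
            enrichment_log2=2.0,
            pericentromere=[("chrM", 1_200_000, 2_800_000)],
        ),
        seed=seed,
    )


@dataclass
class YAncestryScenario:
    """A male/female assembly pair of a second species plus a target Y.

    ``mY`` is male-limited apart from a 20-kb segment sharing 2%-diverged
    ancestry with the female X; the target Y's short arm descends from
    ``mY`` (2% diverged) while the long arm is unrelated sequence.
    """

    male_assembly: dict[str, str]
    female_assembly: dict[str, str]
    target_y: dict[str, str]
    wga: pd.DataFrame  # male-assembly coordinates of male->female alignments
    read_ids: list[str]
    read_seqs: list[str]
    read_origin: np.ndarray  # scaffold name per read
    male_specific_truth: set[str]
    short_arm: tuple[str, int, int]
    long_arm: tuple[str, int, int]


def _diverged(seq: str, divergence: float, rng: np.random.Generator) -> str:
    from .synthetic import decode, encode

    arr = encode(seq)
    mask = rng.random(len(arr)) < divergence
    n = int(mask.sum())
    arr[mask] = (arr[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return decode(arr)


def yancestry_scenario(seed: int, depth: float = 5.0, read_length: int = 100,
                       divergence: float = 0.02) -> YAncestryScenario:
    rng = np.random.default_rng([seed, 10])
    fA = random_sequence(rng, 400_000)
    fX = random_sequence(rng, 300_000)
    mA = _diverged(fA, divergence, rng)
    mX = _diverged(fX, divergence, rng)
    mY = random_sequence(rng, 250_000)
    shared = _diverged(fX[100_000:120_000], divergence, rng)
    mY = mY[:150_000] + shared + mY[170_000:]
    male = {"mA": mA, "mX": mX, "mY": mY}
    female = {"fA": fA, "fX": fX}
    short = _diverged(mY, divergence, rng)
    long_arm = random_sequence(rng, 350_000)
    target = {"Ymir": short + long_arm}
    wga = pd.DataFrame(
        [
            {"scaffold": "mA", "start": 0, "end": len(mA)},
            {"scaffold": "mX", "start": 0, "end": len(mX)},
            {"scaffold": "mY", "start": 150_000, "end": 170_000},
        ]
    )

    ids, seqs, origin = [], [], []
    for name, seq in male.items():
        n_reads = int(round(depth * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, n_reads)
        for j, s in enumerate(starts):
            ids.append(f"{name}:{j}")
            seqs.append(seq[s : s + read_length])
            origin.append(name)
    return YAncestryScenario(
        male_assembly=male,
        female_assembly=female,
        target_y=target,
        wga=wga,
        read_ids=ids,
        read_seqs=seqs,
        read_origin=np.array(origin),
        male_specific_truth={"mY"},
        short_arm=("Ymir", 0, 250_000),
        long_arm=("Ymir", 250_000, 600_000),
    )


def collapse_fixture(seed: int = 0) -> tuple[list[str], dict[str, set[int]]]:
    """Motif set for the 90/90 collapsing check: a 21-bp unit, three
    rotated/substituted variants (>= 92% identity), its 84-bp higher-order
    tetramer, and an unrelated 21-bp motif.  Returns (motifs, expected
    partition by motif index)."""
    rng = np.random.default_rng([seed, 11])
    base = UNIT_21
    variants = []
    for rot in (5, 11, 17):
        v = base[rot:] + base[:rot]
        v = _diverged(v, 0.0, rng)
        arr = list(v)
        pos = int(rng.integers(0, len(arr)))
        arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]  # 1 sub ~ 95% id
        variants.append("".join(arr))
    hor = higher_order_unit(base, 4, 2, rng)
    motifs = [base, *variants, hor, UNIT_21_OTHER]
    expected = {"family_of_base": {0, 1, 2, 3, 4}, "unrelated": {5}}
    return motifs, expected
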