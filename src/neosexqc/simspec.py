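"""Simulation plans and planted-feature truth records.

A :class:`SimSpec` describes a synthetic genome down to every planted
feature: scaffolds with a sex-linkage class, homolog pairs with a
substitution divergence, satellite and telomere arrays, duplications,
BAC clones and a ChIP experiment.  The generator returns a
:class:`TruthSet` enumerating every plant, which downstream tests use as
the oracle.  Coordinates are 0-based half-open throughout (BED).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

LINKAGE_CLASSES = ("autosomal", "X", "Y", "neoX", "neoY")

# Copy number of each linkage class in a diploid female / male individual.
FEMALE_COPY = {"autosomal": 2, "X": 2, "neoX": 2, "Y": 0, "neoY": 0}
MALE_COPY = {"autosomal": 2, "X": 1, "neoX": 1, "Y": 1, "neoY": 1}


class SimSpecError(ValueError):
    """A simulation plan violates its invariants; the message names the record."""


@dataclass
class ScaffoldPlan:
    name: str
    length: int
    linkage: str = "autosomal"


@dataclass
class HomologPlan:
    """Emit ``target`` as a copy of ``source`` with i.i.d. substitutions."""

    source: str
    target: str
    divergence: float


@dataclass
class SatellitePlant:
    scaffold: str
    start: int
    unit: str
    copies: int
    phased_at: bool = False
    per_copy_sub: int = 0  # substitutions introduced per tandem copy

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies


@dataclass
class TelomerePlant:
    scaffold: str
    end: str  # "left" | "right"
    length: int


@dataclass
class DuplicationPlant:
    source_scaffold: str
    source_start: int
    target_scaffold: str
    target_start: int
    length: int
    mode: str  # "erroneous" | "true"


@dataclass
class BacPlan:
    n: int = 50
    insert_min: int = 80_000
    insert_max: int = 120_000
    vector_name: str = "pSYN-BAC1"
    vector_length: int = 8_000
    chimera_fraction: float = 0.0
    depth: float = 100.0


@dataclass
class ChipPlan:
    background_rate: float = 800.0  # mean input reads per full 10-kb window
    depletion_log2: float = -0.5  # applied over satellite arrays
    enrichment_log2: float = 2.0  # applied over the pericentromere
    pericentromere: list[tuple[str, int, int]] = field(default_factory=list)
    window: int = 10_000


@dataclass
class ReadPlan:
    read_length: int = 100
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    haploid_depth: float = 20.0
    error_rate: float = 0.0  # optional uniform substitution rate; default off


@dataclass
class SimSpec:
    scaffolds: list[ScaffoldPlan]
    homologs: list[HomologPlan] = field(default_factory=list)
    satellites: list[SatellitePlant] = field(default_factory=list)
    telomeres: list[TelomerePlant] = field(default_factory=list)
    duplications: list[DuplicationPlant] = field(default_factory=list)
    bac: BacPlan | None = None
    chip: ChipPlan | None = None
    reads: ReadPlan = field(default_factory=ReadPlan)
    seed: int = 0

    def scaffold_lengths(self) -> dict[str, int]:
        return {s.name: s.length for s in self.scaffolds}

    def validate(self) -> None:
        lengths = {}
        for s in self.scaffolds:
            if s.length <= 0:
                raise SimSpecError(f"scaffold {s.name!r}: length must be > 0")
            if s.linkage not in LINKAGE_CLASSES:
                raise SimSpecError(f"scaffold {s.name!r}: unknown linkage {s.linkage!r}")
            if s.name in lengths:
                raise SimSpecError(f"scaffold {s.name!r}: duplicate name")
            lengths[s.name] = s.length
        for h in self.homologs:
            for name in (h.source, h.target):
                if name not in lengths:
                    raise SimSpecError(f"homolog pair {h.source}->{h.target}: unknown scaffold {name!r}")
            if lengths[h.source] != lengths[h.target]:
                raise SimSpecError(
                    f"homolog pair {h.source}->{h.target}: lengths differ (substitution-only model)"
                )
            if not 0.0 <= h.divergence < 1.0:
                raise SimSpecError(f"homolog pair {h.source}->{h.target}: divergence must be in [0, 1)")
        categories = {
            "satellite": [(p.scaffold, p.start, p.start + p.length, p) for p in self.satellites],
            "telomere": [],
            "duplication": [],
        }
        for p in self.telomeres:
            if p.scaffold not in lengths:
                raise SimSpecError(f"telomere plant on {p.scaffold!r}: unknown scaffold")
            if p.end not in ("left", "right"):
                raise SimSpecError(f"telomere plant on {p.scaffold!r}: end must be left/right")
            start = 0 if p.end == "left" else lengths[p.scaffold] - p.length
            categories["telomere"].append((p.scaffold, start, start + p.length, p))
        for p in self.duplications:
            if p.mode not in ("erroneous", "true"):
                raise SimSpecError(f"duplication on {p.target_scaffold!r}: unknown mode {p.mode!r}")
            categories["duplication"].append(
                (p.source_scaffold, p.source_start, p.source_start + p.length, p)
            )
            categories["duplication"].append(
                (p.target_scaffold, p.target_start, p.target_start + p.length, p)
            )
        for cat, plants in categories.items():
            for scaf, start, end, p in plants:
                if scaf not in lengths:
                    raise SimSpecError(f"{cat} plant on {scaf!r}: unknown scaffold")
                if start < 0 or end > lengths[scaf]:
                    raise SimSpecError(
                        f"{cat} plant on {scaf!r} [{start}, {end}) exceeds scaffold bounds "
                        f"(length {lengths[scaf]}): {p}"
                    )
            by_scaf: dict[str, list] = {}
            for scaf, start, end, p in plants:
                by_scaf.setdefault(scaf, []).append((start, end, p))
            for scaf, ivals in by_scaf.items():
                ivals.sort()
                for (s1, e1, p1), (s2, e2, p2) in zip(ivals, ivals[1:]):
                    if s2 < e1:
                        raise SimSpecError(
                            f"overlapping {cat} plants on {scaf!r}: "
                            f"[{s1}, {e1}) and [{s2}, {e2})"
                        )
        if self.bac is not None:
            if self.bac.insert_min > self.bac.insert_max or self.bac.insert_min <= 0:
                raise SimSpecError("BAC plan: invalid insert length range")
            if self.bac.insert_max > max(lengths.values()):
                raise SimSpecError("BAC plan: insert range exceeds every scaffold length")
            if not 0.0 <= self.bac.chimera_fraction <= 1.0:
                raise SimSpecError("BAC plan: chimera fraction must be in [0, 1]")
        if self.chip is not None and self.chip.background_rate < 0:
            raise SimSpecError("ChIP plan: negative background rate")
        if self.reads.haploid_depth < 0:
            raise SimSpecError("read plan: depth must be >= 0")
        if self.reads.read_length <= 0:
            raise SimSpecError("read plan: read length must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimSpec":
        raw = json.loads(text)
        return cls(
            scaffolds=[ScaffoldPlan(**s) for s in raw["scaffolds"]],
            homologs=[HomologPlan(**h) for h in raw.get("homologs", [])],
            satellites=[SatellitePlant(**p) for p in raw.get("satellites", [])],
            telomeres=[TelomerePlant(**p) for p in raw.get("telomeres", [])],
            duplications=[DuplicationPlant(**p) for p in raw.get("duplications", [])],
            bac=BacPlan(**raw["bac"]) if raw.get("bac") else None,
            chip=ChipPlan(
                **{
                    **raw["chip"],
                    "pericentromere": [tuple(x) for x in raw["chip"].get("pericentromere", [])],
                }
            )
            if raw.get("chip")
            else None,
            reads=ReadPlan(**raw.get("reads", {})),
            seed=raw.get("seed", 0),
        )


@dataclass
class TruthInterval:
    scaffold: str
    start: int
    end: int
    kind: str
    attrs: dict = field(default_factory=dict)


@dataclass
class TruthSet:
    """Machine-readable record of every planted feature (the test oracle)."""

    linkage: dict[str, str]
    satellites: list[TruthInterval] = field(default_factory=list)
    telomeres: list[TruthInterval] = field(default_factory=list)
    duplications: list[tuple[TruthInterval, TruthInterval, str]] = field(default_factory=list)
    bacs: list[dict] = field(default_factory=list)
    homolog_identity: dict[str, float] = field(default_factory=dict)
    chip_effects: object | None = None  # DataFrame of per-window planted log2 effects

    def satellite_intervals(self, scaffold: str | None = None) -> list[tuple[str, int, int]]:
        return [
            (t.scaffold, t.start, t.end)
            for t in self.satellites
            if scaffold is None or t.scaffold == scaffold
        ]

    def to_json(self) -> str:
        payload = {
            "linkage": self.linkage,
            "satellites": [dataclasses.asdict(t) for t in self.satellites],
            "telomeres": [dataclasses.asdict(t) for t in self.telomeres],
            "duplications": [
                {"a": dataclasses.asdict(a), "b": dataclasses.asdict(b), "mode": mode}
                for a, b, mode in self.duplications
            ],
            "bacs": self.bacs,
            "homolog_identity": self.homolog_identity,
        }
        return json.dumps(payload, indent=2)
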