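"""Synthetic genomes, sexed read sets, BAC clones and ChIP counts.

Every feature the QC pipeline looks for is planted with fully known
coordinates: sexed coverage structure (X at F:M ~ 2, Y absent in
females), neo-sex homologs at a chosen substitution divergence,
satellite arrays with optional 10-bp-phased AA/TT/AT dinucleotides,
telomeric-element arrays at scaffold ends, erroneous and true
duplications, BAC inserts flanked by vector, and H3K9me3-like window
counts with planted enrichment/depletion.

Design notes
------------
* Divergence is substitution-only, so truth alignments stay trivially
  defined; reads are error-free by default (``ReadPlan.error_rate``).
* Read placements are emitted directly as truth alignments
  (:class:`~neosexqc.alignio.Placements`), so every downstream module is
  testable without running an external aligner.
* Background composition is i.i.d. uniform ACGT - neutral for window
  statistics.
* All randomness flows from ``SimSpec.seed`` through per-component
  child generators; identical spec + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignio import Placements, placements_from_arrays, revcomp, write_fastq
from .intervals import window_partition
from .simspec import (
    FEMALE_COPY,
    MALE_COPY,
    SimSpec,
    SimSpecError,
    TruthInterval,
    TruthSet,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

# Generator components draw from independent child streams of the spec seed.
_TAG_GENOME, _TAG_MALE, _TAG_FEMALE, _TAG_BAC, _TAG_CHIP, _TAG_REPL = range(6)


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 code array (0..3)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr > 3).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def decode(arr: np.ndarray) -> str:
    return bytes(_BASES[arr]).decode()


def _rng(spec_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed, tag])


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, length, dtype=np.uint8))


def make_phased_at_unit(length: int = 99, period: int = 10,
                        background_keep: float = 0.3,
                        rng: np.random.Generator | None = None) -> str:
    """A satellite unit carrying AA/TT/AT dinucleotides at every ``period`` bp.

    Emulates the structure of AT-rich centromeric repeats: an otherwise
    random unit with an A/T dinucleotide planted at phases 0, period,
    2*period, ...  Positions adjacent to the planted dinucleotides are
    forced to G/C so phased markers stay isolated; accidental off-phase
    A/T dinucleotides are thinned to a fraction ``background_keep``,
    leaving the low unphased background real AT-rich repeats carry.
    """
    rng = rng or np.random.default_rng(0)
    arr = rng.integers(0, 4, length, dtype=np.uint8)
    dinucs = [encode(d) for d in ("AA", "TT", "AT")]
    gc = np.array([1, 2], dtype=np.uint8)  # C, G
    for pos in range(0, length - 1, period):
        arr[pos : pos + 2] = dinucs[rng.integers(0, 3)]
        for flank in (pos - 1, pos + 2):
            if 0 <= flank < length:
                arr[flank] = gc[rng.integers(0, 2)]
    for i in range(length - 1):
        if i % period in (0, 1):
            continue
        if arr[i] in (0, 3) and arr[i + 1] in (0, 3) and rng.random() > background_keep:
            arr[i + 1] = gc[rng.integers(0, 2)]
    return decode(arr)


def higher_order_unit(unit: str, k: int, n_sub: int,
                      rng: np.random.Generator | None = None) -> str:
    """Concatenate ``k`` copies of ``unit`` and apply ``n_sub`` substitutions,
    producing a higher-order variant of the base repeat."""
    rng = rng or np.random.default_rng(0)
    arr = np.tile(encode(unit), k)
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    arr[pos] = (arr[pos] + rng.integers(1, 4, n_sub)) % 4
    return decode(arr)


def _telomere_element() -> str:
    # Fixed synthetic telomeric retroelement fragment (HeT-A/TART-like role):
    # an arbitrary but constant 400-bp sequence shared by genome plants,
    # repeat-library entries and the reference set.
    return random_sequence(np.random.default_rng(20180730), 400)


TELOMERE_ELEMENT = _telomere_element()


# ---------------------------------------------------------------------------
# genome


def generate_genome(spec: SimSpec) -> tuple[dict[str, str], TruthSet]:
    """Build scaffold sequences and the truth record for every plant.

    Homolog copies are made before feature plants; duplication plants are
    applied last so the duplicate copy reflects the final source sequence.
    """
    spec.validate()
    rng = _rng(spec.seed, _TAG_GENOME)
    arrays: dict[str, np.ndarray] = {}
    for s in spec.scaffolds:
        arrays[s.name] = rng.integers(0, 4, s.length, dtype=np.uint8)
    truth = TruthSet(linkage={s.name: s.linkage for s in spec.scaffolds})

    for h in spec.homologs:
        src = arrays[h.source]
        tgt = src.copy()
        mask = rng.random(len(src)) < h.divergence
        n_sub = int(mask.sum())
        tgt[mask] = (tgt[mask] + rng.integers(1, 4, n_sub, dtype=np.uint8)) % 4
        arrays[h.target] = tgt
        truth.homolog_identity[f"{h.source}|{h.target}"] = 1.0 - n_sub / len(src)

    for p in spec.satellites:
        unit = encode(p.unit)
        block = np.tile(unit, p.copies)
        if p.per_copy_sub:
            offsets = np.repeat(np.arange(p.copies) * len(unit), p.per_copy_sub)
            pos = offsets + rng.integers(0, len(unit), len(offsets))
            block[pos] = (block[pos] + rng.integers(1, 4, len(pos), dtype=np.uint8)) % 4
        arrays[p.scaffold][p.start : p.start + len(block)] = block
        truth.satellites.append(
            TruthInterval(
                p.scaffold,
                p.start,
                p.start + len(block),
                "satellite",
                {"unit": p.unit, "copies": p.copies, "phased_at": p.phased_at},
            )
        )

    telo = encode(TELOMERE_ELEMENT)
    for p in spec.telomeres:
        length_scaf = len(arrays[p.scaffold])
        block = np.tile(telo, -(-p.length // len(telo)))[: p.length]
        start = 0 if p.end == "left" else length_scaf - p.length
        arrays[p.scaffold][start : start + p.length] = block
        truth.telomeres.append(
            TruthInterval(p.scaffold, start, start + p.length, "telomere", {"end": p.end})
        )

    for p in spec.duplications:
        src = arrays[p.source_scaffold][p.source_start : p.source_start + p.length]
        arrays[p.target_scaffold][p.target_start : p.target_start + p.length] = src
        a = TruthInterval(p.source_scaffold, p.source_start, p.source_start + p.length,
                          "duplication", {"role": "source"})
        b = TruthInterval(p.target_scaffold, p.target_start, p.target_start + p.length,
                          "duplication", {"role": "target"})
        truth.duplications.append((a, b, p.mode))

    return {name: decode(arr) for name, arr in arrays.items()}, truth


# ---------------------------------------------------------------------------
# sexed reads


@dataclass
class ReadSet:
    """Paired-end reads with truth placements.

    Rows of ``placements`` are reads, interleaved (2i = read 1, 2i+1 =
    read 2 of fragment i); ``placements.qname`` holds integer fragment
    ids and ``placements.mate`` the mate number, so mates share an id
    stem.  Sequences are materialized on demand (truth placements are
    sufficient for coverage statistics).
    """

    placements: Placements
    id_prefix: str
    sequences: list[str] | None = None

    def __len__(self) -> int:
        return len(self.placements)

    def ids(self) -> list[str]:
        q, m = self.placements.qname, self.placements.mate
        return [f"{self.id_prefix}:{q[i]}/{m[i]}" for i in range(len(self.placements))]

    def materialize_sequences(self, genome: dict[str, str], error_rate: float = 0.0,
                              rng: np.random.Generator | None = None) -> list[str]:
        pl = self.placements
        seqs: list[str] = []
        for i in range(len(pl)):
            s = genome[pl.ref_names[pl.ref[i]]][pl.start[i] : pl.end[i]]
            if pl.strand[i]:
                s = revcomp(s)
            seqs.append(s)
        if error_rate > 0:
            rng = rng or np.random.default_rng(0)
            for i, s in enumerate(seqs):
                arr = encode(s)
                mask = rng.random(len(arr)) < error_rate
                n = int(mask.sum())
                if n:
                    arr[mask] = (arr[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
                    seqs[i] = decode(arr)
        self.sequences = seqs
        return seqs

    def write_fastq(self, path1: str, path2: str) -> None:
        if self.sequences is None:
            raise ValueError("materialize sequences before writing FASTQ")
        ids = self.ids()
        r1 = [i for i in range(len(ids)) if i % 2 == 0]
        r2 = [i for i in range(len(ids)) if i % 2 == 1]
        write_fastq(path1, [ids[i] for i in r1], [self.sequences[i] for i in r1])
        write_fastq(path2, [ids[i] for i in r2], [self.sequences[i] for i in r2])


def _sample_fragments(rng, n_pairs: int, length: int, read_len: int,
                      frag_mean: float, frag_sd: float):
    frag = np.clip(
        np.round(rng.normal(frag_mean, frag_sd, n_pairs)),
        2 * read_len,
        length,
    ).astype(np.int64)
    start = np.floor(rng.random(n_pairs) * (length - frag + 1)).astype(np.int64)
    return start, frag


def simulate_sexed_reads(genome: dict[str, str], truth: TruthSet, spec: SimSpec,
                         sex: str, with_sequences: bool = False) -> ReadSet:
    """Paired-end reads from one sexed individual.

    Copy-number model: females carry {autosome 2, X 2, neoX 2, Y 0,
    neoY 0}; males {autosome 2, X 1, neoX 1, Y 1, neoY 1}.  The fragment
    count per scaffold is set so expected per-base depth equals copy
    number x haploid depth; fragment positions are uniform.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    copy = MALE_COPY if sex == "male" else FEMALE_COPY
    rng = _rng(spec.seed, _TAG_MALE if sex == "male" else _TAG_FEMALE)
    rp = spec.reads
    lengths = {name: len(seq) for name, seq in genome.items()}
    names = list(lengths)
    refs, starts, ends, strands = [], [], [], []
    for ref_idx, name in enumerate(names):
        c = copy[truth.linkage[name]]
        if c == 0:
            continue
        length = lengths[name]
        n_pairs = int(round(c * rp.haploid_depth * length / (2 * rp.read_length)))
        if n_pairs == 0:
            continue
        fs, frag = _sample_fragments(rng, n_pairs, length, rp.read_length,
                                     rp.fragment_mean, rp.fragment_sd)
        r1s, r1e = fs, fs + rp.read_length
        r2s, r2e = fs + frag - rp.read_length, fs + frag
        s = np.empty(2 * n_pairs, dtype=np.int64)
        e = np.empty(2 * n_pairs, dtype=np.int64)
        s[0::2], s[1::2] = r1s, r2s
        e[0::2], e[1::2] = r1e, r2e
        st = np.zeros(2 * n_pairs, dtype=np.int8)
        st[1::2] = 1
        refs.append(np.full(2 * n_pairs, ref_idx, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        strands.append(st)
    if refs:
        ref = np.concatenate(refs)
        start = np.concatenate(starts)
        end = np.concatenate(ends)
        strand = np.concatenate(strands)
    else:
        ref = np.empty(0, dtype=np.int32)
        start = end = np.empty(0, dtype=np.int64)
        strand = np.empty(0, dtype=np.int8)
    n_reads = len(start)
    qname = np.repeat(np.arange(n_reads // 2, dtype=np.int64), 2)
    mate = np.tile(np.array([1, 2], dtype=np.int8), n_reads // 2)
    pl = placements_from_arrays(lengths, ref, start, end, strand, 60, qname, mate)
    rs = ReadSet(pl, id_prefix=sex)
    if with_sequences:
        rs.materialize_sequences(genome, rp.error_rate,
                                 rng if rp.error_rate > 0 else None)
    return rs


# ---------------------------------------------------------------------------
# double-mapping replicates (duplication detection)


def simulate_multimap_replicates(
    genome: dict[str, str], truth: TruthSet, spec: SimSpec,
    depth: float | None = None,
) -> tuple[Placements, Placements]:
    """Two placement sets of one read pool, differing only in the random
    assignment of multi-mapping reads.

    Reads are sampled from the *sample* genome: erroneously duplicated
    target regions exist only in the assembly, so no reads originate
    there, while true duplications are sampled from both copies.  Any
    read falling entirely inside a duplicated interval maps equally well
    to both copies and is assigned to one by an independent coin flip in
    each replicate; all other reads keep their true placement in both.
    Rows of the two returned Placements correspond one-to-one.
    """
    rng = _rng(spec.seed, _TAG_REPL)
    rl = spec.reads.read_length
    depth = 2 * spec.reads.haploid_depth if depth is None else depth
    lengths = {name: len(seq) for name, seq in genome.items()}
    names = list(lengths)
    name_idx = {n: i for i, n in enumerate(names)}

    excluded: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    members: list[tuple[int, int, int, int, int]] = []  # ref, s, partner_ref, partner_s, len
    for a, b, mode in truth.duplications:
        if mode == "erroneous":
            excluded[b.scaffold].append((b.start, b.end))
        members.append((name_idx[a.scaffold], a.start, name_idx[b.scaffold], b.start,
                        a.end - a.start))
        members.append((name_idx[b.scaffold], b.start, name_idx[a.scaffold], a.start,
                        a.end - a.start))

    refs, starts = [], []
    for name in names:
        segs, pos = [], 0
        for s, e in sorted(excluded[name]):
            if s > pos:
                segs.append((pos, s))
            pos = e
        if pos < lengths[name]:
            segs.append((pos, lengths[name]))
        seg_len = np.array([e - s for s, e in segs], dtype=np.int64)
        usable = seg_len - rl + 1
        usable[usable < 0] = 0
        total = int(usable.sum())
        if total == 0:
            continue
        n_reads = int(round(depth * seg_len.sum() / rl))
        offs = np.floor(rng.random(n_reads) * total).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(usable)])
        seg_of = np.searchsorted(cum, offs, side="right") - 1
        pos_arr = offs - cum[seg_of] + np.array([s for s, _ in segs], dtype=np.int64)[seg_of]
        refs.append(np.full(n_reads, name_idx[name], dtype=np.int32))
        starts.append(pos_arr)
    ref = np.concatenate(refs) if refs else np.empty(0, dtype=np.int32)
    start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)

    alt_ref, alt_start = ref.copy(), start.copy()
    is_multi = np.zeros(len(ref), dtype=bool)
    for m_ref, m_s, p_ref, p_s, m_len in members:
        inside = (ref == m_ref) & (start >= m_s) & (start + rl <= m_s + m_len)
        alt_ref[inside] = p_ref
        alt_start[inside] = start[inside] - m_s + p_s
        is_multi |= inside

    reps = []
    for _ in range(2):
        flip = rng.random(len(ref)) < 0.5
        take_alt = is_multi & flip
        r = np.where(take_alt, alt_ref, ref).astype(np.int32)
        s = np.where(take_alt, alt_start, start)
        reps.append(placements_from_arrays(lengths, r, s, s + rl))
    return reps[0], reps[1]


# ---------------------------------------------------------------------------
# BAC clones


@dataclass
class SimulatedBac:
    """One shotgun-sequenced BAC: vector + insert circularized.

    The circle is laid out as ``[0, V)`` vector then ``[V, V+I)`` insert;
    shotgun pairs are sampled uniformly on the circle, so some pairs
    straddle the vector-insert junctions.  A read maps to the vector or
    the assembly only if it lies entirely within one segment;
    junction-spanning reads are unmapped.
    """

    bac_id: str
    intervals: list[tuple[str, int, int]]
    chimeric: bool
    vector_name: str
    vector_length: int
    n_pairs: int
    domain: np.ndarray  # per read: 0 vector, 1 assembly, 2 junction/unmapped
    circle_start: np.ndarray
    asm_ref: np.ndarray
    asm_start: np.ndarray
    read_length: int
    scaffold_lengths: dict[str, int]

    def assembly_placements(self) -> Placements:
        idx = np.flatnonzero(self.domain == 1)
        s = self.asm_start[idx]
        return placements_from_arrays(
            self.scaffold_lengths,
            self.asm_ref[idx],
            s,
            s + self.read_length,
            qname=(idx // 2).astype(np.int64),
            mate=(idx % 2 + 1).astype(np.int8),
        )

    def vector_placements(self) -> Placements:
        idx = np.flatnonzero(self.domain == 0)
        s = self.circle_start[idx]
        return placements_from_arrays(
            {self.vector_name: self.vector_length},
            np.zeros(len(idx), dtype=np.int32),
            s,
            s + self.read_length,
            qname=(idx // 2).astype(np.int64),
            mate=(idx % 2 + 1).astype(np.int8),
        )

    def read_sequences(self, genome: dict[str, str], vector_seq: str) -> list[str]:
        circle = vector_seq + "".join(
            genome[scaf][s:e] for scaf, s, e in self.intervals
        )
        doubled = circle + circle  # reads may wrap the origin
        return [
            doubled[int(p) : int(p) + self.read_length]
            for p in self.circle_start
        ]


def simulate_bac_set(
    genome: dict[str, str], truth: TruthSet, spec: SimSpec
) -> tuple[list[SimulatedBac], str]:
    """Simulate the BAC shotgun set of ``spec.bac``; returns (bacs, vector seq).

    The number of chimeric clones is ``round(chimera_fraction * n)``;
    chimeras concatenate two inserts from different scaffolds (or, with a
    single scaffold, intervals >= 300 kb apart).
    """
    plan = spec.bac
    if plan is None:
        raise SimSpecError("spec has no BAC plan")
    rng = _rng(spec.seed, _TAG_BAC)
    vector_seq = random_sequence(rng, plan.vector_length)
    lengths = {name: len(seq) for name, seq in genome.items()}
    names = list(lengths)
    rl = spec.reads.read_length
    n_chim = int(round(plan.chimera_fraction * plan.n))
    chim_idx = set(rng.choice(plan.n, size=n_chim, replace=False).tolist()) if n_chim else set()

    bacs = []
    for i in range(plan.n):
        insert_len = int(rng.integers(plan.insert_min, plan.insert_max + 1))
        if i in chim_idx:
            part0 = int(round(insert_len * rng.uniform(0.35, 0.65)))
            parts_len = [part0, insert_len - part0]
            eligible = [n for n in names if lengths[n] >= max(parts_len)]
            if len(eligible) >= 2:
                scafs = list(rng.choice(len(eligible), size=2, replace=False))
                scafs = [eligible[int(j)] for j in scafs]
                ivals = []
                for scaf, pl_ in zip(scafs, parts_len):
                    s = int(rng.integers(0, lengths[scaf] - pl_ + 1))
                    ivals.append((scaf, s, s + pl_))
            else:
                scaf = eligible[0]
                gap = 300_000
                if lengths[scaf] < sum(parts_len) + gap:
                    raise SimSpecError(
                        f"BAC {i}: no scaffold arrangement allows a chimeric insert"
                    )
                s0 = int(rng.integers(0, lengths[scaf] - sum(parts_len) - gap + 1))
                s1 = int(rng.integers(s0 + parts_len[0] + gap, lengths[scaf] - parts_len[1] + 1))
                ivals = [(scaf, s0, s0 + parts_len[0]), (scaf, s1, s1 + parts_len[1])]
        else:
            eligible = [n for n in names if lengths[n] >= insert_len]
            if not eligible:
                raise SimSpecError(
                    f"BAC {i}: insert length {insert_len} exceeds every scaffold length"
                )
            weights = np.array([lengths[n] for n in eligible], dtype=float)
            scaf = eligible[int(rng.choice(len(eligible), p=weights / weights.sum()))]
            s = int(rng.integers(0, lengths[scaf] - insert_len + 1))
            ivals = [(scaf, s, s + insert_len)]

        V = plan.vector_length
        C = V + insert_len
        n_pairs = int(round(plan.depth * C / (2 * rl)))
        fs, frag = _sample_fragments(rng, n_pairs, C, rl,
                                     spec.reads.fragment_mean, spec.reads.fragment_sd)
        fs = np.floor(rng.random(n_pairs) * C).astype(np.int64)  # uniform on circle
        starts = np.empty(2 * n_pairs, dtype=np.int64)
        starts[0::2] = fs % C
        starts[1::2] = (fs + frag - rl) % C
        read_end = starts + rl

        domain = np.full(2 * n_pairs, 2, dtype=np.int8)
        asm_ref = np.full(2 * n_pairs, -1, dtype=np.int32)
        asm_start = np.full(2 * n_pairs, -1, dtype=np.int64)
        domain[read_end <= V] = 0
        in_insert = (starts >= V) & (read_end <= C)
        # map insert offsets to assembly coordinates part by part
        part_bounds = np.cumsum([0] + [e - s for _, s, e in ivals]) + V
        off = starts - V
        for p_idx, (scaf, s, e) in enumerate(ivals):
            lo, hi = part_bounds[p_idx] - V, part_bounds[p_idx + 1] - V
            sel = in_insert & (off >= lo) & (off + rl <= hi)
            domain[sel] = 1
            asm_ref[sel] = names.index(scaf)
            asm_start[sel] = off[sel] - lo + s

        bac = SimulatedBac(
            bac_id=f"bac{i:03d}",
            intervals=ivals,
            chimeric=i in chim_idx,
            vector_name=plan.vector_name,
            vector_length=V,
            n_pairs=n_pairs,
            domain=domain,
            circle_start=starts,
            asm_ref=asm_ref,
            asm_start=asm_start,
            read_length=rl,
            scaffold_lengths=lengths,
        )
        bacs.append(bac)
        truth.bacs.append(
            {"bac_id": bac.bac_id, "intervals": ivals, "chimeric": bac.chimeric}
        )
    return bacs, vector_seq


# ---------------------------------------------------------------------------
# ChIP counts


def simulate_chip_counts(genome: dict[str, str], truth: TruthSet, spec: SimSpec):
    """Poisson ChIP and input counts over the 10-kb window tiling.

    Input counts fluctuate around the background rate (scaled by window
    length); ChIP counts are scaled by 2^(planted log2 effect), where
    pericentromeric windows carry the enrichment effect and
    satellite-array windows additionally carry the depletion effect.
    Window-to-region assignment is by majority overlap.  Returns
    (chip DataFrame, input DataFrame) and stores the planted per-window
    effects on ``truth.chip_effects``.
    """
    import pandas as pd

    plan = spec.chip
    if plan is None:
        raise SimSpecError("spec has no ChIP plan")
    if plan.background_rate < 0:
        raise SimSpecError("ChIP plan: negative background rate")
    rng = _rng(spec.seed, _TAG_CHIP)
    lengths = {name: len(seq) for name, seq in genome.items()}
    refs, starts, ends, names = window_partition(lengths, plan.window)
    effect = np.zeros(len(starts))

    def _apply(intervals, value):
        for scaf, s, e in intervals:
            w = refs == names.index(scaf)
            cov = np.minimum(ends, e) - np.maximum(starts, s)
            sel = w & (cov * 2 > (ends - starts))
            effect[sel] += value

    _apply(plan.pericentromere, plan.enrichment_log2)
    _apply([(t.scaffold, t.start, t.end) for t in truth.satellites], plan.depletion_log2)

    scale = (ends - starts) / plan.window
    input_counts = rng.poisson(plan.background_rate * scale)
    chip_counts = rng.poisson(plan.background_rate * scale * 2.0 ** effect)
    base = {
        "scaffold": [names[r] for r in refs],
        "start": starts,
        "end": ends,
    }
    chip_df = pd.DataFrame({**base, "count": chip_counts})
    input_df = pd.DataFrame({**base, "count": input_counts})
    truth.chip_effects = pd.DataFrame({**base, "effect": effect})
    return chip_df, input_df
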