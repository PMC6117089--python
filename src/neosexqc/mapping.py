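"""Seed-and-extend read mapping against small references.

A k-mer index over the reference seeds candidate diagonals; candidates
are verified with banded edit-distance alignment (edlib) and the best
placement below a divergence ceiling wins.  This adapter backs the
operations that need actual sequence mapping (BAC cross-mapping
specificity, male-specific read subtraction) on synthetic data, where
reads are error-free and homologs differ by substitutions only; real
data would come in as SAM/BAM from a production aligner.

Regions can be masked: masked reference positions are simply excluded
from the index and candidate placements overlapping a mask are
rejected, mirroring hard-masking of an assembly before remapping.
"""

from __future__ import annotations

from dataclasses import dataclass
import zlib

import edlib
import numpy as np

from .alignio import revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; windows containing non-ACGT get code -1."""
    b = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(b) < k:
        return np.empty(0, dtype=np.int64)
    valid = (b < 4).astype(np.int64)
    b = np.where(b < 4, b, 0).astype(np.int64)
    weights = 4 ** np.arange(k, dtype=np.int64)
    codes = np.convolve(b, weights, mode="valid")
    ok = np.convolve(valid, np.ones(k, dtype=np.int64), mode="valid") == k
    return np.where(ok, codes, -1)


class ReferenceIndex:
    """Sorted k-mer index over a set of reference sequences."""

    def __init__(
        self,
        seqs: dict[str, str],
        k: int = 21,
        mask: dict[str, list[tuple[int, int]]] | None = None,
    ):
        self.k = k
        self.names = list(seqs)
        self.seqs = [seqs[n] for n in self.names]
        self.lengths = [len(s) for s in self.seqs]
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)]).astype(np.int64)
        self.mask = {n: sorted(v) for n, v in (mask or {}).items()}
        codes_all, pos_all = [], []
        for i, (name, seq) in enumerate(zip(self.names, self.seqs)):
            codes = kmer_codes(seq, k)
            pos = np.arange(len(codes), dtype=np.int64)
            drop = codes < 0
            for s, e in self.mask.get(name, []):
                drop |= (pos + k > s) & (pos < e)
            codes_all.append(codes[~drop])
            pos_all.append(pos[~drop] + self.offsets[i])
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.int64)
        gpos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._gpos = gpos[order]

    def candidates(self, codes: np.ndarray):
        """(read offset, global reference position) pairs for matching k-mers."""
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        counts = hi - lo
        read_off = np.repeat(np.arange(len(codes), dtype=np.int64), counts)
        ref_pos = np.concatenate(
            [self._gpos[a:b] for a, b in zip(lo, hi)]
        ) if counts.sum() else np.empty(0, dtype=np.int64)
        return read_off, ref_pos

    def locate(self, gpos: int) -> tuple[int, int]:
        ref = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return ref, int(gpos - self.offsets[ref])

    def _overlaps_mask(self, ref: int, start: int, end: int) -> bool:
        for s, e in self.mask.get(self.names[ref], []):
            if min(e, end) > max(s, start):
                return True
        return False


@dataclass
class MapResult:
    """Best placements of a read list; arrays are parallel to the input."""

    names: list[str]
    mapped: np.ndarray
    ref: np.ndarray
    pos: np.ndarray
    edit_distance: np.ndarray
    strand: np.ndarray

    def __len__(self) -> int:
        return len(self.mapped)

    def mismatch_rate(self, read_lengths: np.ndarray | int) -> np.ndarray:
        return self.edit_distance / np.asarray(read_lengths)


def map_reads(
    reads: list[str],
    index: ReferenceIndex,
    max_divergence: float = 0.06,
    both_strands: bool = True,
    seed_stride: int | None = None,
    max_diagonals: int = 4,
) -> MapResult:
    """Map reads to the indexed reference; unmatched reads stay unmapped.

    For each read, matching k-mers vote for diagonals; up to
    ``max_diagonals`` top diagonals are verified by edit-distance
    alignment in infix mode with ceiling ``max_divergence * read
    length``.  Equally good placements are resolved by a hash of the
    read sequence - balanced across copies of a repeat, like the random
    assignment production aligners use, but reproducible run to run.
    """
    n = len(reads)
    mapped = np.zeros(n, dtype=bool)
    ref_out = np.full(n, -1, dtype=np.int32)
    pos_out = np.full(n, -1, dtype=np.int64)
    ed_out = np.full(n, -1, dtype=np.int32)
    strand_out = np.zeros(n, dtype=np.int8)
    k = index.k

    for i, read in enumerate(reads):
        best = None  # (ed, ref, start, strand)
        ties: list[tuple] = []
        variants = [(read, 0)]
        if both_strands:
            variants.append((revcomp(read), 1))
        limit = max(1, int(max_divergence * len(read)))
        for seq, strand in variants:
            codes = kmer_codes(seq, k)
            if seed_stride and seed_stride > 1:
                codes_q = codes[::seed_stride]
                offs_scale = seed_stride
            else:
                codes_q = codes
                offs_scale = 1
            read_off, ref_pos = index.candidates(codes_q)
            if len(ref_pos) == 0:
                continue
            diags = ref_pos - read_off * offs_scale
            uniq, counts = np.unique(diags // 8, return_counts=True)
            top = uniq[np.argsort(counts, kind="stable")[::-1][:max_diagonals]]
            for d8 in sorted(top):
                d = int(d8) * 8
                ref, local = index.locate(max(d, 0))
                lo = max(0, local - 16)
                hi = min(index.lengths[ref], local + len(seq) + 16 + 8)
                if hi - lo < k:
                    continue
                target = index.seqs[ref][lo:hi]
                res = edlib.align(seq, target, mode="HW", task="locations", k=limit)
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                start = lo + loc[0]
                end = lo + loc[1] + 1
                if index._overlaps_mask(ref, start, end):
                    continue
                cand = (res["editDistance"], ref, start, strand)
                if best is None or cand[0] < best[0]:
                    best = cand
                    ties = [cand]
                elif cand[0] == best[0] and cand not in ties:
                    ties.append(cand)
        if best is not None:
            if len(ties) > 1:
                ties.sort()
                best = ties[zlib.crc32(read.encode()) % len(ties)]
            ed_out[i], ref_out[i], pos_out[i], strand_out[i] = (
                best[0], best[1], best[2], best[3],
            )
            mapped[i] = True
    return MapResult(index.names, mapped, ref_out, pos_out, ed_out, strand_out)


def find_matches(
    genome: dict[str, str],
    query: str,
    k: int = 13,
    min_length: int = 50,
    both_strands: bool = True,
) -> list[tuple[str, int, int]]:
    """Approximate occurrences of ``query`` (and tandem arrays of it).

    Genome positions whose k-mer occurs in the query (either strand) are
    clustered when closer than the query length; clusters shorter than
    ``min_length`` are dropped.  Suited to locating arrays of a known
    element, e.g. telomeric repeats.
    """
    qcodes = set(kmer_codes(query, k).tolist())
    if both_strands:
        qcodes |= set(kmer_codes(revcomp(query), k).tolist())
    qcodes.discard(-1)
    qarr = np.array(sorted(qcodes), dtype=np.int64)
    out = []
    for name, seq in genome.items():
        codes = kmer_codes(seq, k)
        hits = np.flatnonzero(np.isin(codes, qarr))
        if len(hits) == 0:
            continue
        gap = len(query)
        breaks = np.flatnonzero(np.diff(hits) > gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(hits) - 1]])
        for a, b in zip(starts, ends):
            s, e = int(hits[a]), int(hits[b]) + k
            if e - s >= min_length:
                out.append((name, s, e))
    return out
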