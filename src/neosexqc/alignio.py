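"""Alignment and sequence I/O.

Read placements are kept as flat numpy arrays (one row per aligned read)
rather than per-read objects, which keeps whole-genome simulations and
window statistics fast in pure Python.  SAM round-trips go through pysam,
so files written here interoperate with samtools and real aligners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class UnknownReferenceError(ValueError):
    """An alignment refers to a scaffold absent from the assembly."""


@dataclass
class Placements:
    """A set of read placements on a common reference.

    ``ref`` indexes into ``ref_names``; coordinates are 0-based half-open.
    ``qname`` and ``mate`` are optional: simulations use integer fragment ids
    (cheap), SAM input uses the string query names.
    """

    ref_names: list[str]
    ref_lengths: list[int]
    ref: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    mapq: np.ndarray
    qname: np.ndarray | None = None
    mate: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def subset(self, idx) -> "Placements":
        return Placements(
            self.ref_names,
            self.ref_lengths,
            self.ref[idx],
            self.start[idx],
            self.end[idx],
            self.strand[idx],
            self.mapq[idx],
            None if self.qname is None else self.qname[idx],
            None if self.mate is None else self.mate[idx],
        )

    def length_of(self, name: str) -> int:
        return self.ref_lengths[self.ref_names.index(name)]


def placements_from_arrays(
    scaffold_lengths: dict[str, int],
    ref: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    strand: np.ndarray | None = None,
    mapq: int = 60,
    qname: np.ndarray | None = None,
    mate: np.ndarray | None = None,
) -> Placements:
    n = len(start)
    if strand is None:
        strand = np.zeros(n, dtype=np.int8)
    return Placements(
        list(scaffold_lengths),
        [scaffold_lengths[k] for k in scaffold_lengths],
        np.asarray(ref, dtype=np.int32),
        np.asarray(start, dtype=np.int64),
        np.asarray(end, dtype=np.int64),
        np.asarray(strand, dtype=np.int8),
        np.full(n, mapq, dtype=np.int16) if np.isscalar(mapq) else np.asarray(mapq, dtype=np.int16),
        qname,
        mate,
    )


def from_sam(path: str, scaffold_lengths: dict[str, int] | None = None) -> Placements:
    """Load primary mapped alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped.  If
    ``scaffold_lengths`` is given, any reference absent from it raises
    :class:`UnknownReferenceError` naming the scaffold.
    """
    refs, starts, ends, strands, mapqs, qnames, mates = [], [], [], [], [], [], []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        names = list(fh.references)
        lengths = list(fh.lengths)
        if scaffold_lengths is not None:
            for name in names:
                if name not in scaffold_lengths:
                    raise UnknownReferenceError(
                        f"alignment reference {name!r} not present in the assembly"
                    )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            refs.append(rec.reference_id)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append(1 if rec.is_reverse else 0)
            mapqs.append(rec.mapping_quality)
            qnames.append(rec.query_name)
            mates.append(2 if rec.is_read2 else 1)
    return Placements(
        names,
        lengths,
        np.array(refs, dtype=np.int32),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(strands, dtype=np.int8),
        np.array(mapqs, dtype=np.int16),
        np.array(qnames, dtype=object),
        np.array(mates, dtype=np.int8),
    )


def to_sam(path: str, pl: Placements, sequences: list[str] | None = None) -> None:
    """Write placements as a coordinate-sorted SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in zip(pl.ref_names, pl.ref_lengths)],
    }
    order = np.lexsort((pl.start, pl.ref))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in order:
            a = pysam.AlignedSegment(out.header)
            if pl.qname is not None:
                a.query_name = str(pl.qname[i])
            else:
                a.query_name = f"r{i}"
            length = int(pl.end[i] - pl.start[i])
            if sequences is not None:
                a.query_sequence = sequences[i]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(sequences[i]))
            a.reference_id = int(pl.ref[i])
            a.reference_start = int(pl.start[i])
            a.cigarstring = f"{length}M"
            a.mapping_quality = int(pl.mapq[i])
            flag = 16 if pl.strand[i] else 0
            if pl.mate is not None:
                flag |= 1 | (64 if pl.mate[i] == 1 else 128)
            a.flag = flag
            out.write(a)


def write_fasta(path: str, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fastq(path: str, ids: list[str], seqs: list[str], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_bed(path: str, rows: list[tuple]) -> None:
    """Write (scaffold, start, end, *extra) rows as BED."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(path: str, df, value_col: str) -> None:
    df[["scaffold", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )
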