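"""BAC clone placement, edge verification and cross-mapping specificity.

A shotgun-sequenced BAC is located on the assembly by its coverage
footprint: runs of 1-kb windows at >= 50x mean depth are extracted,
runs within 250 kb of each other are merged (and a merged region longer
than 250 kb is re-merged at 5 kb), candidates are ranked by mean depth,
candidates below half of the best candidate's depth are discarded as
cross-contamination, and regions shorter than 20 kb are removed.  A
clone with exactly one surviving locus maps uniquely.

Insert edges are confirmed by vector-mate reads: reads mapping within
4 kb of either vector end whose mates pile up within 10 kb of a locus
boundary.  Cross-mapping between neo-sex homologs is quantified by
mapping the clone's reads with and without the native locus masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignio import Placements
from .intervals import merge_intervals
from .mapping import ReferenceIndex, map_reads


@dataclass
class Locus:
    scaffold: str
    start: int
    end: int
    mean_depth: float
    rank: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BacPlacement:
    bac_id: str
    loci: list[Locus]
    status: str  # unique | multiple | unplaced | filtered
    start_edge_support: bool | None = None
    start_edge_count: int | None = None
    end_edge_support: bool | None = None
    end_edge_count: int | None = None
    filter_log: list[dict] = field(default_factory=list)


@dataclass
class BacLocusParams:
    window: int = 1_000
    depth_min: float = 50.0
    merge_distance: int = 250_000
    remerge_span: int = 250_000
    remerge_distance: int = 5_000
    half_of_max: float = 0.5
    min_length: int = 20_000
    prefilter_min_aligned: float = 0.1  # fraction of reads aligned anywhere


def _window_depth(pl: Placements, scaffold: str, length: int, window: int) -> np.ndarray:
    nw = -(-length // window)
    bases = np.zeros(nw)
    sel = pl.ref == pl.ref_names.index(scaffold)
    s = pl.start[sel]
    e = np.minimum(pl.end[sel], length)
    w0 = s // window
    w1 = (e - 1) // window
    same = w0 == w1
    np.add.at(bases, w0[same], (e - s)[same])
    sp = ~same
    if sp.any():
        cut = (w0[sp] + 1) * window
        np.add.at(bases, w0[sp], cut - s[sp])
        np.add.at(bases, w1[sp], e[sp] - cut)
    sizes = np.full(nw, window, dtype=float)
    sizes[-1] = length - (nw - 1) * window
    return bases / sizes


def call_bac_locus(
    alignments: Placements,
    bac_id: str = "",
    params: BacLocusParams | None = None,
    total_reads: int | None = None,
) -> BacPlacement:
    """Locate one BAC from its read alignments to the assembly.

    ``total_reads``, when given, enables the pre-filter: a clone with
    fewer than 10% of its reads aligned anywhere fails sequence
    coverage and is reported with status ``filtered`` (distinct from
    ``unplaced``, which means no region reached the depth floor).
    """
    p = params or BacLocusParams()
    log: list[dict] = []
    if total_reads is not None and total_reads > 0:
        frac = len(alignments) / total_reads
        if frac < p.prefilter_min_aligned:
            log.append({"step": "coverage_prefilter", "aligned_fraction": frac})
            return BacPlacement(bac_id, [], "filtered", filter_log=log)

    # step 1: maximal runs of windows at >= depth_min, per scaffold
    runs: list[tuple[str, int, int]] = []
    for scaf, length in zip(alignments.ref_names, alignments.ref_lengths):
        depth = _window_depth(alignments, scaf, length, p.window)
        above = depth >= p.depth_min
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(idx) - 1]])
        for a, b in zip(starts, ends):
            runs.append((scaf, int(idx[a]) * p.window,
                         min(int(idx[b] + 1) * p.window, length)))
    if not runs:
        log.append({"step": "depth_floor", "note": f"no window reached {p.depth_min}x"})
        return BacPlacement(bac_id, [], "unplaced", filter_log=log)

    # steps 2-3: merge within 250 kb; re-merge over-long merges at 5 kb
    candidates: list[tuple[str, int, int]] = []
    by_scaf: dict[str, list[tuple[int, int]]] = {}
    for scaf, s, e in runs:
        by_scaf.setdefault(scaf, []).append((s, e))
    for scaf, ivals in by_scaf.items():
        for ms, me, members in merge_intervals(ivals, p.merge_distance):
            if me - ms > p.remerge_span and len(members) > 1:
                sub = [ivals[i] for i in members]
                for rs, re_, _ in merge_intervals(sub, p.remerge_distance):
                    candidates.append((scaf, rs, re_))
                log.append({"step": "remerge", "region": (scaf, ms, me),
                            "distance": p.remerge_distance})
            else:
                candidates.append((scaf, ms, me))

    def region_depth(scaf: str, s: int, e: int) -> float:
        sel = (alignments.ref == alignments.ref_names.index(scaf)) & \
              (alignments.end > s) & (alignments.start < e)
        bases = np.minimum(alignments.end[sel], e) - np.maximum(alignments.start[sel], s)
        return float(bases.sum() / (e - s))

    # steps 4-5: rank by depth, drop below half of max, drop short regions
    loci = [Locus(scaf, s, e, region_depth(scaf, s, e)) for scaf, s, e in candidates]
    loci.sort(key=lambda x: (-x.mean_depth, x.scaffold, x.start))
    if len(loci) > 1:
        top = loci[0].mean_depth
        kept = []
        for lc in loci:
            if lc.mean_depth < p.half_of_max * top:
                log.append({"step": "half_of_max", "region": (lc.scaffold, lc.start, lc.end),
                            "mean_depth": lc.mean_depth, "max_depth": top})
            else:
                kept.append(lc)
        loci = kept
    kept = []
    for lc in loci:
        if lc.length < p.min_length:
            log.append({"step": "min_length", "region": (lc.scaffold, lc.start, lc.end),
                        "length": lc.length})
        else:
            kept.append(lc)
    loci = kept
    for rank, lc in enumerate(loci, start=1):
        lc.rank = rank
    status = "unplaced" if not loci else ("unique" if len(loci) == 1 else "multiple")
    return BacPlacement(bac_id, loci, status, filter_log=log)


def verify_edges(
    vector_alignments: Placements,
    assembly_alignments: Placements,
    placement: BacPlacement,
    vector_length: int | None = None,
    vector_end_window: int = 4_000,
    edge_window: int = 10_000,
    min_support: int = 3,
) -> BacPlacement:
    """Fill the edge-support fields of a placement.

    Vector reads within ``vector_end_window`` of the vector's start
    (resp. end) are "start" (resp. "end") reads; support is true when at
    least ``min_support`` of their assembly-mapped mates lie within
    ``edge_window`` of a boundary of the top-ranked locus (the two read
    groups are assigned to distinct boundaries, maximizing total
    support).  Unplaced clones keep null edge fields.
    """
    if not placement.loci:
        return placement
    if vector_length is None:
        vector_length = vector_alignments.ref_lengths[0]
    win = min(vector_end_window, vector_length)  # clip to short vectors
    locus = placement.loci[0]

    is_start = vector_alignments.start < win
    is_end = vector_alignments.end > vector_length - win
    keys_start = set(zip(vector_alignments.qname[is_start].tolist(),
                         (3 - vector_alignments.mate[is_start]).tolist()))
    keys_end = set(zip(vector_alignments.qname[is_end].tolist(),
                       (3 - vector_alignments.mate[is_end]).tolist()))

    ref_sel = assembly_alignments.ref == assembly_alignments.ref_names.index(locus.scaffold)
    near_left = ref_sel & (np.abs(assembly_alignments.start - locus.start) <= edge_window)
    near_right = ref_sel & (np.abs(assembly_alignments.end - locus.end) <= edge_window)

    counts = {}
    for grp, keys in (("start", keys_start), ("end", keys_end)):
        for side, near in (("left", near_left), ("right", near_right)):
            idx = np.flatnonzero(near)
            c = sum(
                (assembly_alignments.qname[i], int(assembly_alignments.mate[i])) in keys
                for i in idx
            )
            counts[(grp, side)] = c
    # assign the two vector ends to distinct insert boundaries
    opt1 = counts[("start", "left")] + counts[("end", "right")]
    opt2 = counts[("start", "right")] + counts[("end", "left")]
    if opt1 >= opt2:
        start_count, end_count = counts[("start", "left")], counts[("end", "right")]
    else:
        start_count, end_count = counts[("start", "right")], counts[("end", "left")]
    placement.start_edge_count = int(start_count)
    placement.start_edge_support = start_count >= min_support
    placement.end_edge_count = int(end_count)
    placement.end_edge_support = end_count >= min_support
    return placement


@dataclass
class CrossMapReport:
    bac_id: str
    native: tuple[str, int, int]
    homolog: tuple[str, int, int]
    homolog_fraction_unmasked: float
    homolog_fraction_masked: float
    mismatch_rate_on_homolog: float


def cross_map_fraction(
    reads: list[str],
    assembly: dict[str, str],
    native: tuple[str, int, int],
    homolog: tuple[str, int, int],
    bac_id: str = "",
    paired: bool = True,
    k: int = 21,
    max_divergence: float = 0.06,
) -> CrossMapReport:
    """Mask-and-remap specificity check between homologous loci.

    Reads are mapped to the two loci twice - once as is and once with
    the native locus masked.  Low cross-mapping before masking, together
    with a jump onto the homolog (at an elevated mismatch rate) after
    masking, shows the two loci are real diverged homologs rather than a
    chimeric double assembly of one sequence.

    With ``paired`` (the default), consecutive reads (2i, 2i+1) are
    mates and each fragment is assigned as a unit - the sum of mate edit
    distances decides between the loci, as with a paired-end aligner;
    fragments scoring equally on both loci (SNP-free over their whole
    footprint) split between them by sequence hash, emulating random
    multi-mapper assignment.
    """
    if native[0] == homolog[0] and min(native[2], homolog[2]) > max(native[1], homolog[1]):
        raise ValueError("native and homolog intervals overlap")
    import zlib

    seqs = {
        "native": assembly[native[0]][native[1]:native[2]],
        "homolog": assembly[homolog[0]][homolog[1]:homolog[2]],
    }
    res = {
        name: map_reads(reads, ReferenceIndex({name: seq}, k=k),
                        max_divergence=max_divergence)
        for name, seq in seqs.items()
    }
    step = 2 if paired and len(reads) % 2 == 0 else 1
    n_frag = len(reads) // step
    lens = np.array([len(r) for r in reads], dtype=float)

    def frag_ed(name: str) -> np.ndarray:
        r = res[name]
        ed = np.where(r.mapped, r.edit_distance, np.inf)
        return ed.reshape(n_frag, step).sum(axis=1)

    ed_n, ed_h = frag_ed("native"), frag_ed("homolog")
    placed = np.isfinite(ed_n) | np.isfinite(ed_h)
    tie = placed & (ed_n == ed_h)
    tie_to_h = np.array(
        [bool(zlib.crc32(reads[i * step].encode()) & 1) for i in range(n_frag)]
    )
    on_h = placed & ((ed_h < ed_n) | (tie & tie_to_h))
    frac_open = float(on_h.sum() / n_frag) if n_frag else 0.0

    # masked: only the homolog locus remains mappable; any fragment assigned
    # to the homolog before masking can still map there, so after >= before
    placed_m = np.isfinite(ed_h)
    frac_masked = float(placed_m.sum() / n_frag) if n_frag else 0.0
    if placed_m.any():
        frag_len = lens.reshape(n_frag, step).sum(axis=1)
        mm = float(np.mean(ed_h[placed_m] / frag_len[placed_m]))
    else:
        mm = 0.0
    return CrossMapReport(
        bac_id, native, homolog, frac_open, frac_masked, mm,
    )
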