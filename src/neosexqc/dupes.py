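"""Erroneous-duplication and uncollapsed-haplotype detection.

When a read maps equally well to several places, aligners assign it to
one of them at random, so mapping one read pool twice with different
seeds makes duplicated regions visible: roughly half of their reads
switch primary placement between the two mappings.  Erroneously
duplicated assembly regions additionally drop to about half of the
genome-wide read depth (the real sample carries only one copy), while
true segmental duplications keep full depth; uncollapsed haplotypes are
switched regions spanning most of an unplaced contig.

Windows default to 10 kb.  "Roughly half" is operationalized as a
switch fraction >= 0.35 (binomial 0.5 minus a noise margin) and "half
depth" as a depth ratio <= 0.65; both are configurable - the published
criteria are verbal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignio import Placements
from .intervals import window_partition


@dataclass
class SwitchStats:
    """Per-window switch statistics over two replicate mappings.

    ``frame`` columns: scaffold, start, end, n_reads, n_switched,
    switch_fraction, depth_ratio, partner_scaffold, partner_start,
    partner_end, partner_support.  Each read contributes its window
    under *both* replicate placements, so the statistics are invariant
    under swapping the replicates.
    """

    frame: pd.DataFrame
    window: int
    scaffolds: list[str]
    scaffold_lengths: dict[str, int]
    unpaired_reads: int = 0


def _window_index(refs, starts, names):
    n_windows = np.bincount(refs, minlength=len(names))
    offsets = np.concatenate([[0], np.cumsum(n_windows)[:-1]])
    return offsets


def compute_switch_stats(
    rep1: Placements,
    rep2: Placements,
    window: int = 10_000,
    position_tolerance: int = 5,
) -> SwitchStats:
    """Compare primary placements of one read pool mapped twice.

    Rows of the two inputs must describe the same reads.  If both carry
    ``qname``, reads are joined on name (reads present in only one
    replicate are counted in ``unpaired_reads`` and excluded from the
    fractions); otherwise rows are paired by order.
    """
    if rep1.ref_names != rep2.ref_names:
        raise ValueError("replicates are mapped to different references")
    unpaired = 0
    if rep1.qname is not None and rep2.qname is not None:
        ids1 = [f"{q}/{m}" for q, m in zip(rep1.qname, rep1.mate)] if rep1.mate is not None \
            else [str(q) for q in rep1.qname]
        ids2 = [f"{q}/{m}" for q, m in zip(rep2.qname, rep2.mate)] if rep2.mate is not None \
            else [str(q) for q in rep2.qname]
        pos2 = {q: i for i, q in enumerate(ids2)}
        keep1, keep2 = [], []
        for i, q in enumerate(ids1):
            j = pos2.pop(q, None)
            if j is None:
                unpaired += 1
            else:
                keep1.append(i)
                keep2.append(j)
        unpaired += len(pos2)
        rep1 = rep1.subset(np.array(keep1, dtype=np.int64))
        rep2 = rep2.subset(np.array(keep2, dtype=np.int64))
    elif len(rep1) != len(rep2):
        raise ValueError("replicates without query names must have equal row counts")

    lengths = dict(zip(rep1.ref_names, rep1.ref_lengths))
    refs_w, starts_w, ends_w, names = window_partition(lengths, window)
    offsets = _window_index(refs_w, starts_w, names)

    switched = (rep1.ref != rep2.ref) | (
        np.abs(rep1.start - rep2.start) > position_tolerance
    )
    widx = [offsets[r.ref] + r.start // window for r in (rep1, rep2)]

    nw = len(starts_w)
    total = np.zeros(nw, dtype=np.int64)
    sw = np.zeros(nw, dtype=np.int64)
    bases = np.zeros(nw, dtype=np.float64)
    for k, r in enumerate((rep1, rep2)):
        np.add.at(total, widx[k], 1)
        np.add.at(sw, widx[k], switched)
        np.add.at(bases, widx[k], r.end - r.start)
    with np.errstate(invalid="ignore"):
        switch_fraction = np.where(total > 0, sw / np.maximum(total, 1), 0.0)
    depth = bases / 2.0 / (ends_w - starts_w)
    med = float(np.median(depth))
    depth_ratio = depth / med if med > 0 else depth

    # modal alternate placement per window, from both directions
    part_from = np.concatenate([widx[0][switched], widx[1][switched]])
    part_to = np.concatenate([widx[1][switched], widx[0][switched]])
    partner = np.full(nw, -1, dtype=np.int64)
    support = np.zeros(nw, dtype=np.int64)
    if len(part_from):
        df = pd.DataFrame({"w": part_from, "p": part_to})
        mode = (
            df.groupby(["w", "p"]).size().reset_index(name="n")
            .sort_values(["w", "n", "p"], ascending=[True, False, True])
            .drop_duplicates("w")
        )
        partner[mode["w"].to_numpy()] = mode["p"].to_numpy()
        support[mode["w"].to_numpy()] = mode["n"].to_numpy()

    frame = pd.DataFrame(
        {
            "scaffold": [names[r] for r in refs_w],
            "start": starts_w,
            "end": ends_w,
            "n_reads": total,
            "n_switched": sw,
            "switch_fraction": switch_fraction,
            "depth_ratio": depth_ratio,
            "partner_window": partner,
            "partner_support": support,
        }
    )
    return SwitchStats(frame, window, names, lengths, unpaired)


@dataclass
class DupCall:
    region_a: tuple[str, int, int]
    region_b: tuple[str, int, int]
    size: int
    mode: str  # erroneous_duplication | true_duplication | uncollapsed_haplotype
    mean_switch_fraction: float
    mean_depth_ratio: float
    low_confidence: bool = False


def call_duplications(
    stats: SwitchStats,
    min_size: int = 100_000,
    switch_min: float = 0.35,
    depth_low: float = 0.65,
    depth_high: float = 0.8,
    partner_consistency: float = 0.5,
    min_reads: int = 10,
    unplaced: set[str] | frozenset[str] = frozenset(),
) -> list[DupCall]:
    """Merge switched windows into paired duplicate regions.

    Adjacent windows (gaps of one window allowed) with a switch fraction
    >= ``switch_min`` are merged; a merged region is kept when at least
    ``partner_consistency`` of its switched reads agree on one partner
    region and its span is >= ``min_size``.  Mode is erroneous below the
    depth-ratio floor, true above the ceiling, and erroneous with a
    low-confidence flag in between; a region covering >= 90% of an
    unplaced contig is reported as an uncollapsed haplotype.  Symmetric
    pairs are emitted once.
    """
    df = stats.frame
    window = stats.window
    cand = (df["switch_fraction"].to_numpy() >= switch_min) & (
        df["n_reads"].to_numpy() >= min_reads
    )
    idx = np.flatnonzero(cand)
    if len(idx) == 0:
        return []
    refs = pd.factorize(df["scaffold"])[0]

    # group candidate windows into regions (same scaffold, gap <= 1 window)
    regions: list[list[int]] = []
    current = [int(idx[0])]
    for i in idx[1:]:
        prev = current[-1]
        if refs[i] == refs[prev] and i - prev <= 2:
            current.append(int(i))
        else:
            regions.append(current)
            current = [int(i)]
    regions.append(current)

    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    scafs = df["scaffold"].to_numpy()
    partner = df["partner_window"].to_numpy()
    support = df["partner_support"].to_numpy()
    n_switched = df["n_switched"].to_numpy()
    depth_ratio = df["depth_ratio"].to_numpy()
    switch_fraction = df["switch_fraction"].to_numpy()

    calls: list[DupCall] = []
    for wins in regions:
        a = (scafs[wins[0]], int(starts[wins[0]]), int(ends[wins[-1]]))
        if a[2] - a[1] < min_size:
            continue
        # modal partner region: merge this region's partner windows, take the
        # cluster backed by most switched reads
        pw = [(int(partner[w]), int(support[w])) for w in wins if partner[w] >= 0]
        if not pw:
            continue
        pw.sort()
        clusters: list[list[tuple[int, int]]] = [[pw[0]]]
        for w, s in pw[1:]:
            if w - clusters[-1][-1][0] <= 2:
                clusters[-1].append((w, s))
            else:
                clusters.append([(w, s)])
        best = max(clusters, key=lambda c: sum(s for _, s in c))
        modal_support = sum(s for _, s in best)
        total_switched = int(n_switched[wins].sum())
        if total_switched == 0 or modal_support / total_switched < partner_consistency:
            continue
        b_wins = [w for w, _ in best]
        b = (str(scafs[b_wins[0]]), int(starts[b_wins[0]]), int(ends[b_wins[-1]]))

        both = wins + b_wins
        mean_depth = float(np.mean(depth_ratio[both]))
        mean_switch = float(np.mean(switch_fraction[wins]))
        low_conf = False
        if mean_depth <= depth_low:
            mode = "erroneous_duplication"
        elif mean_depth >= depth_high:
            mode = "true_duplication"
        else:
            mode = "erroneous_duplication"
            low_conf = True
        for region in (a, b):
            scaf, s, e = region
            if scaf in unplaced and (e - s) >= 0.9 * stats.scaffold_lengths[scaf]:
                mode = "uncollapsed_haplotype"
        call = DupCall(a, b, a[2] - a[1], mode, mean_switch, mean_depth, low_conf)
        # symmetric pairs are found from both sides; keep one per reciprocal pair
        def _ovl(x, y):
            return x[0] == y[0] and min(x[2], y[2]) > max(x[1], y[1])

        dup = any(
            (_ovl(c.region_a, a) and _ovl(c.region_b, b))
            or (_ovl(c.region_a, b) and _ovl(c.region_b, a))
            for c in calls
        )
        if not dup:
            calls.append(call)
    return calls


def calls_to_frame(calls: list[DupCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "scaffold_a": c.region_a[0], "start_a": c.region_a[1], "end_a": c.region_a[2],
                "scaffold_b": c.region_b[0], "start_b": c.region_b[1], "end_b": c.region_b[2],
                "size": c.size, "mode": c.mode,
                "mean_switch_fraction": c.mean_switch_fraction,
                "mean_depth_ratio": c.mean_depth_ratio,
                "low_confidence": c.low_confidence,
            }
        )
    return pd.DataFrame(rows)
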