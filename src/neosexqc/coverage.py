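"""Sexed coverage tracks and contig sex-linkage classification.

Contigs are classified as autosomal, X-linked or Y-linked from the
female-to-male ratio of normalized read depth in fixed windows (50 kb by
default).  Expected normalized depth clusters are {female 1, male 1}
for autosomes, {1, 0.5} for X-linked and {0, 0.5} for Y-linked
sequence, so the F:M ratio sits near 1, 2 and infinity respectively;
the default thresholds bisect these clusters in log2 space and are all
configurable.  Per-contig medians (not means) are used, which keeps the
calls robust to repeat-driven coverage spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import Placements, UnknownReferenceError, from_sam
from .intervals import window_partition


@dataclass
class CoverageTrack:
    """Per-window mean depth (aligned bases / window length) for one sample."""

    scaffolds: list[str]
    window_ref: np.ndarray
    window_start: np.ndarray
    window_end: np.ndarray
    depth: np.ndarray
    sample: str
    window_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [self.scaffolds[r] for r in self.window_ref],
                "start": self.window_start,
                "end": self.window_end,
                "depth": self.depth,
            }
        )

    def same_partition(self, other: "CoverageTrack") -> bool:
        return (
            self.scaffolds == other.scaffolds
            and len(self.depth) == len(other.depth)
            and bool(np.array_equal(self.window_start, other.window_start))
            and bool(np.array_equal(self.window_end, other.window_end))
        )

    def scaled(self, factor: float, sample: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            self.scaffolds, self.window_ref, self.window_start, self.window_end,
            self.depth * factor, sample or self.sample, self.window_size,
        )


@dataclass
class ClassifyThresholds:
    """Cutoffs for the linkage rule; defaults bisect the {0, 1, 2} F:M clusters."""

    y_female_max: float = 0.1
    x_log2_ratio_min: float = 0.7
    auto_log2_ratio_max: float = 0.35
    male_depth_min: float = 0.2
    auto_depth_min: float = 0.5
    pseudodepth: float = 0.01


@dataclass
class LinkageCall:
    contig: str
    linkage: str  # autosomal | X-linked | Y-linked | ambiguous
    female_median: float
    male_median: float
    fm_ratio: float
    n_windows: int


def window_coverage(
    alignments: Placements | str,
    scaffold_lengths: dict[str, int] | None = None,
    window: int = 50_000,
    min_mapq: int = 20,
    sample: str = "",
) -> CoverageTrack:
    """Mean depth per fixed window: aligned bases overlapping the window
    divided by window length.

    ``alignments`` may be a :class:`Placements` or a SAM/BAM path.
    Reads below the mapping-quality floor are excluded (unmapped and
    secondary records never enter a ``Placements``).  When
    ``scaffold_lengths`` is given, alignments referencing unknown
    scaffolds raise :class:`UnknownReferenceError`.
    """
    if isinstance(alignments, str):
        alignments = from_sam(alignments, scaffold_lengths)
    pl = alignments
    if scaffold_lengths is None:
        scaffold_lengths = dict(zip(pl.ref_names, pl.ref_lengths))
    else:
        for name in pl.ref_names:
            if name not in scaffold_lengths:
                raise UnknownReferenceError(
                    f"alignment reference {name!r} not present in the assembly"
                )
    refs, starts, ends, names = window_partition(scaffold_lengths, window)
    # per-scaffold offsets into the global window arrays
    n_windows = np.zeros(len(names), dtype=np.int64)
    for r in range(len(names)):
        n_windows[r] = int((refs == r).sum())
    w_offset = np.concatenate([[0], np.cumsum(n_windows)[:-1]])
    name_to_local = {n: i for i, n in enumerate(names)}
    remap = np.array([name_to_local[n] for n in pl.ref_names], dtype=np.int64)

    bases = np.zeros(len(starts))
    keep = pl.mapq >= min_mapq
    r = remap[pl.ref[keep]]
    len_arr = np.array([scaffold_lengths[n] for n in names], dtype=np.int64)
    s = np.clip(pl.start[keep], 0, None)
    e = np.minimum(pl.end[keep], len_arr[r])
    w0 = s // window
    w1 = (e - 1) // window
    same = w0 == w1
    np.add.at(bases, w_offset[r[same]] + w0[same], (e - s)[same])
    # reads spanning a window boundary: split the two parts (reads <= window
    # span at most two windows)
    sp = ~same
    if sp.any():
        cut = (w0[sp] + 1) * window
        np.add.at(bases, w_offset[r[sp]] + w0[sp], cut - s[sp])
        np.add.at(bases, w_offset[r[sp]] + w1[sp], e[sp] - cut)
    depth = bases / (ends - starts)
    return CoverageTrack(names, refs, starts, ends, depth, sample, window)


def normalize_pair(
    female: CoverageTrack,
    male: CoverageTrack,
    thresholds: ClassifyThresholds | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Two-pass normalization so autosomal depth is 1 in both sexes.

    Pass 1 scales each track by its genome-wide median; pass 2 re-scales
    by the median over windows of contigs provisionally classified
    autosomal, making the two sexes directly comparable.
    """
    if not female.same_partition(male):
        raise ValueError("female and male tracks have different window partitions")
    th = thresholds or ClassifyThresholds()
    out = []
    for track in (female, male):
        med = float(np.median(track.depth))
        if med <= 0:
            raise ValueError(f"track {track.sample!r}: genome-wide median depth is zero")
        out.append(track.scaled(1.0 / med))
    # pass 2: anchor on provisionally autosomal windows.  Among windows
    # covered in both sexes the log2(F:M) ratio clusters 1 apart (autosomal
    # lowest, X-linked one above); the lower quartile of ratios lands in the
    # autosomal cluster whenever autosomes make up >= ~25% of such windows.
    covered = (out[0].depth > th.male_depth_min) & (out[1].depth > th.male_depth_min)
    if covered.any():
        r = np.log2(
            (out[0].depth[covered] + th.pseudodepth)
            / (out[1].depth[covered] + th.pseudodepth)
        )
        r0 = float(np.percentile(r, 25))
        anchor = np.zeros(len(out[0].depth), dtype=bool)
        anchor[np.flatnonzero(covered)[np.abs(r - r0) <= th.auto_log2_ratio_max]] = True
        if anchor.any():
            for i in range(2):
                med = float(np.median(out[i].depth[anchor]))
                if med > 0:
                    out[i] = out[i].scaled(1.0 / med)
    return out[0], out[1]


def classify_contigs(
    female: CoverageTrack,
    male: CoverageTrack,
    thresholds: ClassifyThresholds | None = None,
) -> list[LinkageCall]:
    """Per-contig linkage calls from medians of normalized depth.

    Rule (defaults): Y-linked if female median < 0.1 and male median
    > 0.2; X-linked if log2(F:M) >= 0.7 and male median > 0.2; autosomal
    if \\|log2(F:M)\\| <= 0.35 and both medians > 0.5; otherwise ambiguous.
    The F:M ratio uses a pseudodepth of 0.01 in both terms.
    """
    if not female.same_partition(male):
        raise ValueError("female and male tracks have different window partitions")
    th = thresholds or ClassifyThresholds()
    calls = []
    for r, contig in enumerate(female.scaffolds):
        sel = female.window_ref == r
        f = float(np.median(female.depth[sel]))
        m = float(np.median(male.depth[sel]))
        ratio = (f + th.pseudodepth) / (m + th.pseudodepth)
        log2r = np.log2(ratio)
        if f < th.y_female_max and m > th.male_depth_min:
            linkage = "Y-linked"
        elif log2r >= th.x_log2_ratio_min and m > th.male_depth_min:
            linkage = "X-linked"
        elif abs(log2r) <= th.auto_log2_ratio_max and f > th.auto_depth_min and m > th.auto_depth_min:
            linkage = "autosomal"
        else:
            linkage = "ambiguous"
        calls.append(LinkageCall(contig, linkage, f, m, float(ratio), int(sel.sum())))
    return calls


#: Mapping from planted linkage classes to the classifier's label space.
PLANTED_TO_CALL = {
    "autosomal": "autosomal",
    "X": "X-linked",
    "neoX": "X-linked",
    "Y": "Y-linked",
    "neoY": "Y-linked",
}


def calls_to_frame(calls: list[LinkageCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
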