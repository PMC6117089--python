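"""H3K9me3 window enrichment and centromere-candidate depletion testing.

Pericentromeric heterochromatin is strongly enriched for H3K9me3, but
functional centromeric repeats are partly wrapped by cenH3 nucleosomes
that replace canonical H3, so candidate centromeric satellite arrays
should show *reduced* H3K9me3 relative to the surrounding
pericentromere.  Enrichment is log2((ChIP + c)/(input + c)) in 10-kb
windows after library-size scaling (pseudocount c, default 1), and the
depletion is tested with a two-sided Wilcoxon rank-sum test between
array windows and other pericentromeric windows, assigned by majority
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import majority_in


class ChromatinError(ValueError):
    pass


@dataclass
class EnrichmentTrack:
    frame: pd.DataFrame  # scaffold, start, end, chip, input, log2_enrichment
    pseudocount: float

    def values(self) -> np.ndarray:
        return self.frame["log2_enrichment"].to_numpy()


def enrichment_track(
    chip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    pseudocount: float = 1.0,
) -> EnrichmentTrack:
    """Library-scaled log2 ChIP/input ratio per window.

    Both inputs need identical (scaffold, start, end) partitions and a
    ``count`` column.  ChIP counts are scaled by the median per-window
    input/ChIP ratio (median-of-ratios), which makes the track invariant
    to sequencing depth and anchors the unenriched background at 0 as
    long as background windows are the majority - a whole-genome
    library-total scaling would instead shift every window when
    enriched regions occupy a large genome fraction.
    """
    for col in ("scaffold", "start", "end"):
        if not chip_counts[col].equals(input_counts[col]):
            raise ChromatinError("ChIP and input window partitions differ")
    chip_arr = chip_counts["count"].to_numpy(dtype=float)
    input_arr = input_counts["count"].to_numpy(dtype=float)
    if chip_arr.sum() <= 0 or input_arr.sum() <= 0:
        raise ChromatinError("a library has zero total counts")
    size_factor = float(np.median((input_arr + pseudocount) / (chip_arr + pseudocount)))
    scaled = chip_arr * size_factor
    log2 = np.log2((scaled + pseudocount) / (input_arr + pseudocount))
    frame = chip_counts[["scaffold", "start", "end"]].copy()
    frame["chip"] = chip_counts["count"].to_numpy()
    frame["input"] = input_counts["count"].to_numpy()
    frame["log2_enrichment"] = log2
    return EnrichmentTrack(frame, pseudocount)


@dataclass
class DepletionTestResult:
    n_array_windows: int
    n_pericentromeric_windows: int
    array_median: float
    pericentromeric_median: float
    statistic: float
    p_value: float
    direction: int  # -1 depleted at arrays, +1 enriched, 0 equal


def assign_windows(
    track: EnrichmentTrack,
    array_intervals: list[tuple[str, int, int]],
    pericentromere_intervals: list[tuple[str, int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint window groups by majority overlap: array windows first,
    remaining pericentromeric windows second; everything else excluded."""
    df = track.frame
    by_scaf_arr: dict[str, list[tuple[int, int]]] = {}
    for scaf, s, e in array_intervals:
        by_scaf_arr.setdefault(scaf, []).append((s, e))
    by_scaf_peri: dict[str, list[tuple[int, int]]] = {}
    for scaf, s, e in pericentromere_intervals:
        by_scaf_peri.setdefault(scaf, []).append((s, e))
    in_arr = np.zeros(len(df), dtype=bool)
    in_peri = np.zeros(len(df), dtype=bool)
    for i, (scaf, s, e) in enumerate(zip(df["scaffold"], df["start"], df["end"])):
        if majority_in(s, e, by_scaf_arr.get(scaf, [])):
            in_arr[i] = True
        elif majority_in(s, e, by_scaf_peri.get(scaf, [])):
            in_peri[i] = True
    return in_arr, in_peri


def depletion_test(
    track: EnrichmentTrack,
    array_intervals: list[tuple[str, int, int]],
    pericentromere_intervals: list[tuple[str, int, int]],
) -> DepletionTestResult:
    """Two-sided Wilcoxon rank-sum test of array vs pericentromeric windows.

    Direction is the sign of (array median - pericentromeric median);
    depletion at candidate centromeric repeats shows as a negative
    direction with small p.  Each group needs at least 3 windows.
    """
    in_arr, in_peri = assign_windows(track, array_intervals, pericentromere_intervals)
    values = track.values()
    a, b = values[in_arr], values[in_peri]
    for name, grp in (("centromeric-array", a), ("pericentromeric", b)):
        if len(grp) < 3:
            raise ChromatinError(f"group {name!r} has {len(grp)} windows (< 3)")
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    diff = float(np.median(a) - np.median(b))
    return DepletionTestResult(
        int(in_arr.sum()), int(in_peri.sum()),
        float(np.median(a)), float(np.median(b)),
        float(stat.statistic), float(stat.pvalue),
        int(np.sign(diff)),
    )


def depletion_test_per_arm(
    track: EnrichmentTrack,
    array_intervals: list[tuple[str, int, int]],
    pericentromere_intervals: list[tuple[str, int, int]],
    min_windows: int = 3,
) -> dict[str, DepletionTestResult]:
    """Run the depletion test separately on each scaffold that carries at
    least ``min_windows`` windows in both groups (the default mode: arms
    differ in heterochromatin content, so pooling can mask arm-specific
    signals)."""
    out = {}
    for scaffold in track.frame["scaffold"].unique():
        sub_arr = [iv for iv in array_intervals if iv[0] == scaffold]
        sub_peri = [iv for iv in pericentromere_intervals if iv[0] == scaffold]
        if not sub_arr or not sub_peri:
            continue
        try:
            out[scaffold] = depletion_test(track, sub_arr, sub_peri)
        except ChromatinError:
            continue
    return out
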