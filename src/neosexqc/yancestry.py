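"""Y-derived sequence identification by subtractive mapping.

Given a related species with male-only and female-only assemblies,
putative Y-linked scaffolds are those essentially absent from the
female assembly (aligned-base fraction below a threshold; the published
procedure gives no number, 0.1 is the default and configurable).  Male
reads are then distilled to a male-specific set: reads must map to the
male-specific scaffolds and must not map to the female assembly -
"mapped" means any primary alignment, regardless of quality, which is
the strictest subtraction and maximizes specificity.  Mapping the
retained reads onto a target Y assembly and scoring the density of
nonzero 10-kb windows per scaffold (or arm) reveals which parts of the
target Y share ancestry with the other species' Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import union_length


@dataclass
class ScaffoldSpecificity:
    scaffold: str
    aligned_fraction: float
    male_specific: bool
    missing_from_alignments: bool = False


def find_male_specific_scaffolds(
    alignments: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    aligned_fraction_threshold: float = 0.1,
    min_alignment_length: int = 1_000,
) -> list[ScaffoldSpecificity]:
    """Flag male-assembly scaffolds absent from the female assembly.

    ``alignments`` holds whole-genome alignment blocks in male-assembly
    coordinates (columns ``scaffold``, ``start``, ``end``; PAF/coords
    style).  The aligned fraction is the union of blocks of at least
    ``min_alignment_length`` bp over the scaffold length; scaffolds
    missing from the input get fraction 0 with a warning flag.
    """
    keep = (alignments["end"] - alignments["start"]) >= min_alignment_length
    alignments = alignments[keep]
    out = []
    for scaffold, length in scaffold_lengths.items():
        sub = alignments[alignments["scaffold"] == scaffold]
        if len(sub) == 0:
            frac = 0.0
            missing = scaffold not in set(alignments["scaffold"])
        else:
            frac = union_length(list(zip(sub["start"], sub["end"]))) / length
            missing = False
        out.append(
            ScaffoldSpecificity(scaffold, float(frac),
                                frac < aligned_fraction_threshold, missing)
        )
    return out


def filter_male_specific_reads(
    mapped_to_male_specific,
    mapped_to_female,
) -> list:
    """Subtractive read filter: keep reads mapped to the male-specific
    scaffolds AND unmapped to the female assembly.

    Arguments are iterables of read ids (any hashable); the retained set
    is returned sorted for determinism.  Enlarging the female set can
    only shrink the result.
    """
    ms = set(mapped_to_male_specific)
    fem = set(mapped_to_female)
    return sorted(ms - fem)


@dataclass
class DensityTrack:
    frame: pd.DataFrame  # scaffold, start, end, coverage (reads overlapping)
    window: int
    density: dict[str, float]  # per scaffold: nonzero windows / total windows


def y_density(
    read_positions: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    window: int = 10_000,
) -> DensityTrack:
    """Read coverage in 10-kb nonoverlapping windows on the target Y and
    the per-scaffold density of nonzero windows.

    ``read_positions`` columns: ``scaffold``, ``start`` (read start,
    0-based).  Density is nonzero windows / total windows, in [0, 1].
    """
    rows = []
    density = {}
    for scaffold, length in scaffold_lengths.items():
        nw = max(1, -(-length // window))
        counts = np.zeros(nw, dtype=np.int64)
        sub = read_positions[read_positions["scaffold"] == scaffold]
        if len(sub):
            w = (sub["start"].to_numpy() // window).astype(np.int64)
            w = w[(w >= 0) & (w < nw)]
            np.add.at(counts, w, 1)
        for i in range(nw):
            rows.append({"scaffold": scaffold, "start": i * window,
                         "end": min((i + 1) * window, length),
                         "coverage": int(counts[i])})
        density[scaffold] = float((counts > 0).sum() / nw)
    return DensityTrack(pd.DataFrame(rows), window, density)


def density_of_interval(track: DensityTrack, scaffold: str, start: int, end: int) -> float:
    """Nonzero-window density restricted to one interval (e.g. a chromosome arm)."""
    df = track.frame
    sel = (df["scaffold"] == scaffold) & (df["start"] >= start) & (df["end"] <= end)
    sub = df[sel]
    if len(sub) == 0:
        return 0.0
    return float((sub["coverage"] > 0).sum() / len(sub))
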