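"""Satellite discovery, motif collapsing and centromere-diagnostic periodicity.

Tandem arrays are detected (or imported from a tandem-repeat-finder
``.dat`` report), their unit motifs are collapsed into families under
the 90/90 rule - two motifs belong together when they align at over 90%
identity over more than 90% of their length, testing all rotations,
both strands and higher-order multimers of the shorter unit - and each
family's genome abundance is quantified as masked bases.  Candidate
centromeric families are flagged by the 10-bp periodicity of AA/TT/AT
dinucleotides typical of centromeric satellites (sequences with A/T
dinucleotides phased to the ~10-bp helical turn wrap nucleosomes
cheaply).

Tandem units are circular, so rotation handling matters: instead of
local alignment with its edge effects, one unit is rotated explicitly
against the other under global alignment, which preserves the 90/90
threshold semantics.  Identity counts matches over all alignment
columns; gap columns count against both identity and coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .alignio import revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


class SatelliteError(ValueError):
    pass


@dataclass
class TandemArray:
    scaffold: str
    start: int
    end: int
    unit_length: int
    copy_number: float
    consensus: str
    percent_matches: float


# ---------------------------------------------------------------------------
# detection


def _true_runs(mask: np.ndarray):
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = idx[np.concatenate([[0], breaks + 1])]
    ends = idx[np.concatenate([breaks, [len(idx) - 1]])] + 1
    return starts, ends


def _consensus(arr: np.ndarray, start: int, end: int, period: int):
    n_copies = (end - start) // period
    if n_copies < 1:
        return "", 0.0
    block = arr[start : start + n_copies * period].reshape(n_copies, period)
    counts = np.zeros((4, period), dtype=np.int64)
    for b in range(4):
        counts[b] = (block == b).sum(axis=0)
    cons = counts.argmax(axis=0).astype(np.uint8)
    matches = (block == cons).sum() / block.size
    return bytes(np.frombuffer(b"ACGT", np.uint8)[cons]).decode(), float(matches)


def detect_tandem_arrays(
    sequence: str,
    scaffold: str = "",
    min_period: int = 2,
    max_period: int = 120,
    min_copies: float = 3.0,
    min_length: int = 50,
    min_match: float = 0.85,
    seed_run: int = 12,
    max_gap: int | None = None,
) -> list[TandemArray]:
    """Internal tandem-array detector (self-match at candidate periods).

    For each period p, positions where the sequence equals itself shifted
    by p are computed; long match runs (allowing short gaps from
    substitutions) seed arrays, which must reach ``min_copies`` copies,
    ``min_length`` bp and ``min_match`` self-match fraction.  Periods are
    scanned ascending and regions already claimed by a shorter period
    are skipped, so each array is reported at its minimal period.
    """
    arr = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    n = len(arr)
    claimed = np.zeros(n, dtype=bool)
    out: list[TandemArray] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        eq = arr[p:] == arr[:-p]
        starts, ends = _true_runs(eq)
        keep = (ends - starts) >= min(seed_run, p * 2)
        starts, ends = starts[keep], ends[keep]
        if len(starts) == 0:
            continue
        # chain nearby runs; substitutions break runs at two offsets and can
        # leave sub-seed fragments between kept runs, so the chain gap scales
        # with the period (the min_match check vetoes spurious chains)
        gap_limit = max(10, p) if max_gap is None else max_gap
        merged = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= gap_limit:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            length = e - s + p
            if length < max(min_length, min_copies * p):
                continue
            frac = float(eq[s:e].mean()) * (e - s) / length
            # self-match fraction over the whole candidate span
            frac = float(eq[s:e].sum()) / (e - s)
            if frac < min_match:
                continue
            if claimed[s : s + length].mean() >= 0.5:
                continue
            cons, pm = _consensus(arr, s, s + length, p)
            out.append(
                TandemArray(scaffold, s, s + length, p, length / p, cons, pm)
            )
            claimed[s : s + length] = True
    out.sort(key=lambda a: (a.start, a.end))
    return out


def detect_tandem_arrays_genome(genome: dict[str, str], **kw) -> list[TandemArray]:
    out = []
    for name, seq in genome.items():
        out.extend(detect_tandem_arrays(seq, scaffold=name, **kw))
    return out


# ---------------------------------------------------------------------------
# TRF .dat dialect


def import_tandem_report(path: str) -> list[TandemArray]:
    """Parse a tandem-repeat-finder ``.dat`` report.

    Records are ``start end period copy_number consensus_size
    percent_matches percent_indels score A C G T entropy consensus
    sequence`` with 1-based inclusive coordinates; they are converted to
    0-based half-open.  A malformed record raises
    :class:`SatelliteError` with its line number.
    """
    arrays: list[TandemArray] = []
    scaffold = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                scaffold = line.split(":", 1)[1].strip().split()[0]
                continue
            if line.startswith(("Parameters:", "Tandem Repeats Finder", "Gary Benson",
                                "Program written", "Boston University", "Version")):
                continue
            fields = line.split()
            if not fields[0].lstrip("-").isdigit():
                continue
            try:
                start = int(fields[0]) - 1
                end = int(fields[1])
                period = int(fields[2])
                copy_number = float(fields[3])
                percent_matches = float(fields[5])
                consensus = fields[13]
            except (IndexError, ValueError) as exc:
                raise SatelliteError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if start < 0 or end <= start or period < 1:
                raise SatelliteError(f"{path}:{lineno}: invalid coordinates/period")
            arrays.append(
                TandemArray(scaffold, start, end, period, copy_number,
                            consensus, percent_matches / 100.0)
            )
    return arrays


def export_tandem_report(path: str, arrays: list[TandemArray]) -> None:
    with open(path, "w") as fh:
        current = None
        for a in sorted(arrays, key=lambda x: (x.scaffold, x.start)):
            if a.scaffold != current:
                fh.write(f"Sequence: {a.scaffold}\n")
                fh.write("Parameters: 2 7 7 80 10 50 500\n")
                current = a.scaffold
            cons = a.consensus
            counts = {b: 100.0 * cons.count(b) / max(len(cons), 1) for b in "ACGT"}
            fh.write(
                f"{a.start + 1} {a.end} {a.unit_length} {a.copy_number:.1f} "
                f"{len(cons)} {a.percent_matches * 100:.0f} 0 0 "
                f"{counts['A']:.0f} {counts['C']:.0f} {counts['G']:.0f} {counts['T']:.0f} "
                f"0.0 {cons} {cons}\n"
            )


# ---------------------------------------------------------------------------
# collapsing (90/90 rule)


def canonical_unit(unit: str) -> str:
    """Lexicographically minimal rotation over both strands."""
    best = None
    for s in (unit, revcomp(unit)):
        for r in range(len(s)):
            rot = s[r:] + s[:r]
            if best is None or rot < best:
                best = rot
    return best


def _global_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, mutual coverage) of a global alignment.

    Identity is matches / alignment columns (gap columns count against
    it); coverage is aligned (non-gap) columns over each sequence's
    length, minimized over the two.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    eq = x = ins = dele = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch == "=":
                eq += n
            elif ch == "X":
                x += n
            elif ch == "I":
                ins += n
            elif ch == "D":
                dele += n
    columns = eq + x + ins + dele
    identity = eq / columns if columns else 0.0
    aligned = eq + x
    coverage = min(aligned / len(a), aligned / len(b)) if a and b else 0.0
    return identity, coverage


def motif_match(
    a: str,
    b: str,
    identity: float = 0.90,
    coverage: float = 0.90,
    max_multimer: int = 8,
    length_tolerance: float = 0.25,
) -> dict | None:
    """Best rotation/strand/multimer alignment of two tandem units.

    The shorter unit is expanded k-fold (k <= ``max_multimer``) whenever
    k x its length is within ``length_tolerance`` of the longer length;
    every rotation of the longer unit and both strands are tried.
    Returns the best passing configuration or None.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = None
    for k in range(1, max_multimer + 1):
        if abs(k * len(short) - len(long_)) > length_tolerance * len(long_):
            continue
        expanded = short * k
        for strand, seq in ((0, expanded), (1, revcomp(expanded))):
            for r in range(len(long_)):
                rot = long_[r:] + long_[:r]
                ident, cov = _global_identity(seq, rot)
                if ident >= identity and cov >= coverage:
                    cand = {"identity": ident, "coverage": cov, "k": k,
                            "rotation": r, "strand": strand}
                    if best is None or ident > best["identity"]:
                        best = cand
    return best


@dataclass
class MotifFamily:
    family_id: str
    canonical: str
    members: list[dict]  # motif, k, rotation, strand vs canonical
    total_masked_bases: int = 0
    array_count: int = 0


def collapse_motifs(
    motifs: list[str] | list[TandemArray],
    identity: float = 0.90,
    coverage: float = 0.90,
    max_multimer: int = 8,
) -> list[MotifFamily]:
    """Group motifs into families: connected components of the 90/90 graph.

    The family consensus is the canonical form of the shortest member's
    unit; members record the multimer order (k), rotation and strand at
    which they join the family.
    """
    units = [m.consensus if isinstance(m, TandemArray) else m for m in motifs]
    n = len(units)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges: dict[tuple[int, int], dict] = {}
    for i in range(n):
        for j in range(i + 1, n):
            m = motif_match(units[i], units[j], identity, coverage, max_multimer)
            if m is not None:
                edges[(i, j)] = m
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    families = []
    for fid, members in enumerate(sorted(groups.values(), key=lambda g: min(g))):
        shortest = min(members, key=lambda i: (len(units[i]), units[i]))
        canon = canonical_unit(units[shortest])
        rows = []
        for i in members:
            ann = motif_match(canon, units[i], identity, coverage, max_multimer) or {}
            rows.append({"motif": units[i], "index": i,
                         "k": ann.get("k", 1), "rotation": ann.get("rotation", 0),
                         "strand": ann.get("strand", 0)})
        families.append(MotifFamily(f"fam{fid:03d}", canon, rows))
    return families


# ---------------------------------------------------------------------------
# abundance


def quantify_abundance(
    genome: dict[str, str],
    families: list[MotifFamily],
    arrays: list[TandemArray] | None = None,
    window: int = 10_000,
    **detect_kw,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Masked bases per family, greedily non-overlapping, plus a window track.

    Arrays (detected here unless supplied) are assigned to the family
    whose canonical unit they match under the 90/90 rule; competing
    assignments at one position resolve to the longest array first.
    """
    if arrays is None:
        arrays = detect_tandem_arrays_genome(genome, **detect_kw)
    totals = {f.family_id: 0 for f in families}
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for a in sorted(arrays, key=lambda x: (-(x.end - x.start), x.scaffold, x.start)):
        fam = None
        for f in families:
            if motif_match(f.canonical, a.consensus) is not None:
                fam = f
                break
        if fam is None:
            continue
        ivals = occupied.setdefault(a.scaffold, [])
        if any(min(e, a.end) > max(s, a.start) for s, e in ivals):
            continue  # greedy non-overlap
        ivals.append((a.start, a.end))
        totals[fam.family_id] += a.end - a.start
        fam.array_count += 1
        rows.append({"scaffold": a.scaffold, "start": a.start, "end": a.end,
                     "family": fam.family_id})
    for f in families:
        f.total_masked_bases = totals[f.family_id]

    track_rows = []
    for name, seq in genome.items():
        nw = -(-len(seq) // window)
        masked = {f.family_id: np.zeros(nw, dtype=np.int64) for f in families}
        for r in rows:
            if r["scaffold"] != name:
                continue
            w0, w1 = r["start"] // window, (r["end"] - 1) // window
            for w in range(w0, w1 + 1):
                lo, hi = w * window, min((w + 1) * window, len(seq))
                masked[r["family"]][w] += max(0, min(r["end"], hi) - max(r["start"], lo))
        for w in range(nw):
            row = {"scaffold": name, "start": w * window,
                   "end": min((w + 1) * window, len(seq))}
            row.update({fid: int(masked[fid][w]) for fid in masked})
            track_rows.append(row)
    return totals, pd.DataFrame(track_rows)


# ---------------------------------------------------------------------------
# AA/TT/AT periodicity


@dataclass
class PeriodicityProfile:
    lags: np.ndarray
    scores: np.ndarray  # indexed by lag (scores[lag])
    peak_lag: int
    prominence: float


def at_indicator(seq: str, circular: bool = True,
                 include_trinucleotides: bool = False) -> np.ndarray:
    """1 at start positions of AA/TT/AT (optionally A/T-only trinucleotides)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr)
    nxt = np.roll(arr, -1) if circular else arr[1:]
    cur = arr if circular else arr[:-1]
    is_a, is_t = cur == 0, cur == 3
    na, nt = nxt == 0, nxt == 3
    hit = (is_a & na) | (is_t & nt) | (is_a & nt)
    if include_trinucleotides:
        n2 = np.roll(arr, -2) if circular else arr[2:]
        at2 = (n2 == 0) | (n2 == 3)
        tri = ((is_a | is_t) & (na | nt) & at2[: len(hit)])
        hit = hit | tri
    x = np.zeros(n if circular else n - 1, dtype=float)
    x[: len(hit)] = hit
    return x


def periodicity_from_indicator(
    x: np.ndarray, max_lag: int = 50, circular: bool = True
) -> PeriodicityProfile:
    n = len(x)
    d = x.mean()
    lags = np.arange(0, max_lag + 1)
    scores = np.zeros(max_lag + 1)
    if d > 0:
        for lag in range(1, max_lag + 1):
            if circular:
                c = float(np.mean(x * np.roll(x, -lag)))
            else:
                if lag >= n:
                    break
                c = float(np.mean(x[:-lag] * x[lag:]))
            scores[lag] = c / d**2
    search = scores[2 : max_lag + 1]
    peak_lag = int(np.argmax(search)) + 2 if len(search) else 0
    ref = scores[5 : min(51, max_lag + 1)]
    med = float(np.median(ref)) if len(ref) else 0.0
    if med > 0:
        prominence = float(scores[peak_lag] / med)
    else:
        prominence = float("inf") if scores[peak_lag] > 0 else 0.0
    return PeriodicityProfile(lags, scores, peak_lag, prominence)


def periodicity_profile(
    sequence: str,
    max_lag: int = 50,
    circular: bool = True,
    include_trinucleotides: bool = False,
) -> PeriodicityProfile:
    """AA/TT/AT autocorrelation profile of a consensus unit or array.

    Consensus units are analyzed circularly (they live in tandem
    context); pass ``circular=False`` for linear array sequence.  The
    score at lag L is the autocorrelation of the dinucleotide indicator
    normalized by its density squared, so 1 means "no structure";
    prominence is the peak score over the median score at lags 5-50.
    """
    if len(sequence) < 4:
        raise SatelliteError("sequence shorter than 4 bp")
    x = at_indicator(sequence, circular, include_trinucleotides)
    return periodicity_from_indicator(x, max_lag, circular)
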