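"""Tandem and dispersed repeat detection in plastome sequences.

Two detectors:

* :func:`find_ssrs` — perfect simple sequence repeats (SSRs): maximal
  tandem runs of a primitive 1–6 nt motif, reported leftmost, above a
  per-unit-length minimum repeat count (MISA-web defaults: 10 for mono,
  6 for di, 5 for tri/tetra/penta/hexa).
* :func:`find_long_repeats` — dispersed forward and palindromic repeats of
  at least 30 bp allowing up to 3 mismatches (Hamming), found by exact
  k-mer seeding followed by per-diagonal maximal-window enumeration.  A
  plastome's inverted-repeat pair shows up as one giant palindromic hit;
  callers typically drop hits longer than a few kb before summarising.

Every reported repeat re-validates against the raw sequence by
construction (coordinates are derived from direct comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import reverse_complement

__all__ = [
    "SsrRecord",
    "LongRepeat",
    "DEFAULT_SSR_THRESHOLDS",
    "find_ssrs",
    "find_long_repeats",
    "summarize_repeats",
    "merge_compound",
    "canonical_motif_family",
]

DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SsrRecord:
    motif: str          # unit as found in the sequence
    motif_family: str   # canonical: min over cyclic rotations and revcomp
    unit_len: int
    repeats: int
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive; may exceed genome length on wrap

    @property
    def length(self) -> int:
        return self.unit_len * self.repeats


@dataclass(frozen=True)
class LongRepeat:
    kind: str           # 'forward' | 'palindromic'
    length: int
    pos1: int           # 1-based start of first copy
    pos2: int           # 1-based start of second copy
    mismatches: int

    @property
    def score(self) -> int:
        """Matches minus mismatches, for reference."""
        return self.length - 2 * self.mismatches


def canonical_motif_family(motif: str) -> str:
    """Lexicographic minimum over cyclic rotations of the motif and of its
    reverse complement, so e.g. AT, TA both map to 'AT' and AAG/GAA/CTT map
    to one family."""
    rc = reverse_complement(motif)
    candidates = [
        m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))
    ]
    return min(candidates)


def _is_primitive(unit: str) -> bool:
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def find_ssrs(
    seq: str,
    thresholds: dict[int, int] | None = None,
    circular: bool = False,
) -> list[SsrRecord]:
    """Maximal perfect SSRs above the per-unit-length repeat thresholds.

    Only complete units count toward ``repeats``.  Motifs that are powers of
    a shorter unit are skipped (a poly-A run is a mononucleotide SSR, never
    an AA dinucleotide one), and an SSR wholly contained in a longer SSR of
    another unit length is suppressed.  With ``circular=True`` the scan
    appends a short overlap window so origin-spanning runs are caught; their
    ``end`` coordinate then exceeds the sequence length.
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        return []
    scan = seq
    if circular:
        overlap = min(n, 6 * (max(thresholds.values()) + 60))
        scan = seq + seq[:overlap]
    found: list[SsrRecord] = []
    for p, min_rep in sorted(thresholds.items()):
        m = len(scan)
        i = 0
        while i + p * min_rep <= m:
            unit = scan[i : i + p]
            if not _is_primitive(unit) or (set(unit) - set("ACGT")):
                i += 1
                continue
            if i >= p and scan[i - p : i] == unit:
                i += 1  # not leftmost for this phase
                continue
            j = i + p
            while j + p <= m and scan[j : j + p] == unit:
                j += p
            k = (j - i) // p
            # remainder of the periodic region (partial unit at the tail)
            r = 0
            while j + r < m and scan[j + r] == unit[r % p]:
                r += 1
            if k >= min_rep and i < n:
                found.append(
                    SsrRecord(
                        motif=unit,
                        motif_family=canonical_motif_family(unit),
                        unit_len=p,
                        repeats=k,
                        start=i + 1,
                        end=i + p * k,
                    )
                )
            # a different-motif run may start up to p-1 bases before the end
            # of this periodic region, so do not jump fully past it
            i = max(j + r - (p - 1), i + 1) if k >= 2 else i + 1
    # suppress SSRs nested inside a longer SSR of another unit length
    found.sort(key=lambda s: (s.start, -(s.end)))
    kept: list[SsrRecord] = []
    for ssr in found:
        if any(
            o.unit_len != ssr.unit_len and o.start <= ssr.start and ssr.end <= o.end
            and o.length > ssr.length
            for o in found
        ):
            continue
        kept.append(ssr)
    kept.sort(key=lambda s: (s.start, s.unit_len))
    return kept


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------


def _enumerate_windows(
    lbar: int, rbar: int, mismatches: list[int], budget: int, min_len: int
) -> list[tuple[int, int, int]]:
    """Maximal windows within the open span (lbar, rbar) holding at most
    ``budget`` of the listed mismatch positions, ends trimmed onto matches,
    length >= min_len.  Returns (left, right, n_mismatch) triples."""
    import bisect

    ms = sorted(set(mismatches))
    zset = set(ms)
    m = len(ms)
    bounds = [lbar] + ms + [rbar]
    b = min(budget, m)
    candidates = []
    for i in range(0, m - b + 1):
        left = bounds[i] + 1
        right = bounds[i + b + 1] - 1
        while left <= right and left in zset:
            left += 1
        while right >= left and right in zset:
            right -= 1
        if right - left + 1 < min_len:
            continue
        mism = bisect.bisect_right(ms, right) - bisect.bisect_left(ms, left)
        candidates.append((left, right, mism))
    candidates = sorted(set(candidates))
    out = []
    for c in candidates:
        if any(
            (o[0], o[1]) != (c[0], c[1]) and o[0] <= c[0] and c[1] <= o[1]
            for o in candidates
        ):
            continue
        out.append(c)
    return out


def _scan_diagonal(
    x: bytes,
    y: bytes,
    d: int,
    seeds: list[int],
    budget: int,
    min_len: int,
    seed_len: int,
) -> list[tuple[int, int, int]]:
    """All maximal mismatch-budgeted windows on the diagonal ``x[t] vs
    y[t+d]`` that can contain a seed.  Walks outward from seed clusters only
    until the budget is exhausted, so work is proportional to matched area,
    not diagonal length."""
    lo = max(0, -d)
    hi = min(len(x), len(y) - d)
    if hi - lo < min_len:
        return []
    seeds = sorted(set(seeds))
    out: list[tuple[int, int, int]] = []
    j = 0
    while j < len(seeds):
        t0 = seeds[j]
        # collect up to budget+1 mismatches to the left; the last is a barrier
        left_ms: list[int] = []
        t = t0 - 1
        while t >= lo and len(left_ms) <= budget:
            if x[t] != y[t + d]:
                left_ms.append(t)
            t -= 1
        if len(left_ms) > budget:
            lbar = left_ms[-1]
            left_keep = left_ms[:-1]
        else:
            lbar = lo - 1
            left_keep = left_ms
        # walk right, chaining through any further seeds on the way
        ms_right: list[int] = []
        covered_seed = t0
        t = t0
        rbar = hi
        while t < hi:
            while j + 1 < len(seeds) and seeds[j + 1] <= t:
                j += 1
                covered_seed = seeds[j]
            if x[t] != y[t + d]:
                ms_right.append(t)
                since = sum(1 for m in ms_right[-(budget + 1):] if m > covered_seed)
                if since > budget and (
                    j + 1 >= len(seeds) or seeds[j + 1] > t
                ):
                    rbar = t
                    break
            t += 1
        ms = left_keep[::-1] + [m for m in ms_right if m < rbar]
        out.extend(_enumerate_windows(lbar, rbar, ms, budget, min_len))
        j += 1
    return out


def _seed_index(s: bytes, k: int, cap: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        hits = index.setdefault(kmer, [])
        if len(hits) < cap:
            hits.append(i)
    return index


def find_long_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    seed_len: int = 7,
    max_kmer_hits: int = 1000,
) -> list[LongRepeat]:
    """Maximal forward and palindromic repeat pairs under Hamming distance.

    A window of length >= ``min_len`` with at most ``max_mismatch``
    mismatches contains an exact run of at least ceil((min_len −
    max_mismatch)/(max_mismatch + 1)) bp, so ``seed_len=7`` guarantees full
    sensitivity at the 30 bp / 3 mismatch defaults.  ``max_kmer_hits`` caps
    index bucket size in extremely low-complexity regions (detection there
    may be incomplete; such regions are SSR territory).
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_len:
        return []
    if seed_len > -((min_len - max_mismatch) // -(max_mismatch + 1)):
        raise ValueError("seed_len too large for the sensitivity guarantee")
    s = seq.encode()
    rc = reverse_complement(seq).encode()
    out: set[LongRepeat] = set()

    # forward: diagonals d = pos2 - pos1 > 0, seeds keyed per diagonal
    index = _seed_index(s, seed_len, max_kmer_hits)
    fwd_seeds: dict[int, list[int]] = {}
    for hits in index.values():
        for a_i in range(len(hits)):
            for b_i in range(a_i + 1, len(hits)):
                fwd_seeds.setdefault(hits[b_i] - hits[a_i], []).append(hits[a_i])
    for d, seeds in fwd_seeds.items():
        for left, right, mism in _scan_diagonal(
            s, s, d, seeds, max_mismatch, min_len, seed_len
        ):
            length = right - left + 1
            out.add(LongRepeat("forward", length, left + 1, left + d + 1, mism))

    # palindromic: seq vs its reverse complement; diagonal D = u - i
    rc_index = _seed_index(rc, seed_len, max_kmer_hits)
    pal_seeds: dict[int, list[int]] = {}
    for i in range(n - seed_len + 1):
        kmer = s[i : i + seed_len]
        for u in rc_index.get(kmer, ()):
            pal_seeds.setdefault(u - i, []).append(i)
    for dd, seeds in pal_seeds.items():
        for left, right, mism in _scan_diagonal(
            s, rc, dd, seeds, max_mismatch, min_len, seed_len
        ):
            length = right - left + 1
            i1 = left
            j1 = n - (left + dd) - length  # start of the partner copy in seq
            if i1 == j1:
                continue  # self-palindrome, not a repeat pair
            p1, p2 = sorted((i1, j1))
            out.add(LongRepeat("palindromic", length, p1 + 1, p2 + 1, mism))

    return sorted(out, key=lambda r: (r.kind, r.pos1, r.pos2, -r.length))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def merge_compound(ssrs: list[SsrRecord], max_gap: int = 100) -> list[list[SsrRecord]]:
    """Group SSRs whose neighbours start within ``max_gap`` bp of the
    previous SSR's end (MISA's compound-SSR reporting, as a view only)."""
    groups: list[list[SsrRecord]] = []
    for ssr in sorted(ssrs, key=lambda s: s.start):
        if groups and ssr.start - groups[-1][-1].end <= max_gap:
            groups[-1].append(ssr)
        else:
            groups.append([ssr])
    return groups


def summarize_repeats(
    ssrs: list[SsrRecord],
    long_repeats: list[LongRepeat],
    bin_width: int = 10,
) -> dict:
    """Tallies: SSR counts/percentages by unit length, A/T vs G/C motif
    split, long-repeat counts by kind and by length bin (30–39, 40–49, ...)."""
    total = len(ssrs)
    by_unit = {name: 0 for name in _UNIT_NAMES.values()}
    at = gc = mixed = 0
    for s in ssrs:
        by_unit[_UNIT_NAMES[s.unit_len]] += 1
        letters = set(s.motif_family)
        if letters <= {"A", "T"}:
            at += 1
        elif letters <= {"G", "C"}:
            gc += 1
        else:
            mixed += 1
    pct = {
        name: (100.0 * cnt / total if total else 0.0)
        for name, cnt in by_unit.items()
    }
    kinds = {"forward": 0, "palindromic": 0}
    bins: dict[str, int] = {}
    for r in long_repeats:
        kinds[r.kind] = kinds.get(r.kind, 0) + 1
        lo = (r.length // bin_width) * bin_width
        label = f"{lo}-{lo + bin_width - 1}"
        bins[label] = bins.get(label, 0) + 1
    return {
        "ssr_total": total,
        "ssr_by_unit": by_unit,
        "ssr_percent_by_unit": pct,
        "ssr_motif_split": {"AT": at, "GC": gc, "mixed": mixed},
        "long_repeat_total": len(long_repeats),
        "long_repeat_by_kind": kinds,
        "long_repeat_by_length_bin": dict(sorted(bins.items())),
    }


def ssr_frame(ssrs: list[SsrRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": s.motif, "family": s.motif_family, "unit_len": s.unit_len,
                "repeats": s.repeats, "start": s.start, "end": s.end,
            }
            for s in ssrs
        ],
        columns=["motif", "family", "unit_len", "repeats", "start", "end"],
    )


def long_repeat_frame(reps: list[LongRepeat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": r.kind, "length": r.length, "pos1": r.pos1,
                "pos2": r.pos2, "mismatches": r.mismatches,
            }
            for r in reps
        ],
        columns=["kind", "length", "pos1", "pos2", "mismatches"],
    )
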