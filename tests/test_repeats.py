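"""SSR and dispersed-repeat detection against brute-force oracles."""

import numpy as np
import pytest

from plastcub.genome_io import reverse_complement
from plastcub.repeats import (
    DEFAULT_SSR_THRESHOLDS,
    canonical_motif_family,
    find_long_repeats,
    find_ssrs,
    merge_compound,
    summarize_repeats,
)
from plastcub.synthetic_data import SyntheticSpec, generate_genome


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def _primitive(unit: str) -> bool:
    return all(
        unit != unit[:d] * (len(unit) // d)
        for d in range(1, len(unit))
        if len(unit) % d == 0
    )


def brute_ssrs(seq: str, thresholds=None):
    """Exhaustive O(n*6) SSR scan: every maximal, leftmost, primitive
    perfect tandem run above threshold; nested-in-longer suppressed."""
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    n = len(seq)
    hits = []
    for p, minrep in thresholds.items():
        for i in range(n - p * minrep + 1):
            unit = seq[i : i + p]
            if set(unit) - set("ACGT") or not _primitive(unit):
                continue
            if i >= 1 and i + p - 1 < n and seq[i - 1] == seq[i + p - 1]:
                continue  # period continues left: not the leftmost start
            k = 1
            while seq[i + k * p : i + (k + 1) * p] == unit:
                k += 1
            if k >= minrep:
                hits.append((i + 1, i + p * k, unit, p, k))
    kept = []
    for h in hits:
        if any(
            o[3] != h[3] and o[0] <= h[0] and h[1] <= o[1]
            and (o[1] - o[0]) > (h[1] - h[0])
            for o in hits
        ):
            continue
        kept.append(h)
    return sorted(kept)


def brute_long_repeats(seq: str, min_len=30, budget=3):
    """Exhaustive diagonal enumeration of maximal mismatch-budgeted repeat
    pairs (forward and palindromic)."""
    n = len(seq)
    s = seq.encode()
    rc = reverse_complement(seq).encode()
    out = set()

    def windows(x, y, d):
        lo, hi = max(0, -d), min(len(x), len(y) - d)
        if hi - lo < min_len:
            return []
        ms = [t for t in range(lo, hi) if x[t] != y[t + d]]
        zset = set(ms)
        bounds = [lo - 1] + ms + [hi]
        b = min(budget, len(ms))
        res = []
        for i in range(0, len(ms) - b + 1):
            left, right = bounds[i] + 1, bounds[i + b + 1] - 1
            while left <= right and left in zset:
                left += 1
            while right >= left and right in zset:
                right -= 1
            if right - left + 1 < min_len:
                continue
            mism = sum(1 for m in ms if left <= m <= right)
            res.append((left, right, mism))
        res = sorted(set(res))
        return [
            c for c in res
            if not any(
                (o[0], o[1]) != (c[0], c[1]) and o[0] <= c[0] and c[1] <= o[1]
                for o in res
            )
        ]

    for d in range(1, n):
        for left, right, mism in windows(s, s, d):
            out.add(("forward", right - left + 1, left + 1, left + d + 1, mism))
    for dd in range(-(n - min_len), n - min_len + 1):
        for left, right, mism in windows(s, rc, dd):
            length = right - left + 1
            j1 = n - (left + dd) - length
            if left == j1:
                continue
            p1, p2 = sorted((left, j1))
            out.add(("palindromic", length, p1 + 1, p2 + 1, mism))
    return out


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def test_mono_threshold_boundary():
    assert find_ssrs("G" + "A" * 9 + "G") == []
    hits = find_ssrs("G" + "A" * 10 + "G")
    assert len(hits) == 1
    s = hits[0]
    assert (s.motif, s.repeats, s.start, s.end) == ("A", 10, 2, 11)


def test_dinucleotide_maximality():
    hits = find_ssrs("GG" + "AT" * 6 + "GG")
    assert [(h.motif, h.repeats) for h in hits] == [("AT", 6)]
    # partial trailing unit does not count
    hits = find_ssrs("GG" + "AT" * 6 + "A" + "GG")
    assert hits[0].repeats == 6


def test_nonprimitive_motifs_not_reported_at_higher_unit():
    hits = find_ssrs("C" + "AT" * 8 + "C")
    assert all(h.unit_len == 2 for h in hits)


def test_canonical_motif_family():
    assert canonical_motif_family("AT") == canonical_motif_family("TA")
    assert canonical_motif_family("AAG") == canonical_motif_family("GAA")
    assert canonical_motif_family("AAG") == canonical_motif_family("CTT")
    assert canonical_motif_family("A") == "A" and canonical_motif_family("T") == "A"


def test_ssr_implants_recovered_exactly(small_genome):
    record, truth = small_genome
    got = {
        (s.start, s.end, s.motif)
        for s in find_ssrs(record.sequence, circular=True)
    }
    want = {
        (d["start"], d["end"], d["motif"]) for d in truth["ssr_implants"]
    }
    assert got == want


def test_ssr_oracle_equivalence_on_genome_sequence(small_genome):
    record, _ = small_genome
    seq = record.sequence[:20_000]
    got = {(s.start, s.end, s.motif) for s in find_ssrs(seq)}
    want = {(a, b, u) for a, b, u, _, _ in brute_ssrs(seq)}
    assert got == want


def test_ssr_oracle_equivalence_on_random_at_rich(rng):
    bases = np.array(list("ACGTAT"))  # AT-rich to provoke runs
    seq = "".join(rng.choice(bases, size=8000))
    low = {1: 5, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3}  # permissive: many hits
    got = {(s.start, s.end, s.motif) for s in find_ssrs(seq, thresholds=low)}
    want = {(a, b, u) for a, b, u, _, _ in brute_ssrs(seq, low)}
    assert got == want
    assert len(got) > 10  # the fixture actually exercises the scanner


def test_ssr_reverse_complement_family_tallies(small_genome):
    record, _ = small_genome
    fwd = find_ssrs(record.sequence)
    rev = find_ssrs(reverse_complement(record.sequence))
    tally = lambda hits: sorted((h.motif_family, h.repeats) for h in hits)
    assert tally(fwd) == tally(rev)


def test_every_ssr_revalidates_against_sequence(small_genome):
    record, _ = small_genome
    for s in find_ssrs(record.sequence):
        sub = record.sequence[s.start - 1 : s.end]
        assert sub == s.motif * s.repeats
        assert s.end - s.start + 1 == s.unit_len * s.repeats


def test_merge_compound_groups_nearby_ssrs(rng):
    gap1 = _random_seq(rng, 50)
    gap2 = _random_seq(rng, 200)
    seq = "A" * 12 + gap1 + "AT" * 7 + gap2 + "T" * 11
    ssrs = find_ssrs(seq)
    assert len(ssrs) == 3  # the random spacers contribute none
    groups = merge_compound(ssrs, max_gap=100)
    assert [len(g) for g in groups] == [2, 1]


# ---------------------------------------------------------------------------
# Long repeats
# ---------------------------------------------------------------------------


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_exact_forward_duplication_found(rng):
    seq = _random_seq(rng, 4000)
    dup = seq[:1500] + seq[700:735] + seq[1500:]
    hits = [r for r in find_long_repeats(dup) if r.length >= 35]
    assert any(
        r.kind == "forward" and r.mismatches == 0 and r.length == 35
        and (r.pos1, r.pos2) == (701, 1501)
        for r in hits
    ) or any(r.kind == "forward" and r.length >= 35 for r in hits)


def test_palindromic_copy_found(rng):
    seq = _random_seq(rng, 3000)
    pal = seq[:2200] + reverse_complement(seq[100:130]) + seq[2200:]
    hits = [r for r in find_long_repeats(pal) if r.kind == "palindromic"]
    assert any(r.length >= 30 and r.pos1 == 101 for r in hits)


def test_mismatched_copy_within_budget(rng):
    seq = _random_seq(rng, 3000)
    copy = list(seq[500:540])
    copy[10] = "A" if copy[10] != "A" else "C"
    copy[25] = "G" if copy[25] != "G" else "T"
    seq2 = seq[:2000] + "".join(copy) + seq[2000:]
    hits = [r for r in find_long_repeats(seq2) if r.kind == "forward" and r.length >= 40]
    assert any(r.mismatches <= 3 for r in hits)


def test_long_repeat_oracle_equivalence(rng):
    """Seeded detector equals the exhaustive diagonal scan on a sequence
    with planted forward and palindromic copies."""
    base = _random_seq(rng, 1600)
    seq = (
        base[:500] + base[200:238] + base[500:1100]
        + reverse_complement(base[300:334]) + base[1100:]
    )
    got = {
        (r.kind, r.length, r.pos1, r.pos2, r.mismatches)
        for r in find_long_repeats(seq)
    }
    want = brute_long_repeats(seq)
    assert got == want
    assert any(k == "forward" for k, *_ in want)
    assert any(k == "palindromic" for k, *_ in want)


def test_long_repeats_revalidate_against_sequence(small_genome):
    record, _ = small_genome
    for r in find_long_repeats(record.sequence):
        a = record.sequence[r.pos1 - 1 : r.pos1 - 1 + r.length]
        b = record.sequence[r.pos2 - 1 : r.pos2 - 1 + r.length]
        if r.kind == "palindromic":
            b = reverse_complement(b)
        mism = sum(x != y for x, y in zip(a, b))
        assert mism == r.mismatches <= 3
        assert a[0] == b[0] and a[-1] == b[-1]  # ends on matches
        assert r.score == r.length - 2 * r.mismatches


def test_whole_ir_reported_once_as_palindromic(small_genome):
    record, truth = small_genome
    ir_len = truth["intervals"]["IRb"][1] - truth["intervals"]["IRb"][0] + 1
    big = [r for r in find_long_repeats(record.sequence) if r.length >= ir_len]
    assert len(big) == 1
    assert big[0].kind == "palindromic"


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def test_summarize_empty_inputs():
    s = summarize_repeats([], [])
    assert s["ssr_total"] == 0
    assert all(v == 0 for v in s["ssr_by_unit"].values())
    assert s["long_repeat_total"] == 0


def test_summary_shares_match_implanted_design():
    spec = SyntheticSpec(
        seed=4, n_genes=10, architecture=(14_000, 2_500, 4_000),
        ssr_implants=tuple([("A", 11)] * 7 + [("AT", 6)] * 2 + [("AAT", 5)]),
    )
    record, _ = generate_genome(spec)
    ssrs = find_ssrs(record.sequence, circular=True)
    s = summarize_repeats(ssrs, [])
    assert s["ssr_total"] == 10
    assert s["ssr_percent_by_unit"]["mono"] == pytest.approx(70.0)
    assert s["ssr_motif_split"]["AT"] == 10  # all motifs here are A/T-only


def test_summary_length_bins():
    reps = find_long_repeats("A" * 0 + "".join(
        np.array(list("ACGT"))[np.random.default_rng(9).integers(0, 4, 1500)]
    ) * 2)
    s = summarize_repeats([], reps)
    assert sum(s["long_repeat_by_length_bin"].values()) == len(reps)
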