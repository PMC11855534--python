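"""Codon counting, RSCU, positional GC, ENc (observed/expected), CAI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastcub.codon_metrics import (
    CodonCountTable,
    GeneticCode,
    cai,
    count_codons,
    enc_expected,
    enc_observed,
    gc_profile,
    pool_counts,
    rscu,
)

# code-11 synonymous families, written out independently of the implementation
FAMILIES_11 = {
    "F": ["TTT", "TTC"], "Y": ["TAT", "TAC"], "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"], "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "C": ["TGT", "TGC"],
    "I": ["ATT", "ATC", "ATA"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "M": ["ATG"], "W": ["TGG"],
}


def test_code11_family_structure():
    code = GeneticCode.get(11)
    sizes = {}
    for aa, fam in code.families.items():
        sizes[len(fam)] = sizes.get(len(fam), 0) + 1
        assert sorted(FAMILIES_11[aa]) == sorted(fam)
    assert sizes == {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}


def test_count_codons_examples():
    t = count_codons("ATGTGGTAA")
    assert t.counts == {"ATG": 1, "TGG": 1, "TAA": 1}
    assert t.total_codons == 3
    assert count_codons("AAAAAAAAG").counts == {"AAA": 2, "AAG": 1}
    with pytest.raises(ValueError):
        count_codons("ATGA")


def test_count_codons_matches_generator_tally(default_cds):
    cds, truth = default_cds
    for entry in cds.entries[:10]:
        tally = truth["genes"][entry.gene_name]["tally"]
        assert count_codons(entry.sequence).counts == tally


def test_rscu_hand_example_and_met_trp():
    t = CodonCountTable("x", {"AAA": 3, "AAG": 1, "ATG": 5, "TGG": 2})
    r = rscu(t)
    assert r.rscu["AAA"] == pytest.approx(1.5)
    assert r.rscu["AAG"] == pytest.approx(0.5)
    assert r.rscu["ATG"] == pytest.approx(1.0)
    assert r.rscu["TGG"] == pytest.approx(1.0)


def test_rscu_unobserved_family_is_missing_not_zero():
    r = rscu(CodonCountTable("x", {"AAA": 2}))
    assert "TTT" not in r.rscu
    assert "TAA" not in r.rscu  # stops never get RSCU


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rscu_family_normalization(seed):
    """Sum of RSCU over each observed family equals the family size."""
    rng = np.random.default_rng(seed)
    counts = {
        c: int(rng.integers(0, 30))
        for fam in FAMILIES_11.values()
        for c in fam
    }
    r = rscu(CodonCountTable("x", counts))
    for aa, fam in FAMILIES_11.items():
        if sum(counts[c] for c in fam) == 0:
            continue
        assert sum(r.rscu[c] for c in fam) == pytest.approx(len(fam), abs=1e-9)
        assert all(r.rscu[c] >= 0 for c in fam)


def test_gc_profile_examples():
    p = gc_profile("GGGGGG")
    assert (p.gc1, p.gc2, p.gc3) == (1.0, 1.0, 1.0)
    q = gc_profile("ATGTGG")  # Met + Trp only: no synonymous third positions
    assert q.gc3s is None
    assert q.gc3 == 1.0  # both third positions are G
    assert q.gc12 == pytest.approx((q.gc1 + q.gc2) / 2)


def test_gc_profile_matches_brute_force_tally(rng):
    code = GeneticCode.get(11)
    sense = [c for c in code.sense_codons]
    codons = list(rng.choice(sense, size=60))
    seq = "".join(codons) + "TAA"
    p = gc_profile(seq)
    gc = lambda chars: sum(ch in "GC" for ch in chars) / len(chars)
    assert p.gc1 == pytest.approx(gc([c[0] for c in codons]))
    assert p.gc2 == pytest.approx(gc([c[1] for c in codons]))
    assert p.gc3 == pytest.approx(gc([c[2] for c in codons]))
    syn = [c[2] for c in codons if c not in ("ATG", "TGG")]
    assert p.gc3s == pytest.approx(gc(syn))
    # positional average identity
    assert (p.gc1 + p.gc2 + p.gc3) / 3 == pytest.approx(p.gc_all)


def test_enc_is_20_for_one_codon_per_family():
    counts = {fam[0]: 9 for fam in FAMILIES_11.values()}
    res = enc_observed(CodonCountTable("x", counts))
    assert res.enc == pytest.approx(20.0)


def test_enc_near_61_for_uniform_usage(rng):
    sense = [c for fam in FAMILIES_11.values() for c in fam if len(fam) > 1]
    draw = rng.choice(sense, size=10_000)
    counts = {}
    for c in draw:
        counts[c] = counts.get(c, 0) + 1
    res = enc_observed(CodonCountTable("u", counts))
    assert res.enc == pytest.approx(61.0, abs=0.5)


def test_enc_matches_direct_formula_oracle(rng):
    """Wright's estimator recomputed independently on 50 random tables."""
    for _ in range(50):
        counts = {
            c: int(rng.integers(0, 25))
            for fam in FAMILIES_11.values()
            for c in fam
        }
        res = enc_observed(CodonCountTable("x", counts))
        f_by_class: dict[int, list[float]] = {}
        for aa, fam in FAMILIES_11.items():
            if len(fam) < 2:
                continue
            n = sum(counts[c] for c in fam)
            if n < 2:
                continue
            s2 = sum((counts[c] / n) ** 2 for c in fam)
            f_by_class.setdefault(len(fam), []).append((n * s2 - 1) / (n - 1))
        means = {k: sum(v) / len(v) for k, v in f_by_class.items()}
        if 3 not in means and 2 in means and 4 in means:
            means[3] = (means[2] + means[4]) / 2
        if any(k not in means or means[k] == 0 for k in (2, 3, 4, 6)):
            assert res.enc is None
            continue
        expected = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
        expected = min(max(expected, 20.0), 61.0)
        assert res.enc == pytest.approx(expected, abs=1e-9)


def test_enc_monotone_under_increasing_bias():
    """Sharper Dirichlet concentration (stronger bias) never raises mean ENc."""
    alphas = [10.0, 3.0, 1.0, 0.3, 0.1]
    mean_encs = []
    for alpha in alphas:
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = {}
            for fam in FAMILIES_11.values():
                if len(fam) < 2:
                    continue
                p = rng.dirichlet([alpha] * len(fam))
                for c, k in zip(fam, rng.multinomial(60, p)):
                    counts[c] = int(k)
            enc = enc_observed(CodonCountTable("x", counts)).enc
            vals.append(enc)
        mean_encs.append(np.mean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(mean_encs, mean_encs[1:]))


def test_enc_expected_examples_and_symmetry():
    assert enc_expected(0.5) == pytest.approx(60.5)
    assert enc_expected(0.0) == pytest.approx(31.0)
    for s in (0.1, 0.25, 0.4):
        # S^2 + (1-S)^2 term is symmetric about 0.5
        assert enc_expected(s) - s == pytest.approx(enc_expected(1 - s) - (1 - s))
    with pytest.raises(ValueError):
        enc_expected(1.2)


def test_cai_examples():
    ref_counts = {"AAA": 9, "AAG": 1, "GCT": 8, "GCC": 2}
    ref = rscu(CodonCountTable("ref", ref_counts))
    # gene of only reference-preferred codons
    best = cai(CodonCountTable("g", {"AAA": 10, "GCT": 5}), ref)
    assert best.cai == pytest.approx(1.0)
    # two-codon toy with weights 1.0 and 0.5 used equally
    ref2 = rscu(CodonCountTable("ref2", {"AAA": 2, "AAG": 1}))
    two = cai(CodonCountTable("g2", {"AAA": 1, "AAG": 1}), ref2)
    assert two.cai == pytest.approx(math.sqrt(0.5))


def test_pool_counts_sums_tables():
    a = CodonCountTable("a", {"AAA": 2})
    b = CodonCountTable("b", {"AAA": 1, "TTT": 4})
    pooled = pool_counts([a, b])
    assert pooled.counts == {"AAA": 3, "TTT": 4}
    assert pooled.total_codons == 7
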