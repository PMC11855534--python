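"""Plastome-like synthetic data with known ground truth.

The generator emulates the statistical structure of a rubber-tree-style
chloroplast genome — a ~161 kb circle split LSC + IRb + SSC + IRa with
IR ≈ 26.8 kb, overall GC ≈ 35.7%, ~90 protein-coding genes biased toward
A/U-ending codons, and SSRs dominated by A/T mononucleotide runs — while
recording every quantity the analysis stages are supposed to recover
(codon tallies, per-gene GC targets, implanted preferred codons, SSR
coordinates, region intervals).

Codon and amino-acid draws use low-discrepancy (largest-remainder)
allocation of the specified weight vectors rather than independent
multinomial sampling: realized per-gene usage then matches the weights to
within one codon, so ground-truth recovery checks are sharp.  The random
seed controls gene lengths, GC3 targets, ordering and all placement, and
fully determines the output.

Knobs and what they emulate
---------------------------
* ``gc3_range`` + the C-over-G / T-over-A shares: third-position
  composition and the PR2 asymmetry the real genomes show.
* ``neutrality``: per-gene GC12 is steered (by exponentially tilting the
  amino-acid frequencies) to intercept + slope · E[GC3] + noise, giving a
  controlled neutrality-plot relation.
* ``preferred_codons`` + the two expression classes: a high-bias minority
  of genes concentrates usage on designated codons, so ENc-extreme
  libraries and ΔRSCU can be validated against an implanted truth set.
* ``ssr_implants``: the only SSRs above detection thresholds; filler
  sequence is scrubbed of accidental tandem runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cds_filter import CdsEntry, CdsSet
from .codon_metrics import GeneticCode
from .genome_io import Feature, GenomeRecord, reverse_complement
from .repeats import find_ssrs

__all__ = [
    "SyntheticSpec",
    "generate_cds_set",
    "generate_genome",
    "write_genbank",
    "write_truth",
    "preset_spec",
    "PLASTOME_AA_FREQ",
    "DEFAULT_PREFERRED_CODONS",
]

# rough plastid proteome amino-acid frequencies (fractions, renormalized)
PLASTOME_AA_FREQ: dict[str, float] = {
    "L": 0.105, "S": 0.078, "I": 0.082, "F": 0.051, "R": 0.047,
    "G": 0.071, "A": 0.060, "T": 0.052, "V": 0.062, "P": 0.043,
    "K": 0.052, "E": 0.052, "D": 0.042, "N": 0.048, "Q": 0.035,
    "H": 0.023, "Y": 0.035, "C": 0.011, "W": 0.018, "M": 0.024,
}

# one A/T-ending codon per degenerate family, the default implanted truth
DEFAULT_PREFERRED_CODONS: tuple[str, ...] = (
    "TTA", "TCA", "ATT", "TTT", "AGA", "GGA", "GCT", "ACT", "GTT",
    "CCT", "AAA", "GAA", "GAT", "AAT", "CAA", "CAT", "TAT", "TGT",
)

_GENE_NAME_POOL: tuple[str, ...] = (
    "psbA", "rpoB", "rps2", "matK", "ndhA", "rpl2", "ycf1", "atpA",
    "psaA", "rpoC1", "rps3", "accD", "ndhB", "rpl14", "ycf2", "atpB",
    "psbB", "rpoC2", "rps4", "ccsA", "ndhC", "rpl16", "ycf3", "atpE",
    "psaB", "rpoA", "rps7", "cemA", "ndhD", "rpl20", "ycf4", "atpF",
    "psbC", "infA", "rps8", "clpP", "ndhE", "rpl22", "petA", "atpH",
    "psbD", "rps11", "ndhF", "rpl23", "petB", "atpI", "psbE", "rps12",
    "ndhG", "rpl32", "petD", "psbF", "rps14", "ndhH", "rpl33", "petG",
    "psbH", "rps15", "ndhI", "rpl36", "petL", "psbI", "rps16", "ndhJ",
    "petN", "psbJ", "rps18", "ndhK", "psbK", "rps19", "rbcL", "psbL",
    "psbM", "psbN", "psbT", "psbZ", "psaC", "psaI", "psaJ",
)

_DEFAULT_SSR_IMPLANTS: tuple[tuple[str, int], ...] = (
    # 40 mono (share 40/57 = 70.2%), 8 di, 2 tri, 5 tetra, 1 penta, 1 hexa
    *[("A", r) for r in (10, 11, 12, 13, 14, 10, 11, 12, 13, 15,
                         10, 11, 12, 10, 11, 12, 13, 10, 11, 14)],
    *[("T", r) for r in (10, 11, 12, 13, 10, 11, 12, 14, 10, 11,
                         12, 13, 10, 11, 15, 10)],
    ("C", 10), ("C", 11), ("G", 10), ("G", 12),
    *[("AT", r) for r in (6, 7, 8, 6)],
    *[("TA", r) for r in (6, 7)],
    ("AG", 6), ("TC", 7),
    ("AAT", 5), ("ATT", 6),
    ("AAAT", 5), ("ATTT", 5), ("AATT", 5), ("TTTA", 6), ("TAAA", 5),
    ("AAAAT", 5),
    ("AATAGT", 5),
)


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults emulate one rubber-tree-like
    plastome.  ``seed`` fully determines the output."""

    seed: int = 0
    accession: str = "SYN000001"
    species: str = "Synthetica plastoma"
    n_genes: int = 90
    gene_length_range: tuple[int, int] = (100, 420)  # amino acids
    genetic_code: int = 11
    # third-position composition
    gc3_range: tuple[float, float] = (0.18, 0.37)
    c_over_gc: float = 0.55   # C share of third-position G+C mass
    t_over_at: float = 0.55   # T share of third-position A+T mass
    # expression classes and implanted codon preference
    preferred_codons: tuple[str, ...] = DEFAULT_PREFERRED_CODONS
    high_bias_fraction: float = 0.2
    bias_high: float = 0.85   # mean weight mass moved onto the favoured codon(s)
    bias_low: float = 0.45
    bias_jitter: float = 0.25  # per-gene uniform spread around the class mean
    # 'concentrate': move mass onto one codon per third-position base group,
    # preserving GC3 (selection-like); 'replace': move family mass straight
    # onto the preferred codon, dragging GC3 with it
    bias_mode: str = "concentrate"
    # neutrality-plot relation: gc12 = intercept + slope * E[gc3] + N(0, sigma)
    neutrality: tuple[float, float, float] | None = (0.40, 0.22, 0.02)
    # per-codon weight overrides (normalized within each family)
    codon_weights: dict[str, float] = field(default_factory=dict)
    # genome architecture (bp): LSC, each IR, SSC
    architecture: tuple[int, int, int] = (89_150, 26_810, 18_370)
    gc_target: float = 0.357
    ssr_implants: tuple[tuple[str, int], ...] = _DEFAULT_SSR_IMPLANTS
    violations: tuple[str, ...] = ()  # extra rule-breaking genes on request

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if not (3 <= lo <= hi):
            raise ValueError("gene_length_range must satisfy 3 <= lo <= hi")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.high_bias_fraction <= 1):
            raise ValueError("high_bias_fraction outside [0, 1]")
        if any(x <= 0 for x in self.architecture):
            raise ValueError("architecture lengths must be positive")
        for lim in self.gc3_range:
            if not 0.0 <= lim <= 1.0:
                raise ValueError("gc3_range outside [0, 1]")


def preset_spec(name: str, seed: int = 0) -> SyntheticSpec:
    """Named presets: 'hevea-like' (the defaults), 'uniform' (no bias at
    all), 'strong-bias' (8 implanted codons at high contrast)."""
    if name == "hevea-like":
        return SyntheticSpec(seed=seed)
    if name == "uniform":
        code = GeneticCode.get(11)
        return SyntheticSpec(
            seed=seed, preferred_codons=(), bias_high=0.0, bias_low=0.0,
            gc3_range=(0.5, 0.5), c_over_gc=0.5, t_over_at=0.5,
            neutrality=None,
            codon_weights={c: 1.0 for c in code.sense_codons},
        )
    if name == "strong-bias":
        return SyntheticSpec(
            seed=seed,
            preferred_codons=("TTA", "GCT", "GGA", "CCT", "ACT", "GTT", "TCA", "AGA"),
            bias_high=0.9, bias_low=0.0, bias_jitter=0.0, bias_mode="replace",
            gc3_range=(0.5, 0.5), c_over_gc=0.5, t_over_at=0.5,
            neutrality=None,
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# Weight machinery
# ---------------------------------------------------------------------------


def _family_weights(
    spec: SyntheticSpec, code: GeneticCode, s: float, bias: float
) -> dict[str, np.ndarray]:
    """Per-family codon probability vectors at third-position GC level
    ``s``: the G+C mass s is split over GC-ending members (C favoured by
    ``c_over_gc``), the A+T mass likewise; a preferred codon then receives
    an extra mass ``bias`` of its family (or of its base group, in
    'concentrate' mode)."""
    out: dict[str, np.ndarray] = {}
    for aa, fam in code.families.items():
        k = len(fam)
        if any(c in spec.codon_weights for c in fam):
            w = np.array([spec.codon_weights.get(c, 0.0) for c in fam])
            if w.sum() <= 0:
                raise ValueError(f"codon_weights for {aa} sum to zero")
            out[aa] = w / w.sum()
            continue
        if k == 1:
            out[aa] = np.ones(1)
            continue
        thirds = [c[2] for c in fam]
        gc_members = [i for i, b in enumerate(thirds) if b in "GC"]
        at_members = [i for i, b in enumerate(thirds) if b in "AT"]
        w = np.zeros(k)
        if gc_members and at_members:
            gshare = {"C": spec.c_over_gc, "G": 1 - spec.c_over_gc}
            ashare = {"T": spec.t_over_at, "A": 1 - spec.t_over_at}
            gtot = sum(gshare[thirds[i]] for i in gc_members)
            atot = sum(ashare[thirds[i]] for i in at_members)
            for i in gc_members:
                w[i] = s * gshare[thirds[i]] / gtot
            for i in at_members:
                w[i] = (1 - s) * ashare[thirds[i]] / atot
        else:  # family confined to one group (cannot happen in code 11)
            w[:] = 1.0 / k
        pref = [i for i, c in enumerate(fam) if c in spec.preferred_codons]
        if pref and bias > 0:
            if spec.bias_mode == "replace":
                w = (1 - bias) * w
                w[pref[0]] += bias
            else:  # concentrate within each third-base group, GC3 preserved
                for group in (at_members, gc_members):
                    if len(group) < 2:
                        continue
                    mass = w[group].sum()
                    in_group_pref = [i for i in group if i in pref]
                    top = in_group_pref[0] if in_group_pref else max(
                        group, key=lambda i: w[i]
                    )
                    for i in group:
                        w[i] *= (1 - bias)
                    w[top] += bias * mass
        out[aa] = w / w.sum()
    return out


def _gc12_of(codon: str) -> float:
    return sum(b in "GC" for b in codon[:2]) / 2.0


def _expected_profiles(code: GeneticCode, weights: dict[str, np.ndarray]):
    """Per amino acid: expected GC12 and expected third-position GC given
    the codon weights."""
    e12, e3 = {}, {}
    for aa, fam in code.families.items():
        w = weights[aa]
        e12[aa] = float(sum(wi * _gc12_of(c) for wi, c in zip(w, fam)))
        e3[aa] = float(sum(wi * (c[2] in "GC") for wi, c in zip(w, fam)))
    return e12, e3


def _tilt_aa_freqs(
    base: dict[str, float], e12: dict[str, float], target: float
) -> dict[str, float]:
    """Exponential tilt of amino-acid frequencies so the expected GC12
    matches ``target`` (clamped to the achievable range)."""
    aas = list(base)
    f = np.array([base[a] for a in aas])
    f = f / f.sum()
    e = np.array([e12[a] for a in aas])
    lo_val = e.min() + 1e-4
    hi_val = e.max() - 1e-4
    target = min(max(target, lo_val), hi_val)

    def mean_at(theta: float) -> float:
        w = f * np.exp(theta * (e - e.mean()))
        w = w / w.sum()
        return float(w @ e)

    lo, hi = -400.0, 400.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
    theta = (lo + hi) / 2
    w = f * np.exp(theta * (e - e.mean()))
    w = w / w.sum()
    return dict(zip(aas, w))


def _balanced_counts(total: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder allocation of ``total`` draws to the
    weight vector (ties go to the lower index).  Realized counts stay within
    one unit of ``total * weight``, which keeps ground-truth usage sharp."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    counts = np.floor(raw).astype(int)
    rem = total - int(counts.sum())
    if rem > 0:
        frac = raw - counts
        order = np.argsort(-frac, kind="stable")
        counts[order[:rem]] += 1
    return counts


# ---------------------------------------------------------------------------
# CDS generation
# ---------------------------------------------------------------------------

def _adjust_gc3(codons: list[str], target_count: int, code: GeneticCode) -> list[str]:
    """Drive the third-position G+C count of a codon list onto
    ``target_count`` by swapping codons for same-prefix family members of
    the other base group (e.g. ATT <-> ATC).  First/second positions — and
    hence GC12 and the amino-acid sequence — are untouched."""
    cur = sum(c[2] in "GC" for c in codons)
    delta = target_count - cur
    if delta == 0:
        return codons
    raise_gc = delta > 0
    order = "CG" if raise_gc else "TA"
    swaps: dict[str, str] = {}
    for aa, fam in code.families.items():
        for c in fam:
            if (c[2] in "GC") == raise_gc:
                continue
            for third in order:
                partner = c[:2] + third
                if partner in fam:
                    swaps[c] = partner
                    break
    out = list(codons)
    need = abs(delta)
    stride = max(len(out) // (need + 1), 1)  # spread swaps across families
    for start in range(stride):
        for i in range(start, len(out), stride):
            if need == 0:
                return out
            if out[i] in swaps:
                out[i] = swaps[out[i]]
                need -= 1
    return out


_VIOLATION_SEQS = {
    "not_triplet": "ATG" + "GCT" * 110 + "TA",          # rule 1
    "short": "ATG" + "GCT" * 40 + "TAA",                # rule 2
    "ambiguous": "ATG" + "GCN" * 110 + "TAA",           # rule 3
    "internal_stop": "ATG" + "GCT" * 50 + "TAA" + "GCT" * 60 + "TAA",  # rule 4
}


def _gene_names(n: int) -> list[str]:
    names = list(_GENE_NAME_POOL[:n])
    while len(names) < n:
        names.append(f"orf{len(names) + 1:03d}")
    return names


def _build_gene(
    spec: SyntheticSpec,
    code: GeneticCode,
    rng: np.random.Generator,
    length_aa: int,
    s: float,
    bias: float,
) -> tuple[str, dict[str, int], float]:
    """One CDS: ATG + shuffled interior codons + TAA.  Returns the sequence,
    its realized codon tally and the gene's GC12 target."""
    weights = _family_weights(spec, code, s, bias)
    e12, e3 = _expected_profiles(code, weights)
    base = dict(PLASTOME_AA_FREQ)
    if spec.neutrality is not None:
        intercept, slope, sigma = spec.neutrality
        exp_gc3 = float(
            sum(base[a] * e3[a] for a in base) / sum(base.values())
        )
        eps = float(rng.normal(0.0, sigma))
        # one refinement pass: tilt, recompute E[GC3], retarget, retilt
        target = intercept + slope * exp_gc3 + eps
        freqs = _tilt_aa_freqs(base, e12, target)
        exp_gc3 = float(sum(freqs[a] * e3[a] for a in freqs))
        target = intercept + slope * exp_gc3 + eps
        freqs = _tilt_aa_freqs(base, e12, target)
        gc12_target = target
    else:
        total = sum(base.values())
        freqs = {a: v / total for a, v in base.items()}
        gc12_target = float(sum(freqs[a] * e12[a] for a in freqs))
    aas = list(freqs)
    interior = length_aa - 1  # leading Met is fixed
    aa_counts = _balanced_counts(interior, np.array([freqs[a] for a in aas]))
    # round every degenerate family's count to a multiple of its size, so
    # tied (e.g. uniform) codon weights split with zero remainder; Met
    # absorbs the residual (its family carries no usage information)
    counts_by_aa: dict[str, int] = {}
    for aa, cnt in zip(aas, aa_counts):
        k = len(code.families[aa])
        counts_by_aa[aa] = int(cnt) if k == 1 else k * int(round(int(cnt) / k))
    counts_by_aa["M"] = counts_by_aa.get("M", 0) + interior - sum(counts_by_aa.values())
    while counts_by_aa["M"] < 0:
        donor = max(
            (a for a in counts_by_aa if len(code.families[a]) > 1),
            key=lambda a: counts_by_aa[a],
        )
        k = len(code.families[donor])
        counts_by_aa[donor] -= k
        counts_by_aa["M"] += k
    codons: list[str] = []
    for aa in aas:
        cnt = counts_by_aa.get(aa, 0)
        if cnt == 0:
            continue
        fam = code.families[aa]
        per_codon = _balanced_counts(int(cnt), weights[aa])
        for codon, k in zip(fam, per_codon):
            codons.extend([codon] * int(k))
    if spec.neutrality is not None:
        # pin the realized third-position GC onto its expectation so the
        # planted neutrality relation is not blurred by rounding noise
        exp_gc3_final = float(sum(freqs[a] * e3[a] for a in freqs))
        target_total = int(round(exp_gc3_final * (len(codons) + 1)))
        codons = _adjust_gc3(codons, max(target_total - 1, 0), code)
    order = rng.permutation(len(codons))
    body = "".join(codons[i] for i in order)
    seq = "ATG" + body + "TAA"
    # avoid accidental tandem repeats inside the CDS (they would contaminate
    # the genome-level SSR truth); reshuffle a few times if needed
    for _ in range(25):
        if not find_ssrs(seq):
            break
        order = rng.permutation(len(codons))
        body = "".join(codons[i] for i in order)
        seq = "ATG" + body + "TAA"
    tally: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        c = seq[i : i + 3]
        tally[c] = tally.get(c, 0) + 1
    return seq, tally, gc12_target


def generate_cds_set(spec: SyntheticSpec) -> tuple[CdsSet, dict]:
    """Generate the gene complement of one synthetic plastome.

    Returns the analysis-ready :class:`~plastcub.cds_filter.CdsSet` plus a
    ground-truth dict: per-gene codon tally, expression class, GC3/GC12
    targets, and the implanted preferred-codon set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode.get(spec.genetic_code)
    names = _gene_names(spec.n_genes)
    n_high = int(round(spec.high_bias_fraction * spec.n_genes))
    flags = np.array([True] * n_high + [False] * (spec.n_genes - n_high))
    rng.shuffle(flags)
    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    s_lo, s_hi = spec.gc3_range
    s_values = rng.uniform(s_lo, s_hi, size=spec.n_genes)
    cds = CdsSet(accession=spec.accession, genetic_code=spec.genetic_code)
    truth: dict = {
        "preferred_codons": list(spec.preferred_codons),
        "genes": {},
    }
    for name, high, length_aa, s in zip(names, flags, lengths, s_values):
        mean_bias = spec.bias_high if high else spec.bias_low
        bias = float(
            np.clip(
                rng.uniform(mean_bias - spec.bias_jitter, mean_bias + spec.bias_jitter),
                0.0, 0.95,
            )
        ) if mean_bias > 0 else 0.0
        seq, tally, gc12_target = _build_gene(
            spec, code, rng, int(length_aa), float(s), bias
        )
        cds.entries.append(
            CdsEntry(name, seq, len(seq), len(seq) // 3 - 1)
        )
        truth["genes"][name] = {
            "class": "high" if high else "low",
            "length_aa": int(length_aa),
            "gc3_target": float(s),
            "gc12_target": float(gc12_target),
            "tally": tally,
        }
    for kind in spec.violations:
        cds.entries.append(
            CdsEntry(f"bad_{kind}", _VIOLATION_SEQS[kind],
                     len(_VIOLATION_SEQS[kind]), 0)
        )
    return cds, truth


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


def _filler(
    length: int, p_gc: float, rng: np.random.Generator, run_cap: int = 7
) -> str:
    """Random background sequence at GC fraction ``p_gc`` with homopolymer
    runs capped, so it contributes no mononucleotide SSRs."""
    if length <= 0:
        return ""
    probs = {
        "G": p_gc / 2, "C": p_gc / 2,
        "A": (1 - p_gc) / 2, "T": (1 - p_gc) / 2,
    }
    bases = list(probs)
    p = np.array([probs[b] for b in bases])
    draws = rng.choice(len(bases), size=length, p=p)
    out = [bases[i] for i in draws]
    run = 1
    for i in range(1, length):
        run = run + 1 if out[i] == out[i - 1] else 1
        if run > run_cap:
            alternatives = [b for b in bases if b != out[i]]
            out[i] = alternatives[int(rng.integers(len(alternatives)))]
            run = 1
    return "".join(out)


def _clean_filler(
    length: int, p_gc: float, rng: np.random.Generator
) -> str:
    """Filler regenerated until free of SSRs at the default thresholds."""
    for _ in range(30):
        chunk = _filler(length, p_gc, rng)
        if not find_ssrs(chunk):
            return chunk
    raise RuntimeError("could not generate SSR-free filler")


def _fix_flanks(prev: list[str], motif: str, nxt: list[str]) -> None:
    """Make the bases flanking an SSR implant incompatible with extending
    the run (full-unit or homopolymer merge), in place on the neighbour
    chunks.  The flank base must differ from the motif's first and last
    characters and from its own neighbour."""
    if prev:
        banned = {motif[0], motif[-1], prev[-2] if len(prev) > 1 else ""}
        prev[-1] = next(b for b in "ACGT" if b not in banned)
    if nxt:
        banned = {motif[0], motif[-1], nxt[1] if len(nxt) > 1 else ""}
        nxt[0] = next(b for b in "ACGT" if b not in banned)


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeRecord, dict]:
    """Assemble a circular synthetic plastome LSC + IRb + SSC + IRa.

    IRa is the exact reverse complement of IRb.  CDS (and paired gene)
    features are placed on alternating strands in the single-copy regions
    separated by scrubbed filler; SSR implants are the only tandem repeats
    above the default thresholds and their coordinates are recorded.  The
    truth sidecar carries region intervals, junctions, implants, per-gene
    metadata and the realized GC fraction.
    """
    spec.validate()
    cds, truth = generate_cds_set(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    lsc_len, ir_len, ssc_len = spec.architecture
    total_len = lsc_len + 2 * ir_len + ssc_len

    entries = [e for e in cds.entries if not e.gene_name.startswith("bad_")]
    # split genes between LSC (most) and SSC
    ssc_budget = int(0.55 * ssc_len)
    ssc_genes: list[CdsEntry] = []
    lsc_genes: list[CdsEntry] = []
    acc = 0
    for e in entries:
        if acc + e.length_bp <= ssc_budget and len(ssc_genes) < len(entries) // 4:
            ssc_genes.append(e)
            acc += e.length_bp
        else:
            lsc_genes.append(e)
    implants = list(spec.ssr_implants)
    n_lsc_implants = int(round(len(implants) * 0.8))
    lsc_implants, ssc_implants = implants[:n_lsc_implants], implants[n_lsc_implants:]

    coding_lsc = sum(e.length_bp for e in lsc_genes)
    coding_ssc = sum(e.length_bp for e in ssc_genes)
    ssr_lsc = sum(len(m) * r for m, r in lsc_implants)
    ssr_ssc = sum(len(m) * r for m, r in ssc_implants)
    fill_lsc = lsc_len - coding_lsc - ssr_lsc
    fill_ssc = ssc_len - coding_ssc - ssr_ssc
    fill_ir = ir_len
    min_fill_lsc = 4 * (len(lsc_genes) + len(lsc_implants) + 1)
    min_fill_ssc = 4 * (len(ssc_genes) + len(ssc_implants) + 1)
    if fill_lsc < min_fill_lsc or fill_ssc < min_fill_ssc:
        raise ValueError(
            "architecture too small for the requested genes and implants "
            f"(free LSC {fill_lsc} bp, free SSC {fill_ssc} bp)"
        )
    # solve the filler GC fraction needed to hit the genome-wide target
    fixed = "".join(e.sequence for e in entries) + "".join(
        m * r for m, r in implants
    )
    fixed_gc = sum(b in "GC" for b in fixed)
    fixed_len = len(fixed)
    filler_len = fill_lsc + fill_ssc + 2 * fill_ir
    p_gc = (spec.gc_target * total_len - fixed_gc) / filler_len
    p_gc = min(max(p_gc, 0.02), 0.98)

    features: list[Feature] = []
    ssr_truth: list[dict] = []
    gene_truth_pos: dict[str, dict] = {}

    def build_region(
        genes: list[CdsEntry],
        region_implants: list[tuple[str, int]],
        region_fill: int,
        offset: int,
        strand_start: int,
    ) -> str:
        items: list[tuple[str, object]] = [("gene", e) for e in genes] + [
            ("ssr", mi) for mi in region_implants
        ]
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        n_chunks = len(items) + 1
        chunk_lens = _balanced_counts(
            region_fill - 4 * n_chunks, np.ones(n_chunks)
        ) + 4
        chunks = [list(_clean_filler(int(L), p_gc, rng)) for L in chunk_lens]
        parts: list[list[str]] = [chunks[0]]
        pos = offset + len(chunks[0])  # 0-based genome position
        strand = strand_start
        for idx, (kind, payload) in enumerate(items):
            if kind == "gene":
                e = payload
                plus = strand % 2 == 0
                seq = e.sequence if plus else reverse_complement(e.sequence)
                # break any tandem run straddling the gene/filler boundary
                prev, nxt = parts[-1], chunks[idx + 1]
                if prev and prev[-1] == seq[0]:
                    prev[-1] = next(
                        b for b in "ACGT"
                        if b != seq[0] and (len(prev) < 2 or b != prev[-2])
                    )
                if nxt and nxt[0] == seq[-1]:
                    nxt[0] = next(
                        b for b in "ACGT"
                        if b != seq[-1] and (len(nxt) < 2 or b != nxt[1])
                    )
                start1, end1 = pos + 1, pos + e.length_bp
                loc = ((start1, end1, "+" if plus else "-"),)
                features.append(Feature("gene", loc, e.gene_name))
                features.append(Feature("CDS", loc, e.gene_name))
                gene_truth_pos[e.gene_name] = {
                    "start": start1, "end": end1,
                    "strand": "+" if plus else "-",
                }
                parts.append(list(seq))
                pos += e.length_bp
                strand += 1
            else:
                motif, reps = payload
                run = motif * reps
                _fix_flanks(parts[-1], motif, chunks[idx + 1])
                ssr_truth.append(
                    {
                        "motif": motif, "repeats": reps,
                        "start": pos + 1, "end": pos + len(run),
                    }
                )
                parts.append(list(run))
                pos += len(run)
            parts.append(chunks[idx + 1])
            pos += len(chunks[idx + 1])
        region = "".join("".join(p) for p in parts)
        assert len(region) == region_fill + sum(
            e.length_bp for e in genes
        ) + sum(len(m) * r for m, r in region_implants)
        return region

    lsc_seq = build_region(lsc_genes, lsc_implants, fill_lsc, 0, 0)
    irb_seq = _clean_filler(fill_ir, p_gc, rng)
    irb_off = lsc_len + 0
    ssc_seq = build_region(ssc_genes, ssc_implants, fill_ssc, lsc_len + ir_len, 1)
    # pin region edges so the IR cannot extend into the single-copy regions
    lsc_seq = "A" + lsc_seq[1:-1] + "A"
    ssc_seq = "A" + ssc_seq[1:-1] + "A"
    ira_seq = reverse_complement(irb_seq)
    genome = lsc_seq + irb_seq + ssc_seq + ira_seq
    assert len(genome) == total_len

    # rRNA annotations inside the IR (mirrored into IRa)
    rrn_len = min(1400, ir_len // 4)
    if rrn_len >= 100:
        b_start = irb_off + ir_len // 8
        features.append(
            Feature("rRNA", ((b_start + 1, b_start + rrn_len, "+"),), "rrn16")
        )
        a_end = total_len - (b_start - irb_off)
        features.append(
            Feature("rRNA", ((a_end - rrn_len + 1, a_end, "-"),), "rrn16")
        )

    record = GenomeRecord(
        accession=spec.accession,
        species=spec.species,
        sequence=genome,
        features=features,
    )
    gc_real = record.gc_fraction
    truth.update(
        {
            "intervals": {
                "LSC": (1, lsc_len),
                "IRb": (lsc_len + 1, lsc_len + ir_len),
                "SSC": (lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len),
                "IRa": (lsc_len + ir_len + ssc_len + 1, total_len),
            },
            "junctions": {
                "JLB": lsc_len + 1,
                "JSB": lsc_len + ir_len + 1,
                "JSA": lsc_len + ir_len + ssc_len + 1,
                "JLA": 1,
            },
            "ssr_implants": ssr_truth,
            "gene_positions": gene_truth_pos,
            "gc_realized": gc_real,
            "length_bp": total_len,
        }
    )
    return record, truth


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a GenomeRecord as a GenBank flat file (circular DNA)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    sr = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=record.species,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": record.species,
        },
    )
    for feat in record.features:
        for start, end, strand in feat.locations:
            sr.features.append(
                SeqFeature(
                    FeatureLocation(start - 1, end, 1 if strand == "+" else -1),
                    type=feat.kind,
                    qualifiers={"gene": [feat.gene_name]} if feat.gene_name else {},
                )
            )
    SeqIO.write(sr, str(path), "genbank")


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
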