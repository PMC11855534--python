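"""Per-gene and aggregate codon-usage statistics.

Implements the classical codon-bias toolkit for plastid coding sequences:

* codon counting (frame 0, terminal stop kept under the stop codons);
* relative synonymous codon usage, RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij),
  the observed count of codon j for amino acid i over its expected count
  under uniform use within the synonymous family of size n_i;
* positional GC content GC1/GC2/GC3 plus GC3s, the GC fraction at
  synonymous third positions (Met, Trp and stops excluded) — the S of the
  expected-ENc curve;
* Wright's effective number of codons, ENc in [20, 61]:
  per-family homozygosity F = (n Σ p² − 1)/(n − 1), and
  ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6 over the degeneracy classes of the
  configured genetic code (plastid table 11: nine 2-fold families, Ile the
  single 3-fold, five 4-fold, Leu/Ser/Arg 6-fold);
* the null expectation ENc* = 2 + S + 29/(S² + (1−S)²) at GC3s = S;
* the codon adaptation index as a geometric mean of relative adaptiveness
  weights w_ij = RSCU_ij / max_j RSCU_ij taken from a reference gene set.

Codons are handled as DNA internally; :func:`to_rna` converts for display
(the field prints codons with U).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonCountTable",
    "RscuTable",
    "GcProfile",
    "EncResult",
    "CaiResult",
    "GeneticCode",
    "count_codons",
    "pool_counts",
    "rscu",
    "gc_profile",
    "enc_observed",
    "enc_expected",
    "cai",
    "per_gene_metrics",
    "rscu_frame",
    "to_rna",
    "to_dna",
]

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.replace("U", "T")


class GeneticCode:
    """Synonymous-family structure of an NCBI translation table.

    ``families`` maps each amino acid to its codon tuple; ``degeneracy`` maps
    each sense codon to its family size.  Single-codon families (Met, Trp in
    table 11) carry no synonymous information and are excluded from GC3s,
    ENc and CAI.
    """

    _cache: dict[int, "GeneticCode"] = {}

    def __init__(self, code: int = 11):
        table = CodonTable.unambiguous_dna_by_id[code]
        self.id = code
        self.forward: dict[str, str] = dict(table.forward_table)
        self.stops: frozenset[str] = frozenset(table.stop_codons)
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.forward.get(codon)
            if aa is not None:
                fams.setdefault(aa, []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cods)) for aa, cods in fams.items()
        }
        self.degeneracy: dict[str, int] = {
            codon: len(cods) for aa, cods in self.families.items() for codon in cods
        }
        self.sense_codons: tuple[str, ...] = tuple(
            c for c in ALL_CODONS if c in self.forward
        )
        self.synonymous_codons: tuple[str, ...] = tuple(
            c for c in self.sense_codons if self.degeneracy[c] > 1
        )

    @classmethod
    def get(cls, code: int = 11) -> "GeneticCode":
        if code not in cls._cache:
            cls._cache[code] = cls(code)
        return cls._cache[code]

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.forward[codon]]


@dataclass
class CodonCountTable:
    """Codon tallies for one gene or a pooled set (``scope='aggregate'``)."""

    scope: str
    counts: dict[str, int]
    genetic_code: int = 11

    def __post_init__(self):
        bad = [c for c, x in self.counts.items() if x < 0]
        if bad:
            raise ValueError(f"negative counts for {bad}")

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def sense_counts(self) -> dict[str, int]:
        code = GeneticCode.get(self.genetic_code)
        return {c: x for c, x in self.counts.items() if c in code.forward and x > 0}


def count_codons(cds: str, scope: str = "gene", code: int = 11) -> CodonCountTable:
    """Frame-0 triplet counts of a CDS whose length is a multiple of 3."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{scope}: CDS length {len(cds)} not a multiple of 3")
    counts: dict[str, int] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(scope=scope, counts=counts, genetic_code=code)


def pool_counts(tables: Iterable[CodonCountTable], scope: str = "aggregate") -> CodonCountTable:
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to pool")
    code = tables[0].genetic_code
    pooled: dict[str, int] = {}
    for t in tables:
        if t.genetic_code != code:
            raise ValueError("mixed genetic codes in pool")
        for c, x in t.counts.items():
            pooled[c] = pooled.get(c, 0) + x
    return CodonCountTable(scope=scope, counts=pooled, genetic_code=code)


@dataclass
class RscuTable:
    scope: str
    rscu: dict[str, float]          # sense codons of observed families only
    family_sizes: dict[str, int]    # codon -> n_i
    genetic_code: int = 11

    def get(self, codon: str) -> float | None:
        return self.rscu.get(to_dna(codon))


def rscu(counts: CodonCountTable) -> RscuTable:
    """RSCU per sense codon; stop codons excluded; a family with zero
    observed codons is reported as missing rather than zero."""
    code = GeneticCode.get(counts.genetic_code)
    values: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for aa, fam in code.families.items():
        total = sum(counts.counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        n_i = len(fam)
        for c in fam:
            values[c] = counts.counts.get(c, 0) * n_i / total
            sizes[c] = n_i
    return RscuTable(
        scope=counts.scope, rscu=values, family_sizes=sizes,
        genetic_code=counts.genetic_code,
    )


@dataclass
class GcProfile:
    """Positional GC of one CDS.  ``gc12`` is derived, never stored."""

    gene_id: str
    gc1: float
    gc2: float
    gc3: float
    gc3s: float | None  # None when the gene has no synonymous codons
    gc_all: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2


def _gc(chars: Sequence[str]) -> float:
    return sum(ch in "GC" for ch in chars) / len(chars)


def gc_profile(cds: str, gene_id: str = "gene", code: int = 11) -> GcProfile:
    """GC1/GC2/GC3 over all codons (terminal stop dropped) and GC3s over
    synonymous third positions only."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length not a multiple of 3")
    gcode = GeneticCode.get(code)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in gcode.stops:
        codons = codons[:-1]
    if not codons:
        raise ValueError(f"{gene_id}: no codons left after stop removal")
    p1 = [c[0] for c in codons]
    p2 = [c[1] for c in codons]
    p3 = [c[2] for c in codons]
    syn3 = [c[2] for c in codons if gcode.degeneracy.get(c, 0) > 1]
    return GcProfile(
        gene_id=gene_id,
        gc1=_gc(p1),
        gc2=_gc(p2),
        gc3=_gc(p3),
        gc3s=_gc(syn3) if syn3 else None,
        gc_all=_gc(p1 + p2 + p3),
    )


@dataclass
class EncResult:
    gene_id: str
    enc: float | None  # None when undefined (too few usable families)
    f_means: dict[int, float | None] = field(default_factory=dict)
    capped: bool = False
    f3_substituted: bool = False


def _family_homozygosity(counts: Mapping[str, int], fam: Sequence[str]) -> tuple[int, float] | None:
    n = sum(counts.get(c, 0) for c in fam)
    if n < 2:
        return None
    s = sum((counts.get(c, 0) / n) ** 2 for c in fam)
    f = (n * s - 1) / (n - 1)
    return n, f


def enc_observed(counts: CodonCountTable) -> EncResult:
    """Wright's ENc estimator with CodonW-style missing-family handling.

    Families with fewer than two codons observed are dropped from their
    degeneracy class; a missing 3-fold class mean is replaced by
    (F̄2 + F̄4)/2; any other missing class leaves the gene undefined.  The
    estimate is capped to [20, 61].
    """
    code = GeneticCode.get(counts.genetic_code)
    by_class: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    for aa, fam in code.families.items():
        k = len(fam)
        if k < 2:
            continue
        class_sizes[k] = class_sizes.get(k, 0) + 1
        hf = _family_homozygosity(counts.counts, fam)
        if hf is not None:
            by_class.setdefault(k, []).append(hf[1])
    f_means: dict[int, float | None] = {
        k: (sum(v) / len(v) if v else None)
        for k, v in ((k, by_class.get(k, [])) for k in class_sizes)
    }
    f3_sub = False
    if f_means.get(3) is None and f_means.get(2) and f_means.get(4):
        f_means[3] = (f_means[2] + f_means[4]) / 2
        f3_sub = True
    if any(f_means.get(k) in (None, 0.0) for k in class_sizes):
        return EncResult(counts.scope, None, f_means, f3_substituted=f3_sub)
    enc = 2.0 + sum(class_sizes[k] / f_means[k] for k in class_sizes)
    capped = not (20.0 <= enc <= 61.0)
    enc = min(max(enc, 20.0), 61.0)
    return EncResult(counts.scope, enc, f_means, capped=capped, f3_substituted=f3_sub)


def enc_expected(s: float) -> float:
    """Null ENc at GC3s = s assuming mutation alone shapes third positions:
    ENc* = 2 + s + 29/(s² + (1−s)²)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass
class CaiResult:
    gene_id: str
    cai: float | None
    reference_id: str


def cai(
    counts: CodonCountTable,
    reference: RscuTable,
    unobserved_weight: float = 0.01,
) -> CaiResult:
    """Codon adaptation index against a reference RSCU table (Sharp–Li
    convention): geometric mean of w = RSCU/RSCUmax over the gene's codons,
    Met/Trp/stops excluded.  Codons absent from the reference get a small
    smoothing weight; families wholly unobserved in the reference are
    uninformative and skipped."""
    code = GeneticCode.get(counts.genetic_code)
    weights: dict[str, float] = {}
    for aa, fam in code.families.items():
        if len(fam) < 2:
            continue
        vals = [reference.rscu.get(c) for c in fam]
        if all(v is None for v in vals):
            continue
        top = max(v for v in vals if v is not None)
        if top <= 0:
            continue
        for c, v in zip(fam, vals):
            w = (v if v else 0.0) / top
            weights[c] = max(w, unobserved_weight)
    log_sum, n = 0.0, 0
    for c, x in counts.counts.items():
        if c in weights:
            log_sum += x * math.log(weights[c])
            n += x
    if n == 0:
        return CaiResult(counts.scope, None, reference.scope)
    return CaiResult(counts.scope, math.exp(log_sum / n), reference.scope)


# ---------------------------------------------------------------------------
# Tabular surfaces
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["gene", "L_aa", "gc1", "gc2", "gc3", "gc3s", "gc_all", "enc", "cai"]


def per_gene_metrics(
    entries: Sequence,  # CdsEntry-like: gene_name, sequence, l_aa
    code: int = 11,
    cai_reference: RscuTable | None = None,
) -> pd.DataFrame:
    """One row per gene: L_aa, positional GC, ENc and (optionally) CAI."""
    rows = []
    for e in entries:
        counts = count_codons(e.sequence, scope=e.gene_name, code=code)
        prof = gc_profile(e.sequence, gene_id=e.gene_name, code=code)
        enc = enc_observed(counts)
        cai_val = (
            cai(counts, cai_reference).cai if cai_reference is not None else None
        )
        rows.append(
            {
                "gene": e.gene_name,
                "L_aa": e.l_aa,
                "gc1": prof.gc1,
                "gc2": prof.gc2,
                "gc3": prof.gc3,
                "gc3s": prof.gc3s,
                "gc_all": prof.gc_all,
                "enc": enc.enc,
                "cai": cai_val,
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def rscu_frame(counts: CodonCountTable) -> pd.DataFrame:
    """Aggregate RSCU as a table: codon (RNA), amino_acid, count, rscu."""
    code = GeneticCode.get(counts.genetic_code)
    table = rscu(counts)
    rows = []
    for codon in code.sense_codons:
        if codon not in table.rscu:
            continue
        rows.append(
            {
                "codon": to_rna(codon),
                "amino_acid": code.forward[codon],
                "count": counts.counts.get(codon, 0),
                "rscu": table.rscu[codon],
            }
        )
    return pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "rscu"])
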