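"""Optimal-codon determination from ENc-extreme gene libraries.

Genes are ranked by their effective number of codons; the lowest-ENc 10%
(most biased, taken as a proxy for highly expressed genes) and the
highest-ENc 10% form the high- and low-bias libraries.  Pooled RSCU tables
are computed for each library and ΔRSCU = RSCU_high − RSCU_low measures how
strongly each codon is enriched where bias is strong.  A codon is
*high-frequency* when its genome-wide RSCU exceeds 1, and *optimal* when it
is high-frequency and ΔRSCU ≥ 0.08.  Cross-species comparison intersects
the per-genome optimal sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .codon_metrics import (
    CodonCountTable,
    EncResult,
    GeneticCode,
    RscuTable,
    pool_counts,
    rscu,
    to_rna,
)

__all__ = [
    "OptimalCodonReport",
    "build_bias_libraries",
    "delta_rscu",
    "optimal_codon_set",
    "intersect_species",
]


@dataclass
class OptimalCodonReport:
    accession: str
    high_bias_library: list[str]
    low_bias_library: list[str]
    rscu_high: RscuTable
    rscu_low: RscuTable
    rscu_all: RscuTable
    delta_rscu: dict[str, float]
    high_frequency: set[str]     # DNA codons, RSCU_all > 1
    optimal: set[str]            # DNA codons, RSCU_all > 1 and dRSCU >= 0.08
    flagged_codons: set[str] = field(default_factory=set)

    @property
    def optimal_rna(self) -> set[str]:
        return {to_rna(c) for c in self.optimal}

    def ending_base_fractions(self) -> dict[str, float]:
        """A/U/G/C shares among the high-frequency codons' third bases."""
        if not self.high_frequency:
            return {}
        thirds = [to_rna(c)[2] for c in self.high_frequency]
        return {b: thirds.count(b) / len(thirds) for b in "AUGC"}

    def to_frame(self, code: int = 11) -> pd.DataFrame:
        gcode = GeneticCode.get(code)
        rows = []
        for codon in gcode.sense_codons:
            if codon not in self.rscu_all.rscu:
                continue
            rows.append(
                {
                    "codon": to_rna(codon),
                    "amino_acid": gcode.forward[codon],
                    "rscu_all": self.rscu_all.rscu.get(codon),
                    "rscu_high": self.rscu_high.rscu.get(codon),
                    "rscu_low": self.rscu_low.rscu.get(codon),
                    "delta_rscu": self.delta_rscu.get(codon),
                    "high_frequency": codon in self.high_frequency,
                    "optimal": codon in self.optimal,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "codon", "amino_acid", "rscu_all", "rscu_high", "rscu_low",
                "delta_rscu", "high_frequency", "optimal",
            ],
        )


def build_bias_libraries(
    encs: list[EncResult], fraction: float = 0.10, min_size: int = 2
) -> tuple[list[str], list[str]]:
    """(high-bias, low-bias) gene-id libraries from the ENc extremes.

    Genes sort ascending by ENc with gene-name tie-breaks; the low-ENc end
    is the high-bias library.  Library size is ceil(fraction·N) with a floor
    of ``min_size``.
    """
    usable = [(e.enc, e.gene_id) for e in encs if e.enc is not None]
    if len(usable) < 10:
        raise ValueError(
            f"only {len(usable)} genes with defined ENc; need >= 10 "
            "(increase the library fraction on small gene sets)"
        )
    usable.sort()
    k = max(math.ceil(fraction * len(usable)), min_size)
    high_bias = [g for _, g in usable[:k]]
    low_bias = [g for _, g in usable[-k:]]
    return high_bias, low_bias


def _pooled_rscu(
    counts_by_gene: dict[str, CodonCountTable], genes: list[str], scope: str
) -> RscuTable:
    return rscu(pool_counts([counts_by_gene[g] for g in genes], scope=scope))


def delta_rscu(
    rscu_high: RscuTable, rscu_low: RscuTable
) -> tuple[dict[str, float], set[str]]:
    """Per-codon RSCU_high − RSCU_low; codons missing from either table are
    returned in the flagged set instead of the delta map."""
    deltas: dict[str, float] = {}
    flagged: set[str] = set()
    for codon in set(rscu_high.rscu) | set(rscu_low.rscu):
        hi = rscu_high.rscu.get(codon)
        lo = rscu_low.rscu.get(codon)
        if hi is None or lo is None:
            flagged.add(codon)
            continue
        deltas[codon] = hi - lo
    return deltas, flagged


def optimal_codon_set(
    counts_by_gene: dict[str, CodonCountTable],
    encs: list[EncResult],
    accession: str = "",
    fraction: float = 0.10,
    delta_threshold: float = 0.08,
    high_frequency_on: str = "all",
) -> OptimalCodonReport:
    """Full optimal-codon determination for one genome.

    ``high_frequency_on`` selects which pooled RSCU the ``> 1`` test uses:
    ``'all'`` (genome-wide, default — the reported high-frequency counts are
    genome-wide) or ``'high'`` (the high-bias library).
    """
    high_lib, low_lib = build_bias_libraries(encs, fraction=fraction)
    rscu_high = _pooled_rscu(counts_by_gene, high_lib, "high_bias")
    rscu_low = _pooled_rscu(counts_by_gene, low_lib, "low_bias")
    rscu_all = rscu(pool_counts(counts_by_gene.values(), scope="all_genes"))
    deltas, flagged = delta_rscu(rscu_high, rscu_low)
    base = rscu_all if high_frequency_on == "all" else rscu_high
    gcode = GeneticCode.get(rscu_all.genetic_code)
    multi = {c for c in gcode.synonymous_codons}
    high_frequency = {c for c, v in base.rscu.items() if v > 1.0 and c in multi}
    optimal = {
        c for c in high_frequency if deltas.get(c, float("-inf")) >= delta_threshold
    }
    return OptimalCodonReport(
        accession=accession,
        high_bias_library=high_lib,
        low_bias_library=low_lib,
        rscu_high=rscu_high,
        rscu_low=rscu_low,
        rscu_all=rscu_all,
        delta_rscu=deltas,
        high_frequency=high_frequency,
        optimal=optimal,
        flagged_codons=flagged,
    )


def intersect_species(
    reports: list[OptimalCodonReport],
) -> tuple[set[str], set[str], pd.DataFrame]:
    """(intersection, union, presence matrix) of optimal codons across
    genomes; the matrix has RNA codons as rows and accessions as columns."""
    if len(reports) < 2:
        raise ValueError("need at least 2 genome reports to intersect")
    sets = [r.optimal for r in reports]
    common = set.intersection(*sets)
    union = set.union(*sets)
    rows = []
    for codon in sorted(union):
        row = {"codon": to_rna(codon)}
        for r in reports:
            row[r.accession or "genome"] = codon in r.optimal
        rows.append(row)
    matrix = pd.DataFrame(rows).set_index("codon") if rows else pd.DataFrame()
    return common, union, matrix
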