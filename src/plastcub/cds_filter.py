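"""Coding-sequence quality filter.

Four rules decide whether an annotated CDS enters the codon-usage analysis:

1. the length must be a multiple of three (complete codons);
2. the sequence must be at least 300 bp (stable codon statistics);
3. only the standard bases A/C/G/T may occur;
4. no internal stop codon under the configured genetic code.

Stop codons come from the bacterial/plastid code (NCBI translation
table 11) by default.  A terminal stop is allowed and excluded from the
amino-acid length ``L_aa``; a CDS lacking one is still retained, since only
internal stops are disqualifying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

__all__ = ["CdsEntry", "CdsSet", "filter_cds", "stop_codons", "dedupe_by_gene"]


def stop_codons(code: int = 11) -> frozenset[str]:
    """Stop codons of an NCBI genetic-code table."""
    return frozenset(CodonTable.unambiguous_dna_by_id[code].stop_codons)


@dataclass(frozen=True)
class CdsEntry:
    gene_name: str
    sequence: str
    length_bp: int
    l_aa: int  # amino-acid count, terminal stop excluded


@dataclass
class CdsSet:
    """Retained/rejected partition of a genome's coding sequences."""

    accession: str
    entries: list[CdsEntry] = field(default_factory=list)
    rejected: list[tuple[str, int, list[int]]] = field(default_factory=list)
    genetic_code: int = 11

    @property
    def gene_names(self) -> list[str]:
        return [e.gene_name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": e.gene_name, "length_bp": e.length_bp, "retained": True,
             "rules_failed": ""}
            for e in self.entries
        ]
        rows += [
            {"gene": g, "length_bp": -1, "retained": False,
             "rules_failed": ",".join(map(str, all_rules))}
            for g, _first, all_rules in self.rejected
        ]
        return pd.DataFrame(rows, columns=["gene", "length_bp", "retained", "rules_failed"])


def _violations(seq: str, min_len: int, stops: frozenset[str]) -> list[int]:
    failed = []
    if len(seq) % 3 != 0:
        failed.append(1)
    if len(seq) < min_len:
        failed.append(2)
    if set(seq) - set("ACGT"):
        failed.append(3)
    if 1 not in failed and 3 not in failed:
        internal = (seq[i : i + 3] for i in range(0, len(seq) - 3, 3))
        if any(codon in stops for codon in internal):
            failed.append(4)
    return failed


def filter_cds(
    raw: list[tuple[str, str]],
    accession: str = "",
    min_len: int = 300,
    code: int = 11,
    deduplicate: bool = True,
) -> CdsSet:
    """Apply the four selection rules to ``(gene, sequence)`` pairs.

    Rules are evaluated in order 1..4 and the first violated rule is recorded
    per rejection (all violations are kept alongside for diagnostics).  Input
    order is preserved.  ``deduplicate`` drops repeat copies of a gene name
    (the IR-duplicated genes) keeping the first, before the rules run, so
    per-genome gene counts match unique-gene tallies.
    """
    if not raw:
        warnings.warn(f"{accession or 'CDS set'}: empty input")
        return CdsSet(accession=accession, genetic_code=code)
    if deduplicate:
        raw = dedupe_by_gene(raw)
    stops = stop_codons(code)
    out = CdsSet(accession=accession, genetic_code=code)
    for gene, seq in raw:
        seq = seq.upper()
        failed = _violations(seq, min_len, stops)
        if failed:
            out.rejected.append((gene, failed[0], failed))
            continue
        has_term_stop = seq[-3:] in stops
        l_aa = len(seq) // 3 - (1 if has_term_stop else 0)
        out.entries.append(CdsEntry(gene, seq, len(seq), l_aa))
    return out


def dedupe_by_gene(raw: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Keep the first copy per base gene name (strips ``_2``-style suffixes
    added for IR duplicates)."""
    seen: set[str] = set()
    out = []
    for gene, seq in raw:
        base = gene.rsplit("_", 1)[0] if gene.rsplit("_", 1)[-1].isdigit() else gene
        if base in seen:
            continue
        seen.add(base)
        out.append((gene, seq))
    return out
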