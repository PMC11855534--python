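"""Plastome records: GenBank/FASTA input, CDS extraction, quadripartite structure.

Chloroplast genomes are circular molecules with a conserved four-part
architecture: a large single-copy region (LSC), a small single-copy region
(SSC) and two inverted repeats (IRa/IRb) separating them.  This module reads
annotated records, pulls out coding sequences (handling joined and
origin-spanning locations), locates the IR pair by maximal
reverse-complement matching, and reports the genes flanking the four
junctions JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC).

Coordinates are 1-based inclusive on the public surface (GenBank
convention) and 0-based half-open internally; :func:`to_internal` /
:func:`to_external` convert between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "GenomeRecord",
    "QuadripartiteStructure",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "extract_cds",
    "detect_quadripartite",
    "junction_report",
    "reverse_complement",
    "to_internal",
    "to_external",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "gene", "other")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (uppercase)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


@dataclass(frozen=True)
class Feature:
    """One annotated feature.

    ``locations`` holds ``(start, end, strand)`` segments, 1-based inclusive,
    in annotation order; origin-spanning locations appear as two segments.
    """

    kind: str
    locations: tuple[tuple[int, int, str], ...]
    gene_name: str = ""
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            object.__setattr__(self, "kind", "other")
        for start, end, strand in self.locations:
            if not (1 <= start <= end):
                raise ValueError(
                    f"feature {self.gene_name or self.kind}: bad segment "
                    f"({start}, {end})"
                )
            if strand not in "+-":
                raise ValueError(f"feature {self.gene_name}: strand {strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Overall (min start, max end), 1-based inclusive."""
        return (
            min(s for s, _, _ in self.locations),
            max(e for _, e, _ in self.locations),
        )

    @property
    def strand(self) -> str:
        """Strand of the first segment (plastome features are single-strand)."""
        return self.locations[0][2]


@dataclass
class GenomeRecord:
    """A plastome: sequence plus its annotated features."""

    accession: str
    species: str
    sequence: str
    features: list[Feature]

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        if not self.accession:
            raise ValueError("accession must be non-empty")
        for feat in self.features:
            for start, end, _ in feat.locations:
                if end > self.length_bp:
                    raise ValueError(
                        f"feature {feat.gene_name or feat.kind}: segment end "
                        f"{end} beyond genome length {self.length_bp}"
                    )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    def segment(self, start: int, end: int) -> str:
        """Sequence of a 1-based inclusive interval; wraps past the origin
        when start > end."""
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals (1-based inclusive; wrap allowed) and the
    four junction positions, each the first base of the downstream region."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    ir_found: bool = True
    mismatches: int = 0

    def _ilen(self, iv: tuple[int, int]) -> int:
        s, e = iv
        if s == 0 and e == 0:
            return 0
        return (e - s) % self.genome_length + 1

    @property
    def lengths(self) -> dict[str, int]:
        return {
            "LSC": self._ilen(self.lsc),
            "IRb": self._ilen(self.irb),
            "SSC": self._ilen(self.ssc),
            "IRa": self._ilen(self.ira),
        }

    @property
    def junctions(self) -> dict[str, int]:
        """JLB/JSB/JSA/JLA as the 1-based first base of IRb/SSC/IRa/LSC."""
        return {
            "JLB": self.irb[0],
            "JSB": self.ssc[0],
            "JSA": self.ira[0],
            "JLA": self.lsc[0],
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _from_seqfeature(sf) -> Feature:
    kind = sf.type if sf.type in FEATURE_KINDS else "other"
    segments = []
    for part in sf.location.parts:
        strand = "-" if part.strand == -1 else "+"
        segments.append((int(part.start) + 1, int(part.end), strand))
    gene = sf.qualifiers.get("gene", [""])[0]
    quals = {k: v[0] if len(v) == 1 else list(v) for k, v in sf.qualifiers.items()}
    return Feature(kind=kind, locations=tuple(segments), gene_name=gene, qualifiers=quals)


def read_genbank(path) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    CDS/tRNA/rRNA/gene features are captured in file order with joined
    locations preserved; the sequence is uppercased.  A record without an
    ORIGIN sequence is a parse error.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"{path}: GenBank record has no usable ORIGIN sequence")
    feats = []
    for sf in record.features:
        if sf.type == "source":
            continue
        try:
            feats.append(_from_seqfeature(sf))
        except Exception as exc:  # malformed location -> name the feature
            gene = sf.qualifiers.get("gene", ["?"])[0]
            raise ValueError(
                f"{path}: malformed location on {sf.type} feature {gene}: {exc}"
            ) from exc
    species = record.annotations.get("organism", "") or record.description
    return GenomeRecord(
        accession=record.id or record.name,
        species=species,
        sequence=seq,
        features=feats,
    )


def read_fasta(path, accession: str | None = None) -> GenomeRecord:
    """Read a single-sequence FASTA into a featureless record."""
    record = SeqIO.read(str(path), "fasta")
    return GenomeRecord(
        accession=accession or record.id,
        species=record.description,
        sequence=str(record.seq).upper(),
        features=[],
    )


def write_fasta(record: GenomeRecord, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.accession} {record.species}\n")
        for i in range(0, record.length_bp, width):
            fh.write(record.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def _extract_feature_seq(record: GenomeRecord, feat: Feature) -> str:
    """Concatenate a feature's segments in annotation order; a uniformly
    minus-strand feature is reverse-complemented as a whole (segments are
    annotated in genomic order), mixed-strand joins per segment."""
    strands = {s for _, _, s in feat.locations}
    if strands == {"-"}:
        joined = "".join(record.segment(s, e) for s, e, _ in feat.locations)
        return reverse_complement(joined)
    parts = []
    for s, e, strand in feat.locations:
        seg = record.segment(s, e)
        parts.append(reverse_complement(seg) if strand == "-" else seg)
    return "".join(parts)


def extract_cds(record: GenomeRecord) -> list[tuple[str, str]]:
    """All annotated CDS nucleotide sequences as ``(gene_name, sequence)``.

    Multi-segment locations are concatenated in annotation order and
    minus-strand features reverse-complemented.  Duplicate gene names (the
    IR-duplicated genes, trans-spliced rps12 blocks) get positional suffixes
    ``_2``, ``_3``, ... so downstream tables stay keyed by unique ids.
    """
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    cds_feats = [f for f in record.features if f.kind == "CDS"]
    if not cds_feats:
        warnings.warn(f"{record.accession}: no CDS features annotated")
        return out
    for idx, feat in enumerate(cds_feats):
        name = feat.gene_name or f"cds{idx + 1}"
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            name = f"{name}_{seen[name]}"
        out.append((name, _extract_feature_seq(record, feat)))
    return out


# ---------------------------------------------------------------------------
# Quadripartite structure
# ---------------------------------------------------------------------------

_MOD = (1 << 61) - 1
_BASE = 131


def _prefix_hashes(s: str) -> list[int]:
    h = [0] * (len(s) + 1)
    for i, ch in enumerate(s):
        h[i + 1] = (h[i] * _BASE + ord(ch)) % _MOD
    return h


def _window_hash(pref: list[int], pows: list[int], i: int, length: int) -> int:
    return (pref[i + length] - pref[i] * pows[length]) % _MOD


def _circ_overlap(a: int, b: int, length: int, n: int) -> bool:
    """Do circular intervals [a, a+length) and [b, b+length) (mod n) overlap?"""
    return ((b - a) % n) < length or ((a - b) % n) < length


def _find_ir_pair(seq: str, min_len: int) -> tuple[int, int, int] | None:
    """Longest disjoint reverse-complement pair on the circle.

    Returns ``(a, b, L)`` with 0-based circular starts of the two copies
    (seq[a:a+L] on the circle equals the reverse complement of seq[b:b+L]),
    or None if nothing >= min_len exists.  Rolling-hash binary search on the
    doubled sequence.
    """
    n = len(seq)
    if n < 2 * min_len:
        return None
    s2 = seq + seq
    r2 = reverse_complement(s2)
    max_l = n // 2
    pows = [1] * (2 * n + 1)
    for i in range(1, 2 * n + 1):
        pows[i] = pows[i - 1] * _BASE % _MOD
    ps = _prefix_hashes(s2)
    pr = _prefix_hashes(r2)

    def doubled(src: str, a: int, length: int) -> str:
        return src[a : a + length]

    def probe(length: int) -> tuple[int, int] | None:
        table: dict[int, list[int]] = {}
        for q in range(n):
            table.setdefault(_window_hash(pr, pows, q, length), []).append(q)
        for p in range(n):
            hits = table.get(_window_hash(ps, pows, p, length))
            if not hits:
                continue
            for q in hits:
                b = (-q - length) % n  # genomic start of the partner copy
                if _circ_overlap(p, b, length, n):
                    continue
                if doubled(s2, p, length) == doubled(r2, q, length):
                    return p, b
        return None

    lo, hi, best = min_len, max_l, None
    while lo <= hi:
        mid = (lo + hi) // 2
        hit = probe(mid)
        if hit is not None:
            best = (hit[0], hit[1], mid)
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def _extend_with_mismatches(
    seq: str, a: int, b: int, length: int, rate: float = 0.001
) -> tuple[int, int, int, int]:
    """Symmetric outward extension of an IR pair tolerating a small mismatch
    rate (annotation-grade noise).  Copy A grows left as copy B grows right,
    and vice versa; stops before the copies would touch."""
    n = len(seq)
    comp = str.maketrans("ACGT", "TGCA")

    def base(i: int) -> str:
        return seq[i % n]

    mism = 0
    budget = int(rate * length)
    # grow A-left / B-right
    while budget and ((b + length) % n) != a % n:
        x, y = base(a - 1), base(b + length)
        if x in "ACGT" and y in "ACGT" and x != y.translate(comp):
            if mism + 1 > budget:
                break
            mism += 1
        a -= 1
        length += 1
        budget = int(rate * length)
        if length >= n // 2:
            break
    return a % n, b % n, length, mism


def detect_quadripartite(
    record: GenomeRecord, min_ir_len: int = 1000, mismatch_rate: float = 0.0
) -> QuadripartiteStructure:
    """Locate the inverted-repeat pair and partition the circle.

    The longest pair of disjoint, reverse-complementary segments is taken as
    IRa/IRb; of the two single-copy gaps the longer is the LSC, the shorter
    the SSC.  IRb is the repeat copy immediately downstream of the LSC, so
    walking the circle reads LSC, IRb, SSC, IRa.  With no repeat >=
    ``min_ir_len`` the structure comes back flagged (``ir_found=False``) with
    empty IRs.
    """
    n = record.length_bp
    hit = _find_ir_pair(record.sequence, min_ir_len)
    if hit is None:
        return QuadripartiteStructure(
            lsc=(1, n), irb=(0, 0), ssc=(0, 0), ira=(0, 0),
            genome_length=n, ir_found=False,
        )
    a, b, length = hit
    mism = 0
    if mismatch_rate > 0:
        a, b, length, mism = _extend_with_mismatches(
            record.sequence, a, b, length, mismatch_rate
        )
    # gaps between the two copies, walking forward from each copy's end
    gap_ab = (b - (a + length)) % n  # from end of copy A to start of copy B
    gap_ba = (a - (b + length)) % n
    if gap_ab >= gap_ba:
        # longer gap follows copy A -> copy A precedes the LSC... the LSC is
        # the longer single-copy stretch; IRb is the copy right after it.
        lsc0 = (a + length) % n
        lsc_len, ssc_len = gap_ab, gap_ba
        irb0, ira0 = b, a
    else:
        lsc0 = (b + length) % n
        lsc_len, ssc_len = gap_ba, gap_ab
        irb0, ira0 = a, b

    def iv(start0: int, length_: int) -> tuple[int, int]:
        return (start0 % n + 1, (start0 + length_ - 1) % n + 1)

    return QuadripartiteStructure(
        lsc=iv(lsc0, lsc_len),
        irb=iv(irb0, length),
        ssc=iv((irb0 + length) % n, ssc_len),
        ira=iv(ira0, length),
        genome_length=n,
        mismatches=mism,
    )


# ---------------------------------------------------------------------------
# Junction report
# ---------------------------------------------------------------------------

_JUNCTION_SIDES = {
    "JLB": ("LSC", "IRb"),
    "JSB": ("IRb", "SSC"),
    "JSA": ("SSC", "IRa"),
    "JLA": ("IRa", "LSC"),
}


def junction_report(
    structure: QuadripartiteStructure,
    features: Sequence[Feature],
    kinds: Iterable[str] = ("gene",),
) -> pd.DataFrame:
    """Nearest feature on each side of every junction, with gap/overlap sizes.

    For each of JLB/JSB/JSA/JLA two rows are emitted (upstream and downstream
    side).  ``distance_bp`` is the gap between the feature edge and the
    junction (0 when abutting or straddling); ``overlap_bp`` is how far a
    straddling feature extends past the junction into the neighbouring
    region.  Distances are circular.
    """
    n = structure.genome_length
    rows = []
    feats = [f for f in features if f.kind in set(kinds)]
    if not feats and features:
        feats = [f for f in features if f.kind in ("CDS", "tRNA", "rRNA")]
    if not structure.ir_found:
        return pd.DataFrame(
            columns=["region", "junction", "gene", "side", "distance_bp", "overlap_bp"]
        )
    for jname, jpos in structure.junctions.items():
        up_region, down_region = _JUNCTION_SIDES[jname]
        j0 = jpos - 1  # 0-based first base of downstream region
        best_up = best_down = None  # (gap, feature, overlap)
        for f in feats:
            s, e = f.span
            s0, e0 = s - 1, e - 1
            flen = e0 - s0 + 1
            straddle = ((j0 - s0) % n) < flen and ((j0 - s0) % n) > 0
            if straddle:
                over_down = (e0 - j0) % n + 1  # bases in downstream region
                over_up = flen - over_down
                cand_up = (0, f, over_down)   # upstream gene extending down
                cand_down = (0, f, over_up)   # seen from downstream side
                if best_up is None or cand_up[0] < best_up[0]:
                    best_up = cand_up
                if best_down is None or cand_down[0] < best_down[0]:
                    best_down = cand_down
                continue
            gap_up = (j0 - 1 - e0) % n  # feature wholly upstream
            gap_down = (s0 - j0) % n
            if gap_up <= gap_down:
                if best_up is None or gap_up < best_up[0]:
                    best_up = (gap_up, f, 0)
            else:
                if best_down is None or gap_down < best_down[0]:
                    best_down = (gap_down, f, 0)
        for side_region, best in ((up_region, best_up), (down_region, best_down)):
            if best is None:
                continue
            gap, f, over = best
            rows.append(
                {
                    "region": side_region,
                    "junction": jname,
                    "gene": f.gene_name or f.kind,
                    "side": "upstream" if side_region == up_region else "downstream",
                    "distance_bp": gap,
                    "overlap_bp": over,
                }
            )
    return pd.DataFrame(rows, columns=["region", "junction", "gene", "side", "distance_bp", "overlap_bp"])
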