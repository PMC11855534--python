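"""Plot-style codon-bias analyses as plain computations.

Four classical diagnostics separate mutational pressure from selection in
shaping codon usage:

* the ENc-plot compares each gene's observed effective number of codons
  with the mutation-only expectation at its GC3s — genes falling below the
  curve use fewer codons than composition alone predicts (selection);
* the PR2-bias plot places each gene at (G3/(G3+C3), A3/(A3+T3)) over
  fourfold-degenerate third positions — (0.5, 0.5) means no strand or
  selection asymmetry between complementary bases;
* the neutrality plot regresses GC12 on GC3 across genes — a slope near 1
  means third and first/second positions drift together (mutation), near 0
  means first/second positions are held constant by selection;
* correspondence analysis of the genes × codons RSCU table decomposes the
  usage variation into orthogonal axes (inertia shares), and the axis
  scores are correlated with ENc, CAI, GC3 and gene length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import (
    CodonCountTable,
    EncResult,
    GcProfile,
    GeneticCode,
    RscuTable,
    enc_expected,
    to_rna,
)

__all__ = [
    "Pr2Point",
    "NeutralityFit",
    "CoaResult",
    "CorrelationMatrix",
    "enc_plot_points",
    "pr2_points",
    "pr2_quadrants",
    "neutrality_fit",
    "coa",
    "rscu_matrix",
    "correlate_indices",
    "functional_class",
]


# ---------------------------------------------------------------------------
# ENc plot
# ---------------------------------------------------------------------------


def enc_plot_points(
    profiles: list[GcProfile], encs: list[EncResult]
) -> pd.DataFrame:
    """Per-gene (gc3s, enc, expected_enc, deviation = expected − observed).

    Genes lacking GC3s or a defined ENc are excluded.  A positive deviation
    means the gene lies below the mutation-only curve.
    """
    enc_by_gene = {e.gene_id: e.enc for e in encs}
    rows = []
    for p in profiles:
        enc = enc_by_gene.get(p.gene_id)
        if p.gc3s is None or enc is None:
            continue
        exp = enc_expected(p.gc3s)
        rows.append(
            {
                "gene": p.gene_id,
                "gc3s": p.gc3s,
                "enc": enc,
                "expected_enc": exp,
                "deviation": exp - enc,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "gc3s", "enc", "expected_enc", "deviation"])


def genes_above_enc(points: pd.DataFrame, threshold: float = 45.0) -> int:
    return int((points["enc"] > threshold).sum())


# ---------------------------------------------------------------------------
# PR2 bias plot
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pr2Point:
    gene_id: str
    x: float | None  # G3/(G3+C3)
    y: float | None  # A3/(A3+T3)

    @property
    def defined(self) -> bool:
        return self.x is not None and self.y is not None


def _third_base_tallies(
    counts: CodonCountTable, scope: str
) -> dict[str, int]:
    code = GeneticCode.get(counts.genetic_code)
    if scope == "fourfold":
        eligible = {c for c in code.sense_codons if code.degeneracy[c] == 4}
    elif scope == "all":
        eligible = set(code.synonymous_codons)
    else:
        raise ValueError(f"unknown PR2 scope {scope!r}")
    tally = {"A": 0, "C": 0, "G": 0, "T": 0}
    for codon, x in counts.counts.items():
        if codon in eligible:
            tally[codon[2]] += x
    return tally


def pr2_points(
    counts_per_gene: list[CodonCountTable], scope: str = "fourfold"
) -> list[Pr2Point]:
    """PR2 coordinates per gene.  Default scope uses third positions of the
    fourfold-degenerate families only; ``scope='all'`` uses every synonymous
    third position.  A zero denominator flags the point undefined."""
    points = []
    for counts in counts_per_gene:
        t = _third_base_tallies(counts, scope)
        gc = t["G"] + t["C"]
        at = t["A"] + t["T"]
        points.append(
            Pr2Point(
                gene_id=counts.scope,
                x=t["G"] / gc if gc else None,
                y=t["A"] / at if at else None,
            )
        )
    return points


def pr2_quadrants(points: list[Pr2Point]) -> dict[str, int]:
    """Counts per quadrant keyed by e.g. 'x<0.5,y<0.5' (center points tally
    toward the < side only when strictly below)."""
    keys = {
        (True, True): "x<0.5,y<0.5",
        (True, False): "x<0.5,y>=0.5",
        (False, True): "x>=0.5,y<0.5",
        (False, False): "x>=0.5,y>=0.5",
    }
    out = {k: 0 for k in keys.values()}
    for p in points:
        if not p.defined:
            continue
        out[keys[(p.x < 0.5, p.y < 0.5)]] += 1
    return out


def pr2_frame(points: list[Pr2Point]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": p.gene_id, "g3_over_gc3": p.x, "a3_over_at3": p.y} for p in points],
        columns=["gene", "g3_over_gc3", "a3_over_at3"],
    )


# ---------------------------------------------------------------------------
# Neutrality plot
# ---------------------------------------------------------------------------


@dataclass
class NeutralityFit:
    pairs: pd.DataFrame  # columns gene, gc12, gc3
    slope: float
    intercept: float
    pearson_r: float
    p_value: float

    @property
    def mutational_pressure_percent(self) -> float:
        """Slope × 100: the share of the usage pattern attributable to
        mutational pressure under the neutrality-plot reading."""
        return self.slope * 100.0


def neutrality_fit(profiles: list[GcProfile]) -> NeutralityFit:
    """OLS of GC12 on GC3 across genes, with the Pearson correlation."""
    rows = [
        {"gene": p.gene_id, "gc12": p.gc12, "gc3": p.gc3} for p in profiles
    ]
    if len(rows) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    frame = pd.DataFrame(rows)
    if np.isclose(frame["gc3"].var(ddof=0), 0.0):
        raise ValueError("GC3 has zero variance; neutrality fit undefined")
    res = stats.linregress(frame["gc3"], frame["gc12"])
    return NeutralityFit(
        pairs=frame,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------

_CLASS_PREFIXES = (
    ("rpo", "genetic system"),
    ("inf", "genetic system"),
    ("rps", "ribosomal protein"),
    ("rpl", "ribosomal protein"),
    ("psa", "photosystem"),
    ("psb", "photosystem"),
    ("pet", "photosystem"),
    ("ndh", "photosystem"),
    ("rbc", "photosystem"),
    ("ycf", "conserved ORF"),
)


def functional_class(gene_name: str) -> str:
    """Crude plastid functional category from the gene name (five classes:
    genetic system, ribosomal protein, photosystem, other protein,
    conserved ORF)."""
    low = gene_name.lower()
    for prefix, cls in _CLASS_PREFIXES:
        if low.startswith(prefix):
            return cls
    return "other protein"


@dataclass
class CoaResult:
    row_coords: pd.DataFrame      # genes × axes (principal coordinates)
    col_coords: pd.DataFrame      # codons × axes
    inertia: np.ndarray           # eigenvalues (sigma^2) per axis
    total_inertia: float
    gene_classes: dict[str, str] = field(default_factory=dict)

    @property
    def axis_contributions(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.inertia)
        return self.inertia / self.total_inertia


def rscu_matrix(
    rscu_tables: list[RscuTable], code: int = 11
) -> pd.DataFrame:
    """Genes × 59 sense-codon RSCU matrix (Met/Trp/stops dropped), unobserved
    codons filled with 0 so the table is complete."""
    gcode = GeneticCode.get(code)
    columns = list(gcode.synonymous_codons)
    data = {
        t.scope: [t.rscu.get(c, 0.0) for c in columns] for t in rscu_tables
    }
    frame = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    frame.columns = [to_rna(c) for c in columns]
    return frame


def coa(matrix: pd.DataFrame, n_axes: int | None = None) -> CoaResult:
    """Correspondence analysis of a non-negative genes × codons table.

    SVD of the standardized residuals of the doubly-normalized table:
    S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2} with P the table scaled to sum 1.
    Principal row/column coordinates share the singular values (duality);
    axis contribution = λ_a / Σλ.  Axis signs are fixed by making the codon
    with the largest |loading| positive on each axis.
    """
    if (matrix.values < 0).any():
        raise ValueError("COA table must be non-negative")
    work = matrix.loc[:, matrix.sum(axis=0) > 0]
    work = work.loc[work.sum(axis=1) > 0, :]
    n = work.to_numpy(dtype=float)
    grand = n.sum()
    if grand == 0:
        raise ValueError("COA table is all zero")
    p = n / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    # drop numerically-null axes (the trivial dimension and rank deficits)
    keep = sig > max(sig[0], 1.0) * 1e-12 if sig.size else np.array([], bool)
    u, sig, vt = u[:, keep], sig[keep], vt[keep, :]
    max_axes = max(min(work.shape) - 1, 0)
    u, sig, vt = u[:, :max_axes], sig[:max_axes], vt[:max_axes, :]
    if n_axes is not None:
        u, sig, vt = u[:, :n_axes], sig[:n_axes], vt[:n_axes, :]
    # sign convention: largest-|loading| codon positive on each axis
    col_load = vt.T * sig  # standard coordinates scaled by sigma
    for a in range(sig.size):
        j = int(np.argmax(np.abs(col_load[:, a])))
        if col_load[j, a] < 0:
            u[:, a] *= -1
            vt[a, :] *= -1
    with np.errstate(divide="ignore", invalid="ignore"):
        row_coords = (u * sig) / np.sqrt(r)[:, None]
        col_coords = (vt.T * sig) / np.sqrt(c)[:, None]
    axes = [f"axis{i + 1}" for i in range(sig.size)]
    inertia = sig**2
    total = float((s**2).sum())
    classes = {g: functional_class(str(g)) for g in work.index}
    return CoaResult(
        row_coords=pd.DataFrame(row_coords, index=work.index, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=work.columns, columns=axes),
        inertia=inertia,
        total_inertia=total,
        gene_classes=classes,
    )


# ---------------------------------------------------------------------------
# Index correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        vars_ = list(self.r.columns)
        for i, a in enumerate(vars_):
            for b in vars_[i + 1 :]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "pearson_r": self.r.loc[a, b],
                        "p_value": self.p.loc[a, b],
                        "stars": self.stars.loc[a, b],
                    }
                )
        return pd.DataFrame(rows, columns=["var_a", "var_b", "pearson_r", "p_value", "stars"])


def _star(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate_indices(
    per_gene: pd.DataFrame, coa_result: CoaResult | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson r with two-sided t-test p-values over the per-gene
    index table (axis1/axis2 merged in from the COA when given).  Constant
    variables yield NaN r for their pairs.  No multiple-testing correction
    is applied."""
    table = per_gene.set_index("gene") if "gene" in per_gene.columns else per_gene.copy()
    if coa_result is not None:
        for axis in ("axis1", "axis2"):
            if axis in coa_result.row_coords.columns:
                table[axis] = coa_result.row_coords[axis]
    order = [c for c in ("axis1", "axis2", "enc", "cai", "gc3", "gc3s", "L_aa", "gc_all") if c in table.columns]
    table = table[order].astype(float).dropna()
    if len(table) < 3:
        raise ValueError("index correlation needs at least 3 complete genes")
    k = len(order)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            xi, xj = table.iloc[:, i], table.iloc[:, j]
            if np.isclose(xi.var(ddof=0), 0) or np.isclose(xj.var(ddof=0), 0):
                continue
            rr, pp = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    r_df = pd.DataFrame(r, index=order, columns=order)
    p_df = pd.DataFrame(p, index=order, columns=order)
    stars = p_df.map(_star)
    return CorrelationMatrix(r=r_df, p=p_df, stars=stars)
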