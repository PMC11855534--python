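# Methods

## Scope and model

`plastcub` implements the comparative analysis workflow for annotated
chloroplast genomes: coding-sequence selection, codon-usage statistics
(RSCU, positional GC, ENc, CAI), the four classical mutation-vs-selection
diagnostics (ENc-plot, PR2-bias plot, neutrality plot, correspondence
analysis), optimal-codon determination from ENc-extreme gene libraries,
SSR and dispersed-repeat mining, and quadripartite (LSC/IRb/SSC/IRa)
structure detection. A synthetic-plastome generator with recorded ground
truth closes the loop: every stage is validated against quantities that
were planted, not merely plausible.

## CDS selection

Four rules, applied in order with the first violation recorded per
rejection: (1) length a multiple of 3; (2) length ≥ 300 bp (default
`min_cds_len`); (3) only A/C/G/T; (4) no internal stop codon. Stop codons
come from the bacterial/plastid genetic code (NCBI table 11, the plastome
standard; configurable). A terminal stop is allowed and excluded from the
amino-acid length `L_aa`; a CDS without one is retained, since only
internal stops disqualify. IR-duplicated genes (rpl2, ycf2, ndhB, …
annotated twice) are deduplicated by base gene name before filtering,
keeping the first copy, so per-genome gene counts reflect unique genes; a
switch (`deduplicate=False`) keeps both copies. Trans-spliced rps12
location blocks are treated as written — no transcript reassembly.

## Codon metrics

* **RSCU** = x_ij / ((1/n_i) Σ_j x_ij): observed count of codon j for
  amino acid i over its expectation under uniform use within the
  synonymous family of size n_i. Stop codons are excluded; a family with
  zero observations is reported as missing rather than zero; single-codon
  families (Met, Trp) sit at exactly 1 when observed.
* **Positional GC**: GC1/GC2/GC3 over codon positions 1/2/3 with the
  terminal stop dropped; GC12 = (GC1+GC2)/2 is always derived, never
  stored. **GC3s** is the GC fraction at *synonymous* third positions
  (Met, Trp and stops excluded) — the standard definition, and the S that
  enters the expected-ENc curve. (A looser reading — GC3 over all third
  positions — is available as the plain `gc3` field; GC3s is what the
  ENc-plot uses, since only synonymous sites carry usage information.)
* **ENc** (Wright): per family F̂ = (n Σ p̂² − 1)/(n − 1) for n ≥ 2;
  ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ over the degeneracy classes of
  code 11 (nine 2-fold families, Ile the single 3-fold, five 4-fold,
  Leu/Ser/Arg 6-fold; the leading 2 is Met+Trp). Missing-family handling
  follows CodonW: families with n < 2 are dropped from their class; a
  missing 3-fold class mean is substituted by (F̄₂+F̄₄)/2; any other
  missing class leaves the gene's ENc undefined (flagged, never guessed).
  The estimate is capped to [20, 61] with the cap recorded — the
  estimator exceeds 61 on small or very even samples.
* **Expected ENc**: ENc\*(S) = 2 + S + 29/(S² + (1−S)²). This closed form
  is an approximation to the exact null expectation (at S = 0.5 it gives
  60.5 where the exact uniform limit is 61), so "mean deviation ≈ 0 for
  unbiased genes" holds only to within ~1; the tests allow for that.
* **CAI** (Sharp–Li convention): geometric mean of w = RSCU/RSCU_max over
  the gene's codons, Met/Trp/stops excluded. The reference set defaults to
  the pooled RSCU of the low-ENc (high-bias) 10% library of the same
  genome, since no external reference organism is assumed; codons absent
  from the reference receive a smoothing weight of 0.01, and families
  wholly unobserved there are skipped as uninformative.

## Bias analyses

* **ENc-plot**: deviation = ENc\*(GC3s) − ENc per gene; positive means
  the gene lies below the curve (more restricted usage than composition
  predicts). Genes lacking GC3s or a defined ENc are excluded, not
  imputed.
* **PR2**: x = G3/(G3+C3), y = A3/(A3+T3). The default scope is the third
  positions of the five fourfold-degenerate families only (Val, Pro, Thr,
  Ala, Gly), where the third base is free of amino-acid constraint;
  `scope="all"` uses every synonymous third position. Zero denominators
  flag the point undefined.
* **Neutrality plot**: ordinary least squares of GC12 on GC3 across genes
  plus the Pearson correlation with its exact two-sided t-test p-value;
  slope × 100 is reported as the percent of usage variation attributable
  to mutational pressure. Zero GC3 variance raises rather than returning
  a degenerate fit.
* **COA**: standard correspondence analysis — SVD of the standardized
  residuals D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} of the genes × 59 sense-codon
  RSCU table (Met/Trp/stops dropped; unobserved codons set to 0 so the
  table is complete). Axis contribution = λ_a/Σλ over total inertia. SVD
  sign ambiguity is fixed by making the codon with the largest |loading|
  positive on each axis; correlations with axis scores are reported under
  that convention. Genes are classed into five plastid functional groups
  from name prefixes (rpo/inf → genetic system, rps/rpl → ribosomal,
  psa/psb/pet/ndh/rbcL → photosystem, ycf → conserved ORF, rest → other).
* **Correlations**: pairwise Pearson r with two-sided t-test p, stars at
  0.05/0.01, no multiple-testing correction (matching field practice for
  these index tables). Constant variables yield NaN, flagged not dropped
  silently.

## Optimal codons

Genes sort ascending by ENc (gene-name tie-break for determinism); the
low-ENc 10% is the high-bias library, the high-ENc 10% the low-bias
library, size ceil(0.10·N) with a floor of 2. Library RSCU tables are
computed from summed codon counts (CodonW behaviour), not averaged
per-gene RSCU. ΔRSCU = RSCU_high − RSCU_low; codons missing from either
library are flagged rather than defaulted. High-frequency codons have
genome-wide pooled RSCU > 1 (the `high_frequency_on="high"` switch
evaluates the threshold on the high-bias library instead); optimal codons
additionally require ΔRSCU ≥ 0.08. Cross-species comparison intersects
optimal sets on codon identity.

## Repeats

SSRs are maximal perfect tandem repeats of a primitive 1–6 nt unit,
reported leftmost, complete units only, above per-unit-length minima
(defaults 10/6/5/5/5/5 — the MISA-web defaults, config-exposed since the
counts depend on them). An SSR wholly contained in a longer SSR of
another unit length is suppressed. Motif families are canonicalized as
the lexicographic minimum over cyclic rotations of the motif and of its
reverse complement. Circular scans append a short overlap window so
origin-spanning runs are caught (their `end` exceeds the sequence
length). Compound-SSR grouping (≤ 100 bp gaps) is a reporting view only.

Dispersed repeats are maximal forward and palindromic pairs under
Hamming distance ≤ 3 at length ≥ 30 bp ("minimum match score" style
settings are reported as matches − mismatches for reference). Detection
is exact-k-mer seeding (k = 7; any qualifying window contains an exact
run ≥ ⌈(30−3)/4⌉ = 7, so sensitivity is guaranteed at the defaults)
followed by per-diagonal enumeration of maximal mismatch-budgeted
windows, with window ends trimmed onto matches and contained windows
dropped. Work grows with matched area, not sequence length squared; in
extremely low-complexity regions k-mer buckets are capped (such regions
are SSR territory and their sub-30 bp matches are not of interest). The
plastome IR pair appears as one giant palindromic hit; callers filter by
length before summarising dispersed repeats. Both detectors are checked
against exhaustive brute-force oracles in the test suite.

## Quadripartite structure

The IR pair is the longest pair of disjoint, reverse-complementary
segments on the circle, found by binary search over match length with
rolling hashes on the doubled sequence (candidate matches verified by
direct comparison, so hash collisions cannot create false structure). Of
the two single-copy gaps the longer is the LSC; IRb is the repeat copy
immediately downstream of the LSC, so the circle reads LSC, IRb, SSC,
IRa. Junctions JLB/JSB/JSA/JLA are the first base of the downstream
region. An optional extension step tolerates a small mismatch rate
(default 0.1%) for annotation-grade sequence noise; it is off for exact
synthetic data. Genomes without a repeat ≥ `min_ir_len` (default 1 kb)
return a flagged structure with empty IRs. Coordinates are 1-based
inclusive on the public surface and 0-based half-open internally.

## The synthetic generator

The generator emulates the statistical structure of a rubber-tree-like
plastome: a 161,140 bp circle (89,150 + 26,810 + 18,370 + 26,810), IRa
the exact reverse complement of IRb, overall GC steered to 0.357 by
solving for the intergenic-filler composition, 90 genes of 100–420
codons named from a plastid gene-name pool (so functional classing is
exercised), per-gene GC3 targets uniform on [0.18, 0.37], third-position
asymmetry favouring C over G and T over A (0.55 shares), a 20% high-bias
expression class, and 57 implanted SSRs in the proportions real
plastomes show (~70% mononucleotide, A/T-dominated).

Design choices that matter:

* **Low-discrepancy allocation.** Amino-acid and codon counts are
  allocated by deterministic largest-remainder rounding of the weight
  vectors rather than multinomial draws, and each degenerate family's
  count is rounded to a multiple of its size (Met absorbs the residual).
  Realized usage therefore matches the specified weights to within one
  codon, which makes ground-truth recovery checks sharp: a uniform spec
  yields pooled RSCU of exactly 1, and implanted preferred codons are
  the only source of ΔRSCU signal. The cost is that per-gene sampling
  noise is smaller than in real data; tests that need stochasticity
  (e.g. ENc estimator behaviour) draw multinomially themselves.
* **Bias modes.** `concentrate` (default) moves weight onto one codon per
  third-position base group, preserving GC3 while lowering ENc — the
  signature of selection, and what places most genes below the ENc\*
  curve. `replace` moves family mass straight onto the preferred codon,
  dragging GC3 — used by the `strong-bias` preset where the implanted
  set itself is the object of recovery. Per-gene bias levels are
  jittered (±0.25 around class means 0.85/0.45) to produce a realistic
  ENc spread; these defaults were calibrated once so the default
  conditions show the reference statistics (mean ENc ≈ 46.5, ENc range
  ≈ 30–61, majority of genes below the curve) and are not adjusted per
  test.
* **Neutrality relation.** Per-gene GC12 is steered to
  0.40 + 0.22·E[GC3] + N(0, 0.02) by exponentially tilting the
  amino-acid frequencies (bisection on the tilt parameter), and realized
  GC3 is pinned to its expectation by same-prefix third-base swaps
  (ATT↔ATC style), which leave GC12 and the protein unchanged. Even so,
  a single 90-gene replicate estimates the slope with sampling error
  ≈ ±0.04–0.05 (the noise σ = 0.02 is large relative to the GC3 spread),
  so recovery tests average the fitted slope over ten seeded replicates.
* **SSR cleanliness.** Filler is generated with homopolymer runs capped
  at 7 and regenerated until SSR-free; implant flanks are forced
  incompatible with run extension; gene/filler boundaries are broken the
  same way; gene interiors are reshuffled if a scan finds an accidental
  SSR. The implants are therefore exactly the SSR complement of the
  genome at default thresholds, verified across seeds.

What the generator does **not** emulate: real intergenic sequence
(promoters, tRNA clusters), introns and trans-splicing, annotation
errors, ambiguity codes, indel/rearrangement variation, or a phylogeny
relating multiple genomes. Passing the closed-loop tests shows the
analysis code recovers planted structure; it does not show the
biological conclusions transfer to any particular real genome — the
accession regression test exists for that, and requires the published
GenBank records locally.

## Problem sizes and determinism

The test suite runs entirely from generated data: full-scale (161 kb)
genomes where composition shares matter, 20–36 kb genomes for structure
and orchestration tests, and ≤ 20 kb sequences for brute-force oracle
equivalence. All randomness flows through seeded numpy generators;
pipeline outputs embed a version, config hash and input checksum, and
reruns are byte-identical. The regression against the six published
records asserts the reported values (genome sizes and GC to Table-1
precision, IR ≥ 26,810 bp, pooled RSCU(UUA) ≥ 2.0291, mean ENc ≥ 46.47,
43–45 genes above ENc 45, neutrality slope in [0.20, 0.25] with
r ≥ 0.1825, COA axis-1 share ≥ 10.11%, 31/22 optimal-codon union and
intersection, 126–137 SSRs at the default MISA thresholds) and fails
with a clear diagnostic when the records are not present.

## Known limitations

* ENc on exact-proportion (low-discrepancy) counts runs higher than the
  weight-implied value because Wright's F̂ is an unbiased estimator for
  multinomial sampling; generator calibration accounts for this, but
  per-gene ENc should not be read as a deterministic function of the
  planted weights.
* The dispersed-repeat detector's bucket cap can miss sub-repeats inside
  extreme low-complexity tracts; such tracts are handled by the SSR
  detector.
* Junction reporting uses each feature's overall span (min start, max
  end), which is conservative for multi-segment features that straddle a
  junction with an intron.
* CAI depends on the reference library; with the default self-referential
  library it measures within-genome adaptation, not adaptation to an
  external expression host.
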