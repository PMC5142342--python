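# Methods

## The measure catalogue

The catalogue holds 79 similarity (S) and dissimilarity (D) equations over
the OTU quantities (a, b, c, d) of a binary vector pair; 17 are
dissimilarities, and 46 depend on the negative-match count d — either
explicitly or through the constant n = a + b + c + d. Evaluation is plain
float64 arithmetic; an exact-rational mode is deliberately out of scope.
Undefined sub-expressions never raise: a division by zero yields status
`nonfinite`, and 0/0, log of a nonpositive argument, or the square root of
a negative yields `indeterminate`. This is a design point, not an error
path — the validity screen eliminates equations on exactly this behaviour,
so the status must be a value, not an exception.

Two entries need interpretation:

* **Sokal & Sneath-5** is implemented in its literature form
  `ad / √((a+b)(a+c)(b+d)(c+d))` — the 0.5 exponent applies to the whole
  margin product, which is what makes it exactly identical to Ochiai-2 and
  lets the corresponding identity group verify numerically. A variant that
  exponentiates only the last factor would break that identity.
* **Tarantula and Ample** differ only by an absolute value; both are kept
  as catalogued. Together with Peirce they are the only entries that are
  *not* symmetric under swapping the two vectors. All three are removed by
  the validity screen before any downstream use, so the b/c orientation
  convention (b counts x=1,y=0) is immaterial everywhere it matters; the
  symmetry property is tested for every other equation.

Intermediate statistics reused across entries (χ², the phi-style
correlation ρ, and the row/column maxima sums σ, σ′ of the Goodman &
Kruskal family) are exposed as accessors on `OTUQuantities` so they can be
tested in isolation.

## Reduction

**Identity stage.** The seven identity groups are hard-coded (no symbolic
algebra system is used — a stated non-goal) and verified numerically on
1,000 random strictly-positive OTU quadruples at 1e-12 relative tolerance
before their 12 eliminations are applied. Kulczynski-2 and
Driver & Kroeber are also algebraically identical to each other, but the
catalogue resolves both at the affine/clustering stage, so the identity
stage is defined by the seven groups rather than by a blind all-pairs
equality scan.

**Validity stage.** The screen evaluates each equation on a fixture corpus
of degenerate pairs: generic, identical-nonzero (b=c=0), disjoint (a=0),
nested (b=0, c>0), complement-free (d=0), and a saturated identical pair
(a=n). The saturated fixture exists because the Goodman & Kruskal
denominator 2n − σ′ vanishes only when the 2×2 table has both a full row
and a full column; such a pair also trips several otherwise-retained
equations, which is why the *pipeline* applies the catalogue's annotated
invalid list (11 equations) rather than the corpus verdicts. One annotated
entry — Anderberg, whose denominator 2n is strictly positive — cannot be
reproduced as invalid by any corpus at all; it is honoured from the
annotation.

**Zero-distance stage.** Coefficient columns for the 56 survivors are
computed on an actual dataset, standardized (mean 0, sample sd 1, ddof=1),
and collapsed whenever two columns sit at Euclidean distance ≤
1e-8 × √(#pairs): affine collapse is exact up to accumulated rounding, so
the tolerance only has to absorb float error that grows with the column
length. Components of the thresholded graph are retained by a single
representative — the lowest id among the designated affine-family
representatives when present, else the lowest id. Standardization maps v
and αv + β (α > 0) to identical z-scores, so the 11 affine families
collapse on *every* dataset with nonconstant columns, not just the corpus
the catalogue was derived on; negative-α relations (e.g. Sokal & Michener
vs Hamming) map to opposite-sign z-scores and correctly do not collapse.
The elimination is idempotent: rerunning it on the retained columns removes
nothing (tested).

When the validity stage is skipped, columns that are non-finite on the
given dataset cannot be placed in the coefficient space; they pass through
unclustered rather than being silently dropped, since only the (skipped)
validity stage has the authority to eliminate them.

## Clustering

Centroid linkage is implemented directly in the standardized coefficient
space: a cluster's profile is the arithmetic mean of its member columns,
and each step merges the pair of clusters with minimum Euclidean distance
between centroids. Ties are broken by the lexicographically smallest pair
of smallest member equation ids, making the merge sequence deterministic.
Centroid linkage is not monotone; height inversions are detected and
reported, never repaired. The implementation is cross-checked against an
independent reference implementation of centroid linkage
(`scipy.cluster.hierarchy.linkage(method="centroid")`) to 1e-9 on random
inputs. Dendrograms export to Newick with branch lengths equal to
parent-minus-child merge heights (negative under inversion, kept as-is);
dissimilarity columns are clustered as-is, without conversion to
similarities, so S- and D-measures separate naturally.

## ROC ranking

* **Match rule.** A pair matches when the two formulas' efficacy-class sets
  *share at least one class*; exact-set equality is available as a switch
  (`rule="exact"`). The shared-class reading is the sensible extension of
  "same efficacy" to multi-label formulas. The per-class variant labels a
  pair match when both formulas carry the class, mismatch when exactly one
  does, and excludes pairs involving the class not at all.
* **Normalization.** Min-max normalization is computed per equation over
  the *full* pair population, before any bootstrap subsetting, so
  thresholds mean the same thing in every replicate; dissimilarities are
  then converted by S = 1 − D².
* **Threshold grid.** The 100 thresholds are the lower limits of 100
  equal-width intervals of [0, 1] (0.00, 0.01, …, 0.99); the decision rule
  is similarity ≥ threshold. (0,0) and (1,1) closure points complete the
  curve. AUC is the trapezoid area over this grid, mirroring the
  curve-based protocol; the Mann–Whitney rank AUC serves as the testing
  oracle (agreement within 0.01 on continuous scores) but is not the
  reported statistic.
* **Bootstrap balance.** 20 mismatch samples of exactly the match-class
  size are drawn with replacement; AUC and κ are averaged over replicates.
  κ is computed at each replicate's own minimum-distance threshold — the
  procedure's native operating-point criterion; a fixed-threshold variant
  is a one-line switch. The minimum distance itself and the recognition
  rate are computed once on the full (unbalanced) populations.
* **Seeds.** A single integer seed fans out to all stochastic stages via
  `numpy.random.SeedSequence.spawn`; identical seeds give byte-identical
  ranking tables.

## Synthetic data

The generators define the study conditions rather than emulating any real
corpus in detail:

* `random_matrix(density)` — i.i.d. Bernoulli cells; the 1%, 5% and 10%
  density controls. Their ROC curves hug the diagonal (mean AUC within
  0.48–0.52 at 200 formulas and 20 replicates), as a no-signal control
  should.
* `row_count_matrix` — exact per-row ones counts at uniform positions.
  Row-count profiles are truncated discrete normals: Jamu-like
  (mean 4.904, sd 2.969, range 1–26) and Kampo-like (mean 8.923, sd 3.885,
  range 3–19). Only mean/sd/range of the emulated corpora are pinned down;
  the truncated-normal family is a modelling choice, and truncation at the
  lower bound lifts the realized mean slightly above the parent mean
  (≈ 5.36 for the Jamu profile).
* `structured_dataset` — the labeled stand-in. Each of `n_classes = 4`
  classes owns a disjoint 20-ingredient pool out of 101 ingredients; each
  formula picks its ingredients (Kampo-like counts) from its class pool
  with probability `p_in = 0.5` and uniformly from the full ingredient set
  otherwise. Falling back to the full set rather than the pool complement
  matters: complement-only draws concentrate cross-class picks in the
  shared remainder and wash out the overlap difference between match and
  mismatch pairs. With these defaults the within-class expected overlap
  exceeds the between-class one, and the best equation reaches a mean AUC
  of ≈ 0.75 (Jamu-like row counts give ≈ 0.61); the pool size and row
  profile were fixed once by a pilot simulation at a fixed seed and not
  revisited. An odd ingredient count (101) is deliberate: with an even
  vector length M, the integer |ad − bc| can hit M/2 exactly, where the
  Stiles coefficient takes log₁₀(0) = −∞ on an otherwise unremarkable pair;
  odd M excludes that case for every seed.
* A configurable fraction of formulas receives a second class label (label
  only — ingredients still follow the first class) to exercise the
  multi-label match rule.

What passing tests on these generators do *not* show: real formularies have
correlated ingredient co-occurrence, heavy-tailed ingredient popularity and
overlapping, hierarchical efficacy classes, none of which the generators
model. The structural results (the 79 → 67 → 56 → 45 reduction, affine
collapse, symmetry) are data-independent and carry over; the *ranking* of
the 45 measures is data-dependent by construction — different corpora
legitimately promote different equations, which is the point of running the
procedure per dataset rather than recommending a universal coefficient.

## Problem sizes

The default desk-scale corpus is 200 formulas × 101 ingredients
(19,900 pairs); the full test suite and the acceptance script each run in
well under a minute on one CPU. All operations are vectorized over pairs,
so the pipeline scales to corpora of a few thousand formulas (≈ 5 × 10⁶
pairs) in memory.

## Known limitations

* The validity screen's fixture corpus is intentionally harsher than
  real sparse data; its verdicts are a diagnostic, and the pipeline's
  counts come from the catalogue annotation.
* Grid AUC carries a discretization error of order the grid resolution;
  heavy score ties (tiny sparse vectors) can make grid and rank AUC differ
  by more than the continuous-score bound.
* No statistical test compares AUCs between equations; the ranking is
  descriptive. Precision–Recall analysis is out of scope.
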