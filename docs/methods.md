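# Methods

This note documents the models, conventions, numerical choices and open
design decisions behind `pathwave`, in the order of the pipeline.

## Pathway networks

Metabolic mode builds one node per reaction and joins reactions *i*, *j*
whenever products(*i*) ∩ substrates(*j*) ≠ ∅ or vice versa; signaling
mode builds one node per protein entity and one edge per relation.
Edges are undirected and unweighted regardless of reaction reversibility
flags: the analysis consumes only the binary symmetric adjacency matrix,
and directionality would not change which reactions are neighbors.
Reactions without annotated genes are kept as nodes — they shape the
topology — and are flagged "unmeasured" downstream.

**Currency metabolites.** A metabolite is dropped from all
substrate/product lists when it takes part in more than
`degree_threshold` reactions (default 8) of the *whole* input model —
degrees are global, not per pathway, since ubiquity is a property of the
organism's metabolism. A whitelist can retain specific informative hubs
and a blacklist can remove low-degree but uninformative compounds; both
ship empty because any defensible default is organism- and
database-specific. The filter is idempotent.

Disconnected pathways are embedded on a single grid: components interact
through no edges, so the optimal total length is the sum of
per-component optima and nothing is lost by co-embedding.

## Grid embedding

The grid for *n* nodes is the smallest near-square: cols = ⌈√n⌉,
rows = ⌈n/cols⌉ (so |rows − cols| ≤ 1). Strictly square grids are not
forced; rectangular near-squares (e.g. 3×4 for 10 nodes) avoid wasting
cells.

**Exact solver.** Optimality means: minimum of Σ_{uv∈E} (|r_u − r_v| +
|c_u − c_v|) over injective placements. We solve a mixed-integer program
over binary node×cell assignment variables with per-edge continuous
row/column distance variables bounded from below by ± the coordinate
differences (their minimized sum is exactly the Manhattan distance).
Three ingredients make the HiGHS solve practical, none affecting the
optimum:

- per-edge cut d_row + d_col ≥ 1 (endpoints occupy distinct cells);
- per-node cuts Σ_{e∋v} d_e ≥ f(deg v), where f(d) is the sum of the d
  smallest distances available around any cell on an infinite grid
  (4 cells at distance 1, 8 at distance 2, ...) — a valid bound a
  fortiori on a finite grid;
- a symmetry break confining one highest-degree anchor node to the
  fundamental domain of the grid's symmetry group (quarter, or eighth
  for squares).

Distance variables are declared integral (true at any optimum).
Correctness is certified against a brute-force enumerator over all
injective placements (grids ≤ 9 cells), an independent code path.
The default exact-size limit is 16 nodes; runtime grows steeply with
instance size, and callers above the limit either raise the limit
knowingly or fall back to the heuristic.

**Heuristic.** Simulated annealing over placements: breadth-first
initial placement along a snake-ordered cell sequence, swap/relocate
moves between random cell pairs, geometric cooling from T=2.0 to 0.01,
iteration count scaled with grid area, fully determined by the seed. On
random instances of 8–10 nodes its gap to the certified optimum measured
0–1 length units.

**Canonical form.** Among the 4 (rectangular) or 8 (square) grid
symmetries of a placement — all length-preserving — the one with the
lexicographically smallest placement vector is stored, so serialized
grids are reproducible byte-for-byte.

Unused cells are allowed and carry 0 after z-scoring, consistent with
the wavelet zero-padding semantics.

## Expression mapping

Order of operations: pseudocount/log2 (RNA-seq only) → gene-to-reaction
mean → z-transform → grid layout.

- RNA-seq RPKM: the smallest non-zero value of the whole matrix is added
  everywhere before log2, so zeros get a finite floor scaled to the
  dataset's detection limit.
- Microarray probesets mapping to several genes are discarded; several
  probesets of one gene are averaged.
- Reaction expression is the arithmetic mean over the reaction's
  measured genes.
- z-scores use the sample standard deviation (ddof = 1, across samples);
  the convention is stated here because either choice rescales all
  features of a pathway equally and leaves permutation p-values
  unchanged. z-transformation is performed over exactly the analyzed
  sample set. Constant profiles map to all-zero rather than NaN
  (constancy is detected by zero range, not zero computed sd, which
  rounding can miss); unmeasured reactions contribute 0, the z-score
  mean, and are therefore neutral for low-pass features.

## Haar features

Each grid is zero-padded (bottom/right) to even dimensions and cut into
disjoint 2×2 sections [[a, b], [c, d]]. With row means mu = (a+b)/2,
ml = (c+d)/2 and row differences du = a−b, dl = c−d, the four features
are (mu+ml)/2, mu−ml, (du+dl)/2, du−dl. Means divide by 2 and
differences are unscaled — the plain mean/difference convention rather
than orthonormal Haar scaling; the two differ by a constant per (level,
kind), which cannot change any permutation-based statistic. The section
means form the next-level grid; odd intermediate grids are padded by the
same rule; recursion stops at 1×1. The number of levels equals
⌈log2 max(rows, cols)⌉.

Frameshifts prepend (top/left) a zero row, column, or both, so that the
rigid tiling is re-applied at shifted boundaries; across the four
variants every 2×2 neighborhood of the original grid falls inside some
section. The *full multi-level* transform is applied to every variant
(a 2×2 grid yields 4 + 12 + 12 + 20 = 48 features over the four
variants). Features over all-padding sections are retained: they are
constant across samples, hence never discriminative, and keeping them
makes the feature indexing a pure function of the grid shape.

The map grid → features is linear and (per 2×2 block) invertible, both
verified by property tests.

## Statistics

- **Feature statistic:** |Welch two-sample t| per feature; the pathway
  score is the maximum over features, ties broken by canonical feature
  order (shift, level, section row-major, kind). The statistic sits
  behind a narrow interface so a rank-based alternative can be plugged
  in. When both groups have zero variance, the statistic is 0 if the
  means agree and is capped at 10⁶ otherwise (a finite stand-in for an
  infinite t that keeps the Gumbel fit well-posed).
- **Permutation null:** labels are shuffled without replacement
  preserving class sizes; duplicate permutations are allowed (uniform
  sampling of arrangements). Paired designs swap labels within pairs.
  A Gumbel distribution — the natural family for a maximum-type
  statistic — is fitted to the permuted scores by maximum likelihood,
  with a method-of-moments fallback (β = s·√6/π, μ = m − γβ) if the MLE
  fails. The pathway p-value is the fitted survival function at the
  observed score, clamped to [tiny, 1]. Fitting a parametric tail rather
  than counting exceedances gives resolution below 1/n_perm; calibration
  is checked empirically (KS distance of null p-values from uniform
  ≈ 0.04–0.06 at n_perm = 1000 in the acceptance run).
- **Multiple testing:** Bonferroni by default (Holm, Benjamini-Hochberg
  available), delegated to statsmodels.
- **Up/down counts:** per measured reaction a two-sided Wilcoxon
  rank-sum test (signed-rank within pairs for matched designs),
  Bonferroni-corrected *within* the pathway. Per-pathway (rather than
  collection-wide) correction keeps a pathway's counts independent of
  how many other pathways happen to be analyzed alongside it. "Up" means mean(class A) > mean(class B),
  where class A is the lexicographically first label.
- **Filtering/ranking:** pathways pass with adjusted p below the
  threshold and at least `min_dysregulated` reactions up *or* down;
  sorting is by adjusted p, then score (descending), then pathway id.
  Pathways with fewer than two measured reactions are skipped with a
  warning.
- **Seeds:** one master seed; each pathway derives an iteration-order-
  independent child generator from (master seed, crc32(pathway id)), so
  adding or reordering pathways never changes another pathway's null.

## Synthetic benchmark generator

Pathways are random spanning trees over 8–14 nodes plus independent
extra edges (p = 0.15), each node annotated with 1–3 genes — the size
and annotation range of typical curated metabolic maps after currency
filtering. Expression is Gaussian with unit sd at the gene level; a
planted switch shifts the *node-level* mean of a connected k-node subset
(BFS-grown, default k = 4) by delta (default 3 sd) in class A only, with
all genes of a node sharing the node mean so gene→reaction averaging
reduces variance the way replicate measurements of one enzyme would.
Default design: 20 pathways, 10 samples per class. delta = 0 yields
exchangeable classes for calibration studies.

What the generator does *not* emulate: count-based noise (negative
binomial overdispersion of RNA-seq), gene-gene correlation beyond the
node structure, correlation between pathways, batch effects, or
database-dependent annotation error. Passing tests therefore demonstrate
correctness of the machinery and calibration/power under an idealized
noise model — not performance on any particular real dataset.

Benchmark grids use the annealing embedder: certified optimality is a
property of the embedding solver (validated separately against the
enumeration oracle) and does not affect the statistical behavior under
study.

## Problem sizes in the validation suite

Calibration uses 200 null pathways (10+10 samples, 1000 permutations);
the KS statistic of 200 uniform p-values has null median ≈ 0.06, so the
0.1 bound is a meaningful test at this n. Power uses 20 replicates of a
21-pathway screen with one planted k = 4, delta = 3 switch; ranking
stability compares two independent 1000-permutation runs on a 50-pathway
benchmark with 5 weak (delta = 1.5) planted switches. Embedding
optimality is certified on 100 random connected graphs of ≤ 8 nodes.

## Known limitations

- The exact embedder is exponential in practice beyond ~16 nodes; large
  KEGG maps rely on the annealer, which carries no optimality
  certificate.
- The Gumbel fit uses all permuted scores, not only tail exceedances;
  for very heavy-tailed feature statistics (many capped values) the fit
  degrades — the degenerate-null error path catches the extreme case.
- KGML support covers entry/reaction/substrate/product/relation
  elements; map-links between pathways and group entries are ignored.
- The KEGG coloring URL format targets the documented multi-query GET
  form and may need updating as the KEGG web interface evolves.
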