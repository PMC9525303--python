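# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot demonstrate. Symbols follow the README.

## Simple indel coding

Every maximal gap run with identical endpoints observed in at least one
sequence becomes one binary character over half-open 0-based column
ranges. A sequence scores 1 when one of its own gap runs equals the
range, inapplicable (`?`) when one of its runs strictly contains it
(the deletion state cannot be observed under a larger deletion), and 0
otherwise — including partial overlaps, which under the simple variant
are separate characters. Terminal gap runs are excluded by default
because in spacer alignments they usually record missing sequence, not
deletion events; `exclude_terminal=False` restores them. Each coded
character counts one mutational step regardless of gap length.

## Statistical-parsimony connection limit

The estimator treats sites as i.i.d. Poisson mutation targets. For two
haplotypes differing at j of L sites, the per-site hit rate λ̂ is the
Jukes–Cantor–corrected divergence at p = j/L, and the probability that
the observed differences are the complete mutational path (no site hit
twice) is [(1+λ̂)e^(−λ̂)]^L. The connection limit at confidence α is the
largest j for which this probability is ≥ α, floored at 1 (single-step
connections are always made). This parameterization is the package's
own; it preserves the properties tests rely on — monotone
non-decreasing in L, limit → 1 as α → 1⁻, and agreement with an
independent dual-route evaluation — and gives limits of ~7 steps at
L = 500–600, α = 0.95. For compatibility with published analyses a
fixed limit can be supplied, bypassing the computation.

## Network construction

Agglomerative, level by level in mutational distance d = 1..limit.
Distances count substitution mismatches over columns where both
haplotypes carry bases (ambiguity codes match any compatible base) plus
one step per differing indel character (`?` contributes nothing). At
each level the component structure is snapshotted; every cross-component
pair at exactly distance d is connected through d−1 median vectors, and
*all* such ties are kept, so reticulations visible in real networks
survive. Pairs already in one component are never reconnected. Median
vector contents are materialized along a deterministic
(column-ascending) mutation order; only their count and connectivity
are contract-bearing, since intermediate states are not identifiable.

## Dirichlet–multinomial clustering

The score is exact: with a symmetric Dirichlet(1) prior over the S
states observed at a locus, a cluster containing counts n₁..n_S
contributes log Γ(S) − log Γ(N+S) + Σ log Γ(nₛ+1), additive over loci
and clusters. Gaps are ordinary alleles; `N` and ambiguity codes are
missing and add no counts. The search is a stochastic greedy ascent —
full single-sequence reassignment sweeps (including opening a new
cluster up to k_max), best-pair merges, and 2-way splits found by
2-means on the one-hot allele matrix with farthest-point
initialization — accepting only strict improvements, restarted n_runs
times from random partitions; the second level re-runs the search
independently inside each level-1 cluster.

Two properties of this score are worth knowing. It is exactly the
quantity the exhaustive small-n oracle maximizes, and the search ties
that optimum in ≥95% of seeded runs at n = 8. But at such small n the
marginal *itself* can prefer spurious splits of unstructured data
(grouping near-duplicate genotypes is cheap when each cluster term pays
only a small Occam factor), so "K = 1 under no structure" is a
large-sample property: it holds at the default synthetic sizes (tens of
individuals, ~100 loci) and is tested there, not at n = 8.

## Binary ancestral ranges

Each area is a 2-state symmetric chain, P(change | t) = (1 − e^(−2rt))/2,
with equal stationary frequencies ("Jukes–Cantor-style" fixed
frequencies in the binary analogue) and one rate r shared across areas
(equal variation across characters). r is fitted by bounded ML on the
total log-likelihood. Per-node, per-area marginals come from an
inside–outside pass of the pruning algorithm, which handles polytomies
natively; the range posterior at a node is the product of per-area
marginals renormalized over non-empty sets of ≤ max_areas areas (4 by
default). Modal-range ties break toward the smaller range, then
lexicographically. Zero-length branches propagate mass exactly
(P(change) = 0) with no special casing.

The MCMC mode exists for fidelity to the classic two-run protocol and
for larger area sets. Its chain augments the per-area node states and,
because the exact mode conditions on the shared ML rate, the default
chain does the same so that the two routes target the identical
posterior (the agreement contract is sup-norm < 0.02 at protocol
settings); `sample_rate=True` enables the log-window rate move under a
log-uniform prior, yielding the rate-marginalized posterior instead.
Samples with empty or oversized ranges at a node are excluded by the
admissible-set renormalization. A total-variation gap > 0.25 between
the two runs' per-node posteriors is recorded as a warning.

Event classification compares modal ranges along each branch: areas
gained are dispersals, areas lost local extinctions; a node whose
daughter ranges are pairwise disjoint subsets of its own range is a
vicariance. Scenario strings use the arrow/plus/pipe notation
(`D → D+SC → D | SC`) and parse back to (before, gained, split).

## Relative-rate dating

time(v) is the tip-count-weighted mean of (time(child) + branch) over
v's children — equivalently the mean v→tip path length — normalized by
the root's value. This is the mean-path-length variant of relative-rate
dating, chosen over the full local-rate-averaging procedure because the
latter's published form leaves implementation freedom that cannot be
pinned down bit-for-bit; the variant coincides with it in the clock
limit, which is what the recovery guarantees exercise (< 1e-9 relative
error on clock trees with one exact calibration). Calibration densities
are normal with σ = (CI_high − CI_low)/3.92; the WLS scale is the
closed-form maximizer of their product under age = s·t, and a
zero-variance calibration short-circuits to exact fitting (conflicting
exact calibrations raise). Reported CIs reflect calibration uncertainty
only — not topology or branch-length error, which would require
resampling machinery outside this scope.

## Ensemble niche modeling

Screening removes near-zero-variance layers (sd < 1e-8 over background
cells), then exact linear dependences (greedy rank test in name order,
earlier names win), then iteratively the layer with the most partners at
|r| ≥ 0.7 (ties: larger mean |r|, then name order) until no pair
remains. Correlations are computed over background cells.

Variable selection against random probes runs per algorithm: append one
uniform probe per active variable (capped at 5), each spanning that
variable's observed range and regenerated every round so probes cannot
be memorized; compute cross-validated permutation importance (4 folds,
fit in-fold, permute the held-out fold, 3 repeats; the held-out
evaluation stops flexible learners from awarding importance to
memorized noise); discard the worst true variable while any true
variable scores below the best probe. A variable leaves the final set
only when ≥ 3 of the 5 algorithms discarded it. The procedure is run on
the cell-level occurrence data, before environmental thinning, because
the thinning's PCA maps are themselves defined over the previously
selected variables — and because importance estimation needs the
hundreds of points that exist before thinning.

Environmental thinning deduplicates by raster cell, then keeps one
uniformly random point per 1×1 cell of the space spanned by the first
two principal components of the retained layers (standardized, fitted
on background cells; component signs fixed by the largest loading).
Applied to both presences and background. On the default synthetic
bundle this reduces ~600 presences to ~30–50 — the same order of
compression as real workflows, but to a much smaller absolute count,
because standardized synthetic layers span only a few PC units; the
consequences are noted under Limitations.

The five learner families are sklearn estimators behind one interface:
MLPClassifier (8 hidden units), DecisionTreeClassifier, a
StandardScaler→quadratic-features→LogisticRegression pipeline (a
maximum-entropy-style model with linear+quadratic features),
GradientBoostingClassifier, and RandomForestClassifier (bagged trees).
Each is fit n_reps times (100 by default; desk-scale runs use 10) on
class-stratified bootstrap draws; degenerate single-class draws are
redrawn. The suitability grid is the mean predicted probability; AUC
and MAE are evaluated out-of-bootstrap, each repetition scoring the
rows its draw omitted. "Best by AUC and MAE" is read as highest AUC and
lowest MAE (MAE is a loss; the literal reading is selectable via
`mae_best="max"`).

The consensus map is the first principal component over models
(pixels as observations, columns centered only — the maps share the
[0, 1] scale; whether to standardize was an open choice, and centering
preserves between-model amplitude differences), sign-fixed to correlate
positively with the across-model mean and min–max rescaled to 0–100, so
it attains both ends on every map. Past-period projection re-runs
prediction and consensus per period and reports, per period, each
retained variable's mean and the pixel count with consensus > 30, both
divided by the present value; a zero present value leaves the ratio
defined only where the value is unchanged (0/0 → 1), which keeps the
present row identically 1.

## Synthetic data

The sequence generator evolves a Yule tree (pure birth, rate 1; branch
lengths in expected substitutions per site), Jukes–Cantor substitutions
as per-site Poisson events, and multi-base deletions (Poisson events
per branch, geometric lengths, inherited down the lineage,
rejection-sampled against overlap so simple gap coding stays
unambiguous in default fixtures; an overlap flag generates stress
fixtures). One region token per lineage switches with probability
1 − e^(−dt) per branch. Everything (tree, per-node regions, tip
regions) is recorded.

The loci generator plants K clusters: per locus a common frequency
vector from a sparse Dirichlet(0.5) — the major-allele-dominated
spectrum typical of SNPs; flat frequencies would make every locus
hyper-polymorphic and unrealistically reward spurious partitioning —
mixed with a cluster-specific fixed allele in proportion `divergence`.

The environment generator emulates a 19-layer bioclimatic stack:
Gaussian-smoothed white noise fields (scale 5 cells), standardized, all
sharing a common "climate" latent (pairwise r ≈ 0.42, below the 0.7
screen) plus near-duplicate layers (r ≈ 0.9, screening fodder), four
informative layers with β = ±4 (the strong climatic determinism of a
montane specialist), an independent elevation field, logistic truth
suitability, presences drawn ∝ suitability among cells above the
elevation threshold, and the background equal to *all* such cells.
Paleo periods are emulated by shifting each informative layer along its
effect direction (a favourable period shifts by +s·sign(β)); a constant
same-sign shift of all layers would cancel under mixed-sign β and
change nothing after rescaling.

What passing tests on these data do *not* show: real spacer alignments
have rate heterogeneity, homoplasy and alignment error the JC/Yule
generator lacks; real occurrence data carry spatial sampling bias that
cell-and-PC thinning only partly removes; and real climate layers have
trends, anisotropy and cross-scale structure absent from smoothed
noise. Recovery rates measured here are upper bounds in that sense.

## Numerical and interface choices

- Node results are keyed by the sorted, comma-joined tip labels of each
  node's subtree — stable across tip order, node relabeling and
  serialization round trips.
- Grid I/O uses the ESRI ASCII dialect exclusively: plain text,
  bit-exact round trips (floats written with `repr`), diff-able in
  tests; masks are unioned across layers on stacking. Coordinates are
  abstract planar units; no CRS handling anywhere.
- Haplotype collapsing merges each sequence into the first matching
  haplotype in input order; with ambiguity matching this relation is
  not transitive, so pathological N-rich inputs can be order-dependent
  (absent from default fixtures, which emit no ambiguity codes).
- All stage seeds derive from one global seed by SHA-256, and every
  stochastic routine takes an explicit seed; pipeline manifests record
  per-output SHA-256 checksums, and a rerun with the same config is
  bit-identical.
- Desk-scale problem sizes used throughout (24-tip trees, 600 bp,
  80×100 grids, 10 ensemble repetitions in pipeline defaults) were
  chosen so a full run finishes in minutes on one CPU while every
  oracle comparison stays exhaustive.

## Limitations

- After environmental thinning the desk-scale ensemble trains on a few
  dozen points; out-of-bootstrap AUCs hover near 0.5 there even while
  the spatial consensus tracks the truth surface (Spearman ρ ≈ 0.65 at
  the pinned regression seed, > 0.5 required) — discrimination and map
  recovery are different quantities at these sizes.
- The probe-elimination consensus may retain a near-duplicate of an
  informative layer rather than the original when screening removed the
  original first; recovery is therefore scored on prediction, not on
  variable-name identity.
- The MCMC sampler's sup-norm agreement with the exact posterior is a
  Monte-Carlo statement; individual seeds can exceed 0.02 slightly at
  the protocol's 1500 retained samples.
- Dating CIs ignore topology/branch-length uncertainty by design.
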