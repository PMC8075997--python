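# Methods

## Scope and model overview

`wgdcoal` implements two analyses. The first detects and dates
paleopolyploidy from synonymous divergence: colinear gene pairs are chained
into syntenic blocks, each pair's Ks is estimated by the Nei–Gojobori method,
block medians are smoothed into a density curve, Gaussian peaks are fitted,
peaks are rescaled for lineage rate differences, and a calibrated reference
event converts corrected peaks to absolute ages. The second quantifies
incomplete lineage sorting: gene trees are simulated under the multispecies
coalescent (MSC) on a species tree in coalescent units and summarized as
per-branch topology frequencies, which are compared with empirical gene-tree
frequencies by rank correlation. Both analyses run on synthetic
genome-evolution fixtures with planted ground truth; no external data are
required.

## Synthetic genome evolution

A scenario is an ordered event schedule (times in Ma, strictly decreasing):
speciations split a lineage into named children, each with a clock rate
multiplier r (the lineage's Ks accumulation per Myr is `r · ks_per_myr`);
WGD events duplicate every chromosome in place (ploidy 2 or 3), each
duplicated gene independently retained with probability p, order preserved —
colinear duplicate blocks therefore exist by construction. Every extant gene
copy carries a genealogy node; the truth log records, for each pair of
copies in the same gene family, the event at which they diverged and the
expected Ks `ks_per_myr · (D_a + D_b − 2·D_split)`, where D is rate-scaled
depth. Defaults: `ks_per_myr = 0.004` (a typical angiosperm synonymous rate
of ~2×10⁻⁹ per site per year, both branches combined), 300 codons per gene,
and fixture sizes of a few hundred genes per chromosome — large enough that
per-comparison peak standard errors are well below the 0.05-Ks test
tolerances, small enough that the full pipeline runs in seconds.

Sequence divergence is modeled at fourfold-degenerate third codon positions.
Ancestral CDS are drawn uniformly over the 24 sense codons of the six codon
families (Ala, Gly, Pro, Thr, Val, Ser-TCN) in which every member has exactly
one NG86 synonymous site, all of it fourfold; the Leu (CTN) and Arg (CGN)
fourfold families are excluded because third-position exchange there creates
codons with additional synonymous first-position changes, which would inflate
the synonymous site count of mutated sequences and bias Ks low by several
percent at Ks ≈ 2. On this alphabet a branch of target divergence d applies
an exact Jukes–Cantor transition per synonymous site; JC transitions compose
additively across branches, so expected pair Ks equals the summed branch
targets with no small-divergence approximation, and the NG86 + JC estimator
is unbiased (tested: mean within 3% at Ks = 0.3, peaks within 0.05 along the
pipeline). For arbitrary input sequences the mutator rescales the per-site
transition so the NG86-counted expected difference proportion still matches
the target; this is exact on the generator's alphabet and approximate
otherwise. An optional nonsynonymous fraction adds amino-acid-changing
substitutions at first/second positions (never creating stops). Targets
above Ks = 3 are rejected: beyond that the JC correction approaches its
domain boundary (Sd/S → 3/4) and the estimator is unusable.

What the generator does *not* emulate: transition/transversion and codon-usage
bias, selection heterogeneity among sites, indels, transposable elements,
tandem duplications, and gene-order shuffling beyond WGD fractionation. Tests
passing on these fixtures therefore demonstrate correctness of the
*computations* (counting, chaining, fitting, algebra, coalescent sampling),
not robustness to every property of real genomes.

## Syntenic blocks and depth ratios

Anchors are chained per chromosome pair with a DAGchainer-style dynamic
program over 0-based gene ranks: chains advance strictly monotonically in
both genomes (antiparallel chains model inversions; enabled by default), may
skip at most `max_gap = 25` ranks between consecutive anchors, and score the
sum of anchor scores minus `gap_open = 0.05` per skipped rank. The DP keeps
two states per anchor (chain of length 1 vs ≥ 2) so the best reportable
chain is found even when an extension is locally score-decreasing;
non-overlapping chains are extracted greedily by score (ties: longer chain),
and blocks under `min_block = 10` anchors are discarded. Chaining is tested
equal to exhaustive subset search on ≤ 15-anchor inputs. Syntenic depth
counts, in windows of 50 gene ranks, how many blocks from the partner genome
cover each window; the modal depths of the two directions (covered windows
only) form the ratio, e.g. 4:1 after two full-retention doublings.

## Ks estimation

NG86 site counts: per codon position, the fraction of the three alternative
nucleotides that are synonymous, among alternatives that are not stop codons
(so S + N = 3 per codon). Differences: averaged over all orderings of the
single-step pathway between two codons; orderings passing through a stop are
excluded and the remainder reweighted (if all are blocked — impossible for
sense-codon pairs under the standard code, but guarded — stops count as
nonsynonymous steps). Site counts are averaged over the two sequences; gap
or ambiguous codons are skipped. The proportion p_s = Sd/S is JC-corrected;
values with p_s ≥ 3/4, or Ks > 3, are flagged saturated. Block summaries use
the median of unsaturated anchor Ks values (saturated ones are excluded and
counted; all-saturated blocks are dropped with a log entry) — the median is
robust both to the heavy right tail of the JC transform near saturation and
to occasional misassigned anchors.

## Density curves and peak fitting

The per-comparison Ks density is a fixed-bandwidth Gaussian KDE (default
bandwidth 0.025 Ks units) evaluated on a 512-point grid spanning
[0, max + 4·bandwidth]. A sum of Gaussian components is fitted to this
*curve* by bounded nonlinear least squares — deliberately reproducing the
curve-fitting workflow (smooth, then fit) rather than running EM on raw
values, so the bandwidth is part of the model. Components are added from 1
up to 5; each count is tried from two initializations (prominence-ranked
density maxima, leftmost first on ties; and the previous solution warm-started
with a small component at the largest residual, which makes R² non-decreasing
in the component count). Fitting stops at R² ≥ 0.95; if the threshold is
never reached the best fit is returned flagged `below_threshold`. For a
between-genome comparison "the" divergence peak defaults to the
largest-weight component, overridable per comparison.

## Rate correction and dating

With r_i species i's rate relative to the average, λ_i = 1/r_i, and an i–j
Ks peak N(μ, σ²) corrects to N(λ_iλ_jμ, λ_i²λ_j²σ²). Because the two anchor
lineages (At, Ef) diverged from every other studied lineage at effectively
the same time, a_i = λ_i/λ_Vv is estimated as the mean of μ(At–Vv)/μ(At–i)
and μ(Ef–Vv)/μ(Ef–i); the slowest lineage is assumed to evolve at the anchor
rate, giving λ_Vv = 1/max{a_i} and λ_i = λ_Vv·a_i, with λ_At pinned to 1.
When i is itself an anchor species one of the two ratios involves a
within-genome comparison and is undefined; the defined ratio is used alone.
The two pins (λ_At = 1 and max λ_i = 1) coincide only if the slowest
corrected lineage matches the anchor rate; any discrepancy is reported as
`pin_conflict`, never silently rescaled. A consistency report verifies that
all corrected anchor–i peaks equal the corrected anchor–reference peaks.

Ages scale the calibration window linearly: an event with corrected peak μ_e
against a reference with corrected peak μ_ref and calibration [115, 130] Ma
dates to (μ_e/μ_ref)·[115, 130]; both endpoints scale, so every reported
interval preserves the calibration's high/low ratio. Reported endpoints are
rounded to integer Ma; raw values are retained. Only the calibration range
is propagated — σ of the peaks is carried through the correction as a
diagnostic but not folded into the printed intervals.

The correction is multiplicative on whole peaks, which matches reality
exactly when the compared lineages' extra rate sits on one side of the
comparison and the anchors are rate-1; the corrected event/reference ratio
recovers true ages exactly when the dated event shares the reference
lineage's clock (how the recovery fixture is built: both planted polyploidies
in the fast reference lineage). For events on lineages with a different
rate the method's own algebra leaves a residual distortion of order the rate
contrast; this is a property of the procedure being reproduced, not of the
implementation.

## Multispecies coalescent and quartet frequencies

Species trees are rooted and binary, internal branch lengths in coalescent
units, terminal branches defaulting to 1 (one sampled allele per species).
Within a branch of length t carrying k lineages, coalescence waiting times
are exponential at rate k(k−1)/2 with uniformly chosen pairs; surviving
lineages coalesce in an unbounded root branch. Gene trees are stored as
merge sequences over leaf bitmasks, which makes per-branch classification a
vectorized mask query and newick export trivial.

Around a focal internal branch the four neighbour clades are the child
clades C1 and C2, the sibling clade S, and the remainder R (when the branch
is a root child, the sibling's two children serve as S and R; a leaf sibling
leaves only three neighbour groups and is rejected). Each gene tree is
scored by the fraction of one-leaf-per-clade quartets displaying each of the
three resolutions — the same statistic as per-branch quartet support — so
q1 + q2 + q3 = 1 exactly. Under the MSC, q1 = 1 − (2/3)e^(−t) and
q2 = q3 = (1/3)e^(−t) for branch length t; the inversion
t = −ln(1.5·(1 − q1)) converts an empirical concordant fraction to a branch
length.

The 14-taxon study tree places Amborella and Euryale successively sister to
all other angiosperms, and magnoliids then monocots successively sister to
(Ceratophyllum, eudicots); Ginkgo is the outgroup. Focal branch lengths
0.2163 and 0.1004 coalescent units are the inversions of the empirical
concordant fractions 46.3% and 39.7%; non-focal internal branches are set to
5 coalescent units so residual discordance off the focal branch is
O(e⁻⁵) ≈ 0.7%, within the comparison tolerances. Simulations default to
20,000 gene trees (200,000 also supported — both counts appear in the
reproduced workflow); at n = 20,000 the binomial standard error of a
frequency near 45% is ~0.35 percentage points. Concordance between
simulated and empirical frequency vectors uses Spearman's rank correlation
with a two-sided p-value.

## Numerical and design choices

- Saturated Ks values are flagged and excluded, not clipped: clipping would
  pile mass at the cap and distort the KDE.
- Mixture-fit bounds: means within the grid, σ ≥ 10⁻⁴, weights in
  [0, 2·curve mass]; ties among initial means broken leftmost-first.
- Anchors may belong to at most one block; within-genome self-pairs are
  excluded; anchor tables are canonicalized so grouping is orientation-stable.
- Branch identity in all tree outputs is the sorted leaf set of the subtended
  clade, so empirical tables and simulated trees align unambiguously.
- Gene ranks are 0-based everywhere; positions are gene order, not base pairs.
- All randomness flows through explicit integer seeds (NumPy generators for
  sequence evolution, a dedicated `random.Random` stream for the coalescent
  sampler); identical scenario + seed reproduces outputs byte for byte.

## Known limitations

- The NG86 estimator here pairs with Jukes–Cantor only; no
  transition/transversion (kappa) correction is offered.
- The rate correction assumes simultaneous basal divergences of both anchors
  from every corrected lineage; violations propagate into a_i (see the
  consistency report) rather than being modeled.
- The coalescent simulator is topology-only (no substitution-model branch
  lengths on gene trees) — sufficient for frequency summaries, not for
  sequence simulation.
- Syntenic depth uses fixed windows of gene ranks and modal depth; it is a
  diagnostic summary, not a segmentation of the genome into coverage classes.
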