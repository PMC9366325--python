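# Methods

This note records the models, parameter choices and numerical conventions
behind `senemeth`, and what the synthetic-data experiments do and do not
demonstrate about real bisulfite data.

## Data model and coordinates

Per-cytosine records follow the Bismark `--CX --cytosine_report` dialect:
1-based positions on the cytosine's own strand, methylated/unmethylated
read counts, CG/CHG/CHH context (H = A, C or T) and the strand-local
trinucleotide. All interval arithmetic — genes, TEs, promoters, DMRs,
motifs, bins — is 0-based half-open (BED convention); the converters in
`senemeth.io` are the only place the two dialects meet. Sequence context
is decided by the two bases 3′ of the cytosine on its strand; a context
truncated at a chromosome end or containing an N is `NA` and excluded from
all downstream statistics (fabricating a context from incomplete sequence
would bias the CHH class, the catch-all).

Coverage filtering keeps sites with 3 ≤ coverage ≤ 40, the inclusive
complement of removing sites with coverage below 3 (unreliable
proportions) or above 40 (collapsed repeats, PCR stacks). The filter is
applied per sample; it is idempotent and order-preserving.

Fixed-width bins (50 bp default) carry the count-weighted mean
Σmeth/Σ(meth+unmeth) over member cytosines of both strands; bins with no
covered cytosine are *missing*, not zero — treating them as zero would
shrink inter-sample distances toward sparsely covered regions.

## Differential methylation

### Dispersion

Replicate-to-replicate variability is modelled as beta-binomial
overdispersion φ: Var(X/N | N) = p(1−p)(1+(N−1)φ)/N. Per site, φ is
estimated by the method of moments from the replicate proportions of both
groups (residual-df-weighted), clipped into [10⁻⁴, 0.5], and shrunk toward
the context-wide 20%-trimmed mean with weight w = m/(m+k), where m is the
covered-replicate count at the site and k = 4 sets the shrinkage strength
(with triplicate designs, m ≈ 6, so roughly 60/40 site/prior). The two
regimes that matter behave correctly by construction: identical replicate
proportions collapse to the lower clip, and unreplicated sites inherit the
prior exactly. This moment-plus-shrinkage scheme is a deliberately
lightweight alternative to a full Bayesian hierarchical fit; its type-I
calibration is verified by simulation (below). No smoothing across sites
is performed — levels at neighbouring cytosines are taken as exchangeable
only through the dispersion prior, never through their means.

### Site test, DML and DMR calls

The Wald test on pooled group proportions is described in the README. Two
conventions: zero-variance ties (both groups degenerate at the same value)
give z = 0, p = 1, preventing 0/0; sites with zero total coverage in
either group are skipped and counted in the log. The `direction` label
describes the change from group 1 to group 2, so with group 1 the earlier
stage, `hypo` means methylation was lost over time.

A DML requires posterior P(|Δ| > 0.25) ≥ 0.95 under Δ ~ Normal(diff, se²)
— the delta-posterior route; a post-hoc filter (raw p < 0.05 and |diff| ≥
0.25) is available as a flag, as is optional Benjamini–Hochberg
correction (off by default: the study design tests a planned set of six
pairwise comparisons at a fixed per-site threshold).

DMR calling uses *raw-p* significance (p < 0.05) for region membership
with no per-site effect-size gate (`delta = 0`): regions accumulate
evidence across members, and demanding each member individually clear a
25% change would leave region recovery hopeless at realistic coverage —
at coverage 20 with three replicates and φ = 0.05, the per-site power to
clear the delta-posterior at a true 0.30 shift is ≈ 13%. This mirrors the
default behaviour of the established region callers; the delta-posterior
mode remains available via `delta > 0`. Seeds are maximal runs of
same-direction significant sites with inter-site gaps ≤ 100 bp (the one
merge distance the study design fixes); same-direction regions closer
than that are merged; filters (span ≥ 50 bp, ≥ 3 member sites, ≥ 50%
significant members) apply after merging. areaStat = Σz ranks regions.

### Calibration results (recomputed by `scripts/acceptance.py`)

* Type-I error of the site test under the null (β = 0.3, φ = 0.05, 3 vs 3
  replicates, coverage ~15, 5000 sites) sits in the 0.03–0.08 band at the
  nominal 5% level. The mild anti-conservatism (~0.06) is the familiar
  Wald-statistic bias at moderate coverage.
* Planted-region recovery: 20 regions of 10 consecutive sites at
  |Δβ| = 0.30, coverage 20, sites 15 bp apart — the expected CG inter-site
  distance in a 36%-GC genome — are recovered with ≥ 80% sensitivity and
  ≤ 4 false regions at the default caller settings.

## Genomic architecture

Promoters are the 2500 bp immediately upstream of the ATG (the annotation
convention of the study design; a TSS-based switch is a function
argument), clipped at chromosome boundaries. Two compartment views
coexist: non-exclusive membership {promoter, ORF, TE, total} for
stage × compartment × context means (a TE inside a gene counts toward
both, matching how such summary figures are usually drawn), and exclusive
labels with precedence TE-in-promoter > TE-outside-promoter > ORF >
promoter-without-TE > intergenic for composition fractions. Intervals are
labelled by their midpoint (regions can straddle boundaries; per-base
fractional assignment would complicate the partition-of-unity property
for no analytic gain at these scales).

`intersect`/`closest` re-implement the bedtools semantics under half-open
coordinates: overlap requires a non-empty intersection; the gap between
half-open intervals is b.start − a.end, so adjacency is distance 0 with
`overlap=False`; ties break by leftmost start, then lexicographic id.
Both are fuzz-tested against quadratic brute-force oracles.

Metagene profiles take genes strictly longer than 400 bp, 1000-bp flanks
in twenty absolute 50-bp bins, the body in twenty equal relative bins
(body bin count is a resolution/sparsity compromise at desk scale), minus
strand genes reversed so bin 0 is always 5′. Per gene, bins are
count-weighted; across genes the mean is unweighted, so long highly
covered genes do not dominate.

Sample concordance: 50-bp-bin weighted means, listwise deletion of bins
missing in any sample, Manhattan distances, and principal components of
the centred (not scaled) bin matrix — the `prcomp(center=TRUE)`
convention.

## Motif analysis

The scanner expands IUPAC patterns to regular expressions inside a
lookahead so overlapping matches are all reported; with both-strand
scanning, reverse-complement matches are mapped to reference coordinates,
and exact palindromes (the bZIP boxes) are deduplicated to one occurrence
per position. Both-strand scanning is the default (a W-box is functional
on either strand); forward-only mode is provided because a single-pattern
scan convention is also common, and the two modes differ by roughly a
factor of two in genome-wide counts.

Motif cytosines are every reference C (plus strand) and G (minus strand)
inside the occurrence, with contexts derived from the genome — so the
W-box cytosine of TTGACTG reads CHG while TTGACTA reads CHH, and each
bZIP palindrome contributes a symmetric CG pair. Motif-set methylation is
the *unweighted* mean over covered sites of replicate-mean β (site-level
averaging; a coverage-weighted mode is a flag).

The bootstrap draws B subsets of the background (same context, same
compartment) of the motif-set size, without replacement, and reports the
add-one-corrected one-sided empirical P in the observed direction; a
pre-registered direction and a two-sided doubling are available. Sorting
the background before sampling makes the P estimate exactly invariant to
background order, and the generator seed fixes the draw sequence. Under
the null (motif set itself drawn from the background), fixed-direction
p-values are uniform: the KS statistic against U(0,1) over 500 repeats at
B = 2000 stays below 0.08. A planted +0.10 shift on 200 motif cytosines
against 20 000 background sites is detected at p ≤ 0.01 in ≥ 95% of
seeded runs. In the pipeline the background is capped at 20 000 sites
(seeded subsample) and B defaults to 2000 to keep a full run fast; both
are config fields and the B = 10 000 convention is one line of YAML away.

## Expression and leaf-colour tools

The ΔΔCt implementation follows the Livak scheme: per technical
replicate, ΔCt = Ct(gene) − mean Ct(reference gene) at the same (time
point, biological replicate); per (gene, biological replicate), ΔΔCt
subtracts the mean ΔCt at the reference time point; expression is 2^−ΔΔCt
with technical replicates averaged on the log scale. Averaging the
technical-replicate ΔCt *before* subtracting the reference-time-point
entry of the same aggregate makes the reference value an exact
floating-point 1 per biological replicate — the normalization contract —
rather than 1 ± ε. Arithmetic-scale averaging is available behind a flag
and does not preserve the exact identity.

The chlorophyll model is OLS on [1, pg, pg·g_norm, pg·pgy] with
pg = green/total pixels, pgy = green-yellow/total, and g_norm the
green-pixel deficit relative to the leaf position's maximum green count.
Quality is summarised by repeated stratified 5-fold cross-validation
(10 repeats, folds stratified on outcome-quantile bins, deterministic per
seed, fold sizes within one); at a noise SD of 30% of the response SD the
held-out R² lands near 0.89–0.91, the regime such colour-based predictors
typically report. Rank-deficient designs raise an error naming the
collinear terms.

## Synthetic data: what it emulates, and what it does not

The generator produces an AT-rich (GC 0.36) two-chromosome genome with
non-overlapping genes and TEs (a configurable fraction of TEs placed
inside promoter windows so the TE-in-promoter compartment exists), planted
motif instances, and per-cytosine counts for 4 stages × 3 replicates.
True levels are compartment × context baselines (TE-CG 0.85, TE-CHG 0.40,
TE-CHH 0.10, gene-body CG 0.15, promoters/intergenic lower) plus additive
stage shifts encoding the senescence narrative — CG loss to a minimum at
SD (strongest in TEs), partial CG recovery at SM, late CHH/CHG gain in
TEs and promoters above the starting level — plus planted differential
elements: contiguous runs of 5–50 same-context cytosines (region-shaped)
and isolated single sites, with clipping-safe placement so each element's
defining |Δβ| is actually realised. Replicate noise is beta-binomial
(Beta-distributed per-replicate level around the truth, φ = 0.05 per
context) over truncated negative-binomial coverage (mean 15, size 8,
ceiling 100), which deliberately produces sites below 3× and above 40× so
the coverage filter is exercised. One seed determines everything;
identical configs give byte-identical files and manifest hashes.

Default problem sizes: the generator's default genome is 2 Mb; the
analysis drivers and the reproduction script run a 400-kb configuration
(80 genes, 40 TEs, ~144 000 cytosine sites, ~864 000 site-tests across
the six comparisons), the package's desk-scale choice that keeps a full
run around a minute while leaving every statistic well inside its
asymptotic regime.

What passing on synthetic data shows: the estimators recover the
parameters they were built for, the callers are calibrated at their
nominal levels, and the planted qualitative narrative (directional
asymmetries, CG dip, CHH-led late gains, stage-wise clustering,
motif-methylation contrasts) survives the whole pipeline. What it cannot
show: robustness to mapping bias, bisulfite-conversion failure,
centromeric repeat structure, copy-number variation, or biological
dispersion heterogeneity beyond a single φ per context — none of which
the generator simulates. Conclusions about real tissue still require the
real data.

## Known limitations

* The dispersion model is moment-based with a single shrinkage constant;
  extreme low-coverage designs (single replicates everywhere) degrade to
  the pooled-binomial floor with a warning rather than borrowing strength
  across positions.
* The site test is unsmoothed; sparse CHH sites in small compartments can
  be underpowered relative to smoothing callers.
* `closest` ties are resolved deterministically (leftmost start, then id),
  which may differ from other tools' undocumented tie orders.
* The motif dictionary is exact-match (two W-box variants, three bZIP
  palindromes); degenerate extensions and PWM scanning are out of scope.
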