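# Methods

This note documents the models implemented in `ggxe`, their assumptions,
the defaults and why, and the design choices made where the methodology was
genuinely open.  No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Population and genotype model

The population is a biparental recombinant inbred line (RIL) cross taken to
the infinite-selfing limit: every line is fully homozygous at every marker,
coded `A` (parent 1, "Ler"-like) or `B` (parent 2, "Cvi"-like), numerically
+1/−1.  Genotypes are simulated chromosome-wise as a Markov chain over the
ordered markers: the first marker is A or B with probability 1/2, and
adjacent markers at genetic distance *d* cM differ with probability

R(d) = 2r / (1 + 2r),  r = (1 − e^(−2d/100)) / 2,

the classical map expansion of a selfed RIL under Haldane's (no
interference) map function.  A marker-to-marker chain rather than an
explicit crossover process is deliberate: every downstream statistic sees
only the marker-level correlation structure, which the chain reproduces
exactly in expectation.  Crossover interference is not modelled.  The two
parents are carried as pseudo-lines of constant genotype (all A / all B) so
that parents and RILs flow through the same code paths.

Default scaffold: 5 chromosomes × 20 equally spaced markers over 85 cM
(≈4.5 cM spacing, 250 kb/cM), 160 lines — a desk-scale configuration that
keeps the full test suite fast.  A paper-scale density (120 lines, 35
markers per chromosome ≈ 2.5 cM spacing) is used wherever a result depends
on dense-map correlation, notably the FDR-inflation analysis.

## Expression model

Gene *g* in a sample of line *l* is

y = baseline_g + β_g(env) · x(l, source_g) + N(0, σ_g),

with environment-specific β.  The three canonical architectures are
*cis* (source marker nearest the gene's own annotated position), *trans*
(source anywhere), and *null* (β = 0).  Genotype-by-environment interaction
is expressed through the per-environment βs; the sign-flip architecture
(β, −β) is the scenario in which the two parental alleles are most active
in different environments.  Defaults mirror the replication structure of
the emulated design (3 replicates per RIL, 9 per parent); most calibration
runs use 1 RIL replicate since scans average replicates per line anyway.
The generator emulates normalized log-scale expression directly; it does
not model array/dye effects, count noise, batch structure, or correlated
residuals between genes — so passing recovery tests demonstrate correctness
of the statistics under the stated model, not robustness to those
real-data complications.

## Genome scan

Replicates are averaged per line, then every gene is regressed on every
marker in one vectorised operation.  With ±1 coding the regression slope
equals half the genotype-class mean difference (the additive effect; the
sign convention is that positive effects mean the parent-1 allele raises
expression) and the slope *t*-test is identical to the pooled two-sample
*t*-test — the suite verifies this equivalence to 1e−10 against an
independent implementation.  −log10(p) is computed through the log survival
function so the far tail is exact, and capped at 300 to avoid infinities
(flat genes return p = 1 and effect 0; zero residual variance with a
non-zero effect returns the cap).

A multiple-QTL mode is provided as greedy forward selection of marker
cofactors (smallest conditional p below `entry_p`, deterministic
(chromosome, position) tie-break, capped at `max_cofactors`), with markers
within 10 cM of a cofactor skipped in the conditional scan.  This is a
declared stand-in for unpublished cofactor-selection procedures used in
earlier work of this kind; plain marker regression is the default mode.

## Genome-wide significance

Two thresholds, combined by taking the more stringent:

1. **Permutation threshold.** Line labels of a trait are permuted against
   the fixed genotypes; the genome-wide minimum p per permutation is
   recorded (permutations cycle round-robin over the gene panel) and the
   empirical α-quantile (default α = 0.05, 10,000 permutations) is the
   threshold.  On an all-null simulation the per-gene genome-wide
   false-positive rate at this threshold is α within Monte-Carlo error
   (acceptance check).
2. **Corrected pooled-FDR threshold.** All gene × marker p-values from a
   thinned marker set are pooled, Storey q-values computed, and the largest
   p with q ≤ nominal_FDR / correction_factor returned.  Thinning is greedy
   left-to-right per chromosome, keeping a marker only if its genotype r²
   with the last kept marker is ≤ `r2_max` (default 0.95) — an
   operationalisation of "leave out neighbouring markers", which adjacency
   alone does not pin down.

**Why the correction factor.** FDR control on the pooled gene×marker tests
is not FDR control on gene discoveries: a true eQTL drags a block of
correlated neighbouring markers into the rejection set, the step-up cutoff
loosens, and extra null genes pass.  `estimate_fdr_inflation` measures the
realized gene-level FDR by simulation on the actual genotype correlation
structure — a minority of single-marker effect genes (default 1/5 of the
null count, β = 1) among nulls, q-values over the pooled matrix, a gene
counted as discovered if any marker passes — and reports mean FDP /
nominal.  The simulation must contain signal genes: with an all-null pool
the false-discovery proportion degenerates to an any-discovery indicator
and the mechanism above cannot occur.  At one marker per chromosome the
factor is ~1 (no correlation, no multiplicity distortion); at 35 markers
per chromosome with 120 lines it exceeds 2 and grows with density
(acceptance check).  The integer `correction_factor` defaults to the
ceiling of the estimated inflation, mirroring the "round the estimated
inflation up" practice.

Storey's π₀ is estimated by a cubic polynomial fit of π₀(λ) over λ ∈
{0.05, …, 0.90} evaluated at the largest λ (the polynomial plays the role
of the usual df=3 smoothing spline; an interpolating spline would
degenerate to the last grid value).  `pi0_mode="one"` reproduces
Benjamini–Hochberg exactly (verified to 1e−12) and a fixed-λ mode is
available for deterministic tests.

## Peaks and local/distant classification

Per gene and chromosome, each maximal run of adjacent markers with score ≥
threshold is one eQTL; the peak is the highest-scoring marker (leftmost on
ties) and the support interval is the run.  A peak is **local** iff it lies
on the gene's chromosome within `window_bp` of the gene (inclusive),
default 2 Mb — a deliberate, configurable choice reflecting the broad
linkage disequilibrium of a ~120-line RIL cross; no published window
exists for this design.  Genes roll up into {only local, only distant,
both}.

## Hotspots

Peaks are counted per peak-marker.  Under the uniform null the count at one
marker is ≈ Poisson(λ = T/M) for T peaks over M markers; the hotspot
cutoff is the smallest c with P(X ≥ c) ≤ α/M (Bonferroni across markers).
The Poisson/Bonferroni rule is this package's choice — hotspot thresholds
in the literature are typically unstated — and it is conservative by
design: uniform placements are flagged in well under α of runs, while a
simulated 30-target trans band is detected essentially always (acceptance
checks).  Either the total or only the distant count can be tested.

## Plasticity across two experiments

Per gene, the signed profile s_m = −log10(p_m)·sign(a_m) condenses a scan;
the Pearson correlation of a gene's two profiles classifies regulation as
strong-positive (r > 0.5), strong-negative (r < −0.5) or weak — the
boundaries are strict inequalities by convention.  Profiles that are
constant (no signal) leave r undefined; such genes are classed weak with r
recorded as missing.  Genes measured in only one experiment are excluded.
Called peaks are additionally matched per gene across experiments by
greedy closest-pair matching on the same chromosome within
`max_peak_distance_cm` (default 10 cM, inclusive); "overlap" by peak
distance was chosen over marker identity (too strict under noise) and
support-interval intersection (offered implicitly via the interval columns)
because it is monotone in a single interpretable parameter.  Matched pairs
with strictly opposite effect signs are the opposite-effect (plastic)
eQTLs; opposite-effect implies overlapping by construction.

## Population statistics

* **Differential expression**: pooled-variance two-sided *t* per gene
  (identical groups give p = 1), Storey q over the full gene set.  This is
  a plain linear-model test, not an empirical-Bayes moderated one;
  moderation is out of scope and at the replicate numbers simulated here
  the difference is immaterial to the calibration tests.
* **Broad-sense heritability**: parents mode decomposes the parental
  replicate ANOVA (Ve = within-line mean square, Vg = (MSB − MSW)/n₀
  floored at 0); RIL mode takes the among-line variance of line means as
  total and the pooled parental replicate variance — rescaled to the
  line-mean level by the number of replicates averaged per line — as Ve,
  Vg = total − Ve floored at 0.  H² = Vg/(Vg+Ve), clipped to [0, 1].  The RIL
  decomposition is a declared reconstruction; the suite verifies that the
  median estimate recovers the generating ratio within ±0.05.
* **Transgression**: per gene, μ and SD of each parent's replicates; count
  RIL line means above μ_max + 2·SD_max or below μ_min − 2·SD_min.  A gene
  is called transgressive at `n_min` extreme lines (default 2: one extreme
  line is not evidence).  The published "(n = 20)" notation for this
  statistic is ambiguous (a per-gene count? a calling threshold?) and is
  deliberately not guessed; `n_min` is configuration.

## Enrichment and genomic bookkeeping

The hypergeometric upper tail is summed in log space (gammaln +
logsumexp), exact to floating precision — verified against rational
arithmetic enumeration for N ≤ 60 and spot-checked at N = 2000.  The
default tail is strict, P(X > k), matching the convention behind published
over-representation bounds; the inclusive tail is available and every
result records which was used.  Intervals (e.g. NIL introgression
segments, defaults chr1 5.0–8.2 Mb and 26.5–30.4 Mb) are closed and
1-based.  Binned counts assign positions to midpoint-to-midpoint marker
loci (chromosome ends extend outward), optionally weighted.  Distribution
correlations use t = r·√((n−2)/(1−r²)) with n−2 df, two-sided.

## Numerical and reproducibility choices

* All simulators take integer seeds; the pipeline fans a single config
  seed out per stage; identical seeds give byte-identical outputs (hashed
  in the suite).
* TSV everywhere, header row, `NA` for missing, floats at 6 significant
  digits, deterministic sort orders.
* −log10(p) ceiling 300; p is reconstructed as 10^(−score) so the two
  views agree exactly.
* Degenerate inputs are pinned: flat traits p = 1; monomorphic markers are
  errors; constant profiles give missing r.

## Problem sizes

Calibration and recovery analyses run at 160 lines × 100 markers with
500-gene panels and 1,000 permutations; FDR inflation at 120 lines × 175
markers with 300 null + 60 signal genes × 5 replicates; hotspot power over
100 simulated replicates and 200 null placements.  These sizes were chosen
to put Monte-Carlo error well inside the tested margins while keeping the
whole suite runnable in minutes on a single core.

## Known limitations

* Single-marker (optionally cofactor-conditioned) scans only: no interval
  mapping between markers, no epistasis, no QTL-effect confidence
  intervals.
* Profile correlation is the only genotype-by-environment statistic; no
  joint two-environment interaction model is fitted.
* The simulator's independence assumptions (gene-independent noise, no
  batch or array structure) mean calibration results transfer to real data
  only to the extent those assumptions hold.
* Heritability decompositions assume balanced or near-balanced replication.
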