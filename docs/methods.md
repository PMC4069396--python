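# Methods

`sedimeta` reimplements, as a tested pipeline over synthetic data, the
computational analysis typically applied to oil-spill-impacted marine
sediment surveys: (1) community ordination of 16S OTU counts with
environmental-vector fitting, (2) exceed vs non-exceed comparison of
metagenome functional profiles, and (3) predicted relative metabolic
turnover (PRMT) of metabolites from enzyme (EC) abundances. This note
records the models, their assumptions, the defaults and the numerical
choices; the simulator section states exactly what the synthetic study does
and does not emulate.

## Community ordination

**Filtering and rarefaction.** OTUs with fewer than `min_count = 10` total
sequences across all samples are removed (boundary inclusive: a 10-sequence
OTU is kept). Each sample is then subsampled *without replacement* to a
common depth (`depth = 122 804` reads by default, the survey's minimum
retained library size) using a multivariate hypergeometric draw, so
per-feature expectations are `depth * x / total` and no count can exceed its
input. Samples below the depth are dropped with a logged warning. A single
draw is taken per sample (no averaging over draws); the seed is mandatory.

**Dissimilarity.** Bray–Curtis, `d(u,v) = Σ|u−v| / Σ(u+v)`, computed on the
rarefied counts. Jaccard could be substituted upstream of `nmds` by passing
a different distance matrix; Bray–Curtis is the default because it is the
standard abundance-based companion of NMDS in community ecology.

**NMDS.** Non-metric multidimensional scaling minimizing Kruskal stress-1,

    stress = sqrt( Σ (d̂_ij − δ_ij)² / Σ δ_ij² ),

where δ are configuration distances and d̂ the isotonic (monotone)
regression of δ on the rank order of the input dissimilarities, with the
*primary* approach to ties (tied dissimilarities are sub-sorted by δ and
impose no constraint). The optimizer alternates the isotonic fit with a
Guttman (majorization) update of the configuration; an update is accepted
only if stress decreases, with step halving otherwise, which makes the
per-iteration stress sequence non-increasing by construction. The first of
`n_restarts = 20` starts is a Torgerson (classical metric MDS)
initialization, the rest are Gaussian random; the lowest-stress solution
wins, ties broken by restart index. Convergence is a relative stress change
below `tol = 1e-6` within `max_iter = 300` iterations; non-convergence sets
a flag rather than raising. The returned configuration is centered and
rotated to principal axes with a deterministic sign convention
(largest-magnitude loading positive).

**Environmental vectors.** A variable `v` is fitted by least-squares
regression of the centered values on the ordination coordinates; the fitted
direction is the unit coefficient vector and `r²` the regression R². The
p-value permutes the raw variable values across samples (vegan's
convention), with the add-one estimator

    p = (1 + #{ permuted r² ≥ observed r² }) / (1 + n_permutations),

`n_permutations = 999` by default, so p is bounded below by 1/1000. Samples
missing the variable are excluded from that variable's fit only.

**Species scores.** A feature's ordination position is the weighted average
of sample coordinates, weights proportional to the feature's per-sample
relative abundance; a feature present in a single sample sits on that
sample, a uniformly abundant one at the origin.

## Functional comparison

Per-read alignment hits (tabular BLAST/usearch dialect) are filtered at
e-value ≤ 1e-5, identity ≥ 60 %, alignment length ≥ 15 (all inclusive); the
single surviving hit with the highest bit score, subject to bit score ≥ 40,
is assigned per read. Equal bit scores break to the lexicographically
smallest subject id, making assignment independent of input order. Counts
aggregate per (gene family, sample) and can be rolled up a three-level
function hierarchy with column totals conserved.

Group comparison is a per-family two-sided Welch (unequal-variance) t-test
on percent proportions with Welch–Satterthwaite degrees of freedom and a
0.95 confidence interval of the difference. The effect filter keeps
features with |difference of mean proportions| ≥ 1.00 percentage point;
Benjamini–Hochberg q-values are computed over the filtered set alongside the
raw p-values (the default significance call is raw p ≤ 0.05 plus the effect
filter). Features with zero variance in both groups and equal means get
p = 1 rather than NaN. The sample–function network keeps an edge whenever a
family is observed ≥ 20 times in a sample ("fewer than 20" omitted, so 20
stays, 19 goes); the graph is exported as an edge list / networkx object,
not drawn.

## PRMT

The environmental transformation matrix (ETM) condenses a reaction database
into metabolite × EC weights: for EC *e* with reaction set *R_e*,

    W[m, e] = (1/|R_e|) Σ_{r ∈ R_e} s(m, r),

with `s = +ν` when the reaction consumes metabolite *m* with stoichiometric
coefficient ν, `−ν` when it produces it. Averaging over |R_e| keeps
promiscuous ECs from dominating; a `sum` mode is available. Reversible
reactions are scored in the written direction (left side consumed), or can
be skipped entirely. Currency metabolites (H2O, H+, ATP, ADP,
orthophosphate, NAD(P)+/NAD(P)H, CoA) get no row by default; nitrogen
species are never excluded by default because they are the analysis target.

EC abundance columns are quantile normalized (each value replaced by the
mean of the per-sample sorted values at its rank; ties receive the linear
interpolation of the reference at their average rank, so identical columns
are unchanged) and then log2(x + 1) transformed — the pseudocount handles
zero counts, on which the transform is otherwise undefined. Scores are

    S[m, j] = Σ_e W[m, e] · (A[e, j] − mean_j' A[e, j']),

i.e. each sample is compared against the mean of all samples; every
metabolite row therefore sums to zero, and a positive score predicts
relative *consumption*, a negative one relative *accumulation*.

Quantile normalization assumes most features are not differentially
abundant between groups; when a large fraction of a small feature set is
enriched, the forced common distribution transfers enriched-column
magnitudes onto whichever null feature tops a column. The simulator
therefore ships a ~140-family catalog (enriched fraction ≈ 6 %), matching
the realistic regime of annotation tables with hundreds to thousands of
functions.

Group comparison defaults to the Wilcoxon rank-sum statistic with a
two-sided group-label permutation p-value (1000 permutations, add-one
estimator, expectation-centered: `|W − n_a(n+1)/2|`). A paired signed-rank
mode with sign-flip permutations is provided for matched designs; the
unpaired default is used for the independent exceed / non-exceed groups.
The direction report labels each metabolite by the sign of the mean score
gap between groups (`consumption_up` when the first group's mean score is
higher, `ambiguous` at exact equality).

## The synthetic study

The generator emulates the *structure* of a deep-sea spill survey, not its
measurements: 64 samples at log-uniform distances 0.3–256 km, the 19
nearest (within 5 km) flagged as exceeding the benchmark; log10(TPH)
decreasing in log-distance with Gaussian noise, spanning 18–65 643 μg kg⁻¹;
ammonium (hence DIN) elevated where TPH is high. The OTU table has a
log-normal rank-abundance baseline plus three responder taxa whose expected
relative abundance follows a Hill curve in TPH (coefficient 2, half
saturation 8 000 μg kg⁻¹; a single-site Monod form cannot be simultaneously
< 1e-4 at 18 μg kg⁻¹ and near its cap at 65 643 μg kg⁻¹). The dominant
responder saturates at 18 % relative abundance, the others at harmonically
decaying caps. Counts are multinomial at depths drawn uniformly from
125 000–180 000 reads, so rarefaction at 122 804 retains every sample.

The metagenome subset is 7 exceed vs 7 non-exceed samples over ~140 gene
families (nitrogen-cycle ECs, hydrocarbon-degradation genes, null
background). Planted counts are Poisson (mean 80 reads/family), multiplied
by `enrichment_fold = 4` in exceed samples for the enriched set
(denitrification ECs nar/nap/nir/nor/nos plus representative BTEX, PAH and
alkane genes). Each counted read gets one true hit (bit score ~ N(80, 10)
truncated ≥ 41) plus decoys under the 40-bit cutoff and decoys failing
exactly one pre-filter, and extra decoy-only queries, so the filtering
stages are exercised; by construction `assign_best_hits ∘ filter_hits`
reproduces the planted table exactly. The reaction database is a
hand-written toy nitrogen cycle with plausible EC labels (a synthetic
fixture, not a KEGG extract). Setting `enrichment_fold = 1` and
`responder_max_fraction = 0` yields a null study used as a negative
control.

What the simulator does *not* emulate: sequencing error, chimeras and OTU
picking artifacts; taxonomic structure beyond a rank-abundance curve;
spatial autocorrelation beyond a single distance axis; measurement error in
the chemistry; compositional coupling between the 16S and metagenome
libraries. Passing recovery tests therefore demonstrates that the pipeline
detects planted effects of realistic size under idealized noise — not that
it would have identical power on field data.

## Problem sizes and determinism

Tests and the acceptance script run the full 64-sample community analysis
and 7-vs-7 functional/PRMT comparisons at the defaults above; replicate
experiments (detection and recovery rates, null calibration) use 10–50
reseeded studies, and per-read hit simulation is skipped where only the
planted count table is needed. Every random draw flows from
`numpy.random.default_rng` seeded either directly or via per-stage seeds
derived as `sha256(master_seed:stage)[:4] mod 2^31`, so a master seed fixes
every input and result file byte for byte. Stage wall times are logged to
`run.log`, which is deliberately outside the determinism contract.
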