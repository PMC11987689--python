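# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `asynchom`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design emulated by the generator

The synthetic module reproduces the shape of an urban-soil field campaign:
three climatic zones (boreal, temperate, tropical); in each zone, young
parks and old parks with three plant types (recalcitrant-litter trees,
labile-litter trees, lawns) at 5 replicates each, and a reference forest
with the two tree types only (lawns do not occur in forests) at 5
replicates — 40 plots per zone, 120 in total. Disturbance level
(reference forest → old park → young park) is the gradient of interest;
plant type and replicate are carried in the metadata so vegetation types
can be averaged within a park (`average_within_park`) when the analysis
should isolate urbanization.

## Community generator

Plots in a (zone × disturbance) group share a mean composition built from
a regional log-normal (or gamma) abundance profile. A `generalist_fraction`
of taxa keep that profile in every group; the remaining specialist taxa are
boosted 5× in one home group (round-robin across groups) and reduced to a
background fraction (default 0.02) elsewhere. Plot compositions are drawn
from a Dirichlet around the group mean with concentration

    c = concentration_scale / (base_dispersion × homogenization_factor),

so the homogenization factor multiplies within-group compositional spread
directly: the defaults 1.0 / 0.6 / 0.3 for forest / old park / young park
encode dispersion shrinking along the gradient. Counts are multinomial with
`n_reads` (default 2000) reads per plot. Defaults (200 taxa, concentration
scale 50) were chosen once to give realistic occupancy structure (most
taxa present in most plots of their home groups, rare elsewhere) and a
clearly bimodal niche-width distribution; the magnitude of the dispersion
effect is a free choice of the generator, not a measured field quantity.

What the generator does **not** emulate: sequencing error, compositional
bias, read-depth variation between plots, taxon correlations beyond the
group structure, or probe-level GeoChip noise. Passing tests therefore
demonstrate correctness of the statistical machinery on data with a known
generating process, not robustness to every artifact of real amplicon data.

Trait intensities are log-normal per-taxon profiles blended between one
shared profile and taxon-specific profiles by the `redundancy` knob
(1 = every taxon functionally identical, 0 = independent); a taxon has
records only in plots where it is present. Because β_diss is a ratio of
sums over taxon × trait intensities, redundancy 1 makes plots with equal
presence sets functionally indistinguishable.

## Preprocessing

* Rare-taxon filter: "occupying fewer than a fraction f of plots" is read
  literally — a taxon is removed iff its occupancy count is strictly below
  f × n_plots (with 120 plots and f = 0.10, the cutoff is "< 12 plots").
* Hellinger transform: square root of row-relative abundances.
* z-scores use the sample standard deviation; zero-variance columns map to
  zeros with a warning so degenerate synthetic tables keep flowing.

## Dispersion testing

PERMDISP follows the `betadisper` formulation: principal coordinates from
Gower-centered −d²/2 with **all** eigenvalues retained; the squared
distance of a plot to its group centroid is the sum over positive-eigenvalue
axes minus the sum over negative-eigenvalue ("imaginary") axes, floored at
zero (floorings are counted and logged, they are a rounding artifact). The
test statistic is the one-way ANOVA F of those distances; significance
comes from permuting group labels. Group centroids are means, not spatial
medians, matching the distance-to-centroid summaries the pipeline reports.
PERMANOVA uses the McArdle–Anderson hat-matrix partitioning with sequential
sums of squares, so one- and two-factor crossed designs (optionally with
interaction) report R² values that sum to one with the residual.

Permutation p-values are (count + 1)/(n_perm + 1) with seeded generators
and a 1e-12 tie tolerance. When the number of distinct orderings n! does
not exceed n_perm, all of them are enumerated and p = count/n! — this makes
tiny-input p-values exact and reproducible without Monte-Carlo error. The
ANOVA F returns exactly 0 when the between-group sum of squares is at
rounding level (≤ 1e-10 of total scale), so degenerate equal-dispersion
configurations are reported as F = 0 rather than noise ratios.

Tukey HSD on the per-plot distances uses the studentized range
(scipy.stats.tukey_hsd). The compact letter display treats groups as
vertices and non-significant pairs as edges; each maximal clique
(Bron–Kerbosch) receives one letter, which is exactly the "share a letter
iff not significantly different" contract.

## Null models

βNTI uses the taxa-shuffle null: tip labels are permuted across the tree
(equivalently, joint row/column permutations of the patristic matrix), the
same shuffle applied to every plot pair, 999 replicates by default;
βNTI = (observed βMNTD − null mean)/null sd. Pairs with zero null variance
(e.g. star trees, or identical presence sets where βMNTD is identically
zero) are reported as NaN and counted, not silently dropped. The βMNTD
kernels are numba-compiled; null moments are accumulated streaming so
memory stays at O(P²).

RC_bray reassembles both plots of a pair from the regional pool preserving
each plot's richness and total individual count: species are sampled
without replacement with probability proportional to occupancy
(exponential-sort-key sampling), each selected species receives one
individual, and the remainder are multinomial with regional relative
abundance weights. RC = 2·[(#(null < obs) + ½·#(null = obs))/n_null] − 1,
ties at 1e-12. Abundances are rounded to integer counts. The per-plot null
draw is exposed (`raup_crick_null_draw`) so the null can be validated
against itself.

Process classification applies the thresholds exactly: |βNTI| > 2 splits
selection from stochasticity; among stochastic pairs RC > 0.95 is dispersal
limitation, RC < −0.95 homogenizing dispersal, the rest drift. Boundary
values (βNTI = ±2, RC = ±0.95) fall to the stochastic/drift side, since the
selection and dispersal calls require strict exceedance. Summaries
stratify by the disturbance level of both plots; mixed pairs are pooled
into a "cross" stratum rather than discarded. "ΔβNTI"/"Δβ_diss" in the
coupling table are the per-pair values of the pairwise comparison — with
120 plots that yields C(120,2) = 7140 records — not differences between
stratum means.

The Mantel correlogram bins environmental distances with Sturges' rule,
computes per class the sign-flipped Pearson correlation between the focal
distance matrix and the class indicator (positive r = more similar than
average at that distance), permutes the focal matrix for two-sided p, and
applies the progressive Holm correction (class i corrected among the first
i tests). Classes with fewer than two pairs are dropped with a log message.

## Niche width and BiSSE

`P_{i,j}` in Levins' B is normalized per taxon (the share of taxon j's
total found in plot i), which preserves B's interpretation as an effective
plot occupancy in [1, n_plots]; the per-plot alternative would lose the
bounds that justify ranking generalists. Ties at the threshold (B = 9
exactly) are generalists. Niche width is computed on the pooled plot set by
default; a per-zone split can be done by subsetting the table first.

The BiSSE likelihood integrates the standard extinction/partial-likelihood
ODE pair per branch with an adaptive Cash–Karp Runge–Kutta 4(5) at
abs/rel tolerance 1e-10 (chosen so that whole-tree log-likelihoods agree
with an independent closed-form factorization oracle to better than 1e-6
on 200-tip trees), with per-branch renormalization of the D vector and log
compensation. At internal nodes D combines as D_left · D_right · λ_state;
E at a node is the mean of the children's E (identical for ultrametric
trees). Root policies: D-weighted (default), equal weights, equilibrium
transition frequencies, or a fixed state. No survival conditioning or
sampling-fraction correction is applied.

ML fits run in log-rate space after internally rescaling the tree to unit
height (rates and the likelihood transform exactly; the search box
[−9, 4.5] in scaled log units then suits trees of any depth and keeps the
integrator out of pathological high-rate regions). Stage 1 is a
Nelder–Mead search from a Yule-moment heuristic plus perturbed restarts;
stage 2 refines with L-BFGS-B. The reported diagnostic is the
finite-difference gradient norm at the optimum, which is invariant to the
rescaling. The MCMC is coordinate-wise slice sampling (stepping-out width
1.0, shrinkage) over the same scaled log-rates, with independent
exponential priors on the natural-scale rates whose mean defaults to twice
the tree's net-diversification heuristic (echoed in the run metadata).
Shrinkage rejections are counted and reported.

The forward simulator is Gillespie sampling over extant lineages
(speciation, extinction, state transition at the six rates). A run stops
the instant the extant count reaches n_tips plus one further exponential
waiting time, which leaves all terminal branches with positive length;
extinct subtrees are pruned, unifurcations merged, and the stem discarded
so the output is a crown tree. Attempts where the clade dies first are
retried up to `max_attempts` (default 100).

Time rescaling: multiplying branch lengths by c and dividing rates by c
changes the log-likelihood by exactly −(n_tips − 1)·log c, the Jacobian of
the n−1 speciation densities; the tests assert this corrected identity.

## Pipeline and problem sizes

`run_pipeline` derives one seed per stage from the master seed via
`SeedSequence.spawn` in a fixed stage order, so reruns reproduce every
number. The default orchestrated run uses 99 null replicates per null
model and skips MCMC; the analysis drivers use 299 nulls and a 1000-step
chain; the acceptance script uses 999 nulls for the calibration blocks,
a 20-seed gradient-recovery ensemble, and 8 BiSSE recovery replicates at
500 tips. These sizes are the package's own choices for a desk-scale
synthetic study; all counts are configurable.

## Known limitations

* The BiSSE machinery is strictly binary-state (no MuSSE/HiSSE, no
  incomplete-sampling correction) and requires binary trees (polytomies
  are resolved with zero-length branches, flagged).
* RC_bray implements only the abundance-based variant; no
  presence/absence Raup–Crick.
* PERMANOVA supports free permutations only (no strata/blocks); the
  design's park structure is handled upstream by averaging vegetation
  types within parks.
* The Mantel precheck uses whatever distance matrix the caller supplies as
  "environment"; the synthetic campaign has no true edaphic covariates, so
  the drivers use compositional distances as a stand-in.
* β_diss between plots with disjoint taxon sets is 1 by construction even
  under full redundancy, because absent taxa contribute no intensity; the
  index measures realized, not potential, functional overlap.
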