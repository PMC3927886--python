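# Methods

## The dispersal relation and its assumptions

For populations arranged along an (effectively) one-dimensional habitat,
isolation-by-distance theory predicts that at migration–drift–mutation
equilibrium the linearized differentiation between two demes,
F_ST/(1 − F_ST), grows linearly with their separation, with slope

    m = 1 / (4 * De * sigma^2)        [per km]

where De is the effective density (effective population size per km of
habitat) and sigma the standard deviation of the axial parent–offspring
dispersal distance (km per generation). Solving for sigma gives the
package's central estimator, `dispersal.sigma_point`:

    sigma = (4 * De * m)^(-1/2)

Assumptions inherited from the theory: a linear lattice of demes with
equal effective density, a dispersal distribution common to all demes,
discrete generations, and equilibrium. The relation is known to be
robust to the shape (skew, kurtosis) of the dispersal distribution
because only the second moment survives the diffusion approximation,
and to the high mutation rates of microsatellites — provided the
pairwise distances analysed are not so large that mutation, rather than
migration, dominates the divergence (see "Simulator design" below).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| mutation rate mu (mean) | /locus/generation | 7.2e-4 | mean over published fish microsatellite pedigrees |
| mu bounds | — | (1e-5, 9.1e-3) | conservative envelope; lower bound reflects limited power of pedigree studies to see rare mutations |
| Ne infinity threshold | individuals | 1e8 | estimator output above this is treated as a failure (infinite) |
| sampling span L | km | 1361 | along-shore span of the nine-site design; used as the divisor in De = Ne/L |
| De floor | fish/km | 1 | sigma diverges as De -> 0; the floor is the lowest density considered credible and caps the upper sigma bound |
| site pooling threshold | km | 50 | samples closer than this are one population (single-linkage on arc-position) |
| permutations | — | 10 000 (F_ST), 999 (Mantel, HWE, LD) | conventional counts; all permutation p-values use the (1 + hits)/(B + 1) correction |
| BH q | — | 0.05 | FDR level, applied per test family |

The span L is a configuration parameter rather than a measured
quantity: it is back-derived from the published density table
(Ne 4.07e5 / De 298.98 ≈ 1361 km), since no explicit span is printed.
When a coastline polyline is supplied, L is the arc distance between
the extreme sites instead.

## Interval propagation

sigma is strictly decreasing in both De and m, so worst-case interval
arithmetic pairs opposite bounds: sigma_low = sigma(De_high, m_high)
and sigma_high = sigma(max(De_low, floor), m_low). The floor applies
only to the lower density bound. The same worst-case convention is used
for Ne = theta/(4 mu) (lower bound with the upper mutation rate) and
Ne/N (lower bound = Ne_low/N_high). All propagation is monotone: a
wider input interval can never give a narrower output interval, which
the test suite asserts on random instances.

Aggregation of per-sample Ne estimates uses the mean of the finite
values, applied to each column (low, point, high) independently: an
estimator run that failed on the point estimate can still contribute a
finite bound. Negative estimates are invalid (NaN) and estimates above
the infinity threshold are infinite; both are excluded from the mean.
The all-samples-pooled run is excluded because it is not an independent
draw of the metapopulation Ne.

## Estimation choices

* **F-statistics.** Weir–Cockerham (1984) variance components a, b, c
  per allele; multilocus values are ratios of summed components (never
  means of per-locus ratios); negative theta retained. Per-population
  F_IS is reported both as the variance-component f (default, matching
  the classical FSTAT output) and as 1 − Ho/He.
* **Missing data.** Pairwise-complete per locus: an individual missing
  at one locus still contributes everywhere else. A locus with no
  genotyped individuals in a population is flagged absent, not zero.
* **Allelic richness.** Hurlbert rarefaction in units of genes (2g),
  with g defaulting to the smallest per-population genotyped count at
  the locus; computed in log-space to avoid binomial overflow.
* **Permutation schemes.** F_ST: whole multilocus genotypes permuted
  among populations (pairwise tests permute within the pair only).
  HWE: alleles permuted within population and locus, statistic F_IS,
  two-sided on |f|. Genotypic disequilibrium: one locus's genotypes
  permuted among individuals within the population, statistic
  two-locus G. Every routine takes an explicit seed.
* **RMA regression.** slope = sign(r) · sd(y)/sd(x) over the n(n−1)/2
  site pairs; always at least as steep as OLS. The slope CI is a
  delete-one-site jackknife normal interval by default (a site
  bootstrap percentile interval is available). Label permutation — the
  Mantel scheme — cannot bracket a nonzero slope, so it supplies only
  the p-value; resampling sites supplies the CI.
* **Distances.** Haversine on a 6371-km sphere; along-shore distances
  by projecting sites onto a south-to-north coastline polyline
  (equirectangular per-segment projection, adequate at coastal scales)
  and differencing arc positions. A site farther than 100 km from the
  polyline triggers a warning and a great-circle fallback for its
  pairs.
* **Multiple testing.** Benjamini–Hochberg step-up via
  `scipy.stats.false_discovery_control`, applied separately per family
  (pairwise F_ST, HWE, disequilibrium).

## Simulator design

`simdata.simulate` is a forward-time Wright–Fisher stepping-stone
model: each generation, every offspring in a deme draws a source deme
from the migration kernel, two parents uniformly with replacement from
that deme, and one allele per parent; transmitted alleles mutate ±1
repeat with probability mu (stepwise mutation, repeat range [5, 60]
with reflection). Boundaries reflect (out-of-range kernel mass folds
back inward), preserving the equal-density assumption. Forward time
was chosen over the coalescent for transparency: every assumption of
the dispersal relation is visible in ~40 lines of update rule.

Default example configuration: 60 demes at 20-km spacing, 50 diploids
per deme (De = 2.5 fish/km), nearest-neighbour rate 0.1 per side
(sigma = 8.94 km), eight loci at mu = 5e-4, 3000 burn-in generations.
The nine sampled demes sit in the middle of the lattice with pairwise
distances of 20–200 km. That window is deliberate: the linearized-F_ST
regression is linear in distance only between roughly sigma and
sigma/(2*sqrt(2*mu)) (~140 km here); at larger separations stepwise
mutation flattens the curve and the fitted slope underestimates the
theoretical one — a real feature of the method, visible in the
simulator if one widens the window. Sample sizes (30–50) echo the
field design while staying within the deme size.

Problem sizes throughout the test suite (deme counts, sample sizes,
permutation counts, 20 recovery seeds) are chosen so a full run
completes in a few minutes on one core while keeping Monte-Carlo error
well inside the asserted bands.

What the generator emulates: the spatial structure, drift, stepwise
mutation and missing-at-random genotypes the theory assumes. What it
does not: advective (asymmetric) currents, temporally fluctuating
density, overlapping generations and age structure, selection, and
null alleles. Passing the recovery tests therefore shows the inference
chain is correct *under the model's assumptions*; it cannot show those
assumptions hold for any particular coastline.

## Degenerate inputs and numerical notes

* F_ST = 1 cannot be linearized (raises); monomorphic loci yield NaN
  statistics and skipped tests rather than zeros.
* A non-positive fitted slope means no isolation-by-distance signal:
  sigma is undefined and the CLI exits with a distinct code (3).
* De_high ≤ 0 leaves the whole sigma interval undefined.
* Jackknife CIs require ≥ 4 sites; below that the CI is flagged NaN.
* Report floats are serialized at 12 significant digits; identical
  config + seed gives byte-identical reports.

## Known limitations

* The two Ne estimator families disagree by two orders of magnitude in
  the packaged example (historical coalescent vs contemporary
  estimators); the package propagates both rather than adjudicating.
* The published upper confidence bound of the coalescent-derived
  density reflects a rounded intermediate (Ne printed as 4.00e5 where
  the exact quotient is 4.09e5); the reproduction mode follows the
  printed density row and also reports the exact-quotient density.
* The census CI uses count ± 1.96·SE propagated linearly; the
  published lower census bound is slightly asymmetric and is matched
  only approximately.
* Reserve geometry is collapsed to intervals on a shared coastline
  polyline; true polygon-edge geodesics and depth-contour extraction
  are out of scope.
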