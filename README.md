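# coastibd

Per-generation dispersal distance from isolation-by-distance genetics
along one-dimensional coastlines, and marine reserve network
connectivity evaluated against it.

Marine reserve networks only function as networks when the reserves are
connected by larval dispersal, but the scale of dispersal is rarely
measured. For species living along an essentially one-dimensional
habitat (a coastline), population-genetic theory links the strength of
isolation by distance to the dispersal kernel: if *m* is the slope of
the regression of linearized genetic differentiation
*F*<sub>ST</sub>/(1 − *F*<sub>ST</sub>) on along-shore distance, and
*D*<sub>e</sub> is the effective density (effective population size per
km of coastline, *D*<sub>e</sub> = *N*<sub>e</sub>/*L*), then the axial
standard deviation of the per-generation dispersal kernel is

σ = (4 *D*<sub>e</sub> *m*)<sup>−1/2</sup>.

`coastibd` implements the full inference chain for microsatellite data
and the downstream reserve evaluation:

* **genotypes / popstats** — GENEPOP I/O, Nei heterozygosities, Hurlbert
  rarefied allelic richness, Weir–Cockerham *F*-statistics with
  permutation tests (θ and log-likelihood *G*), Hardy–Weinberg and
  genotypic-disequilibrium permutation tests, Benjamini–Hochberg FDR
  control, and pooling of sampling sites within 50 km.
* **ibd** — along-shore distances on a coastline polyline (great-circle
  fallback), *F*<sub>ST</sub> linearization, Mantel permutation test,
  reduced major axis regression with jackknife/bootstrap slope CIs, and
  drift–migration equilibrium diagnostics (subrange slopes,
  latitude–diversity correlations).
* **dispersal** — θ = 4 *N*<sub>e</sub>μ conversion with mutation-rate
  bounds, mean-of-finite *N*<sub>e</sub> aggregation, effective density,
  the σ point estimate and worst-case interval propagation (with a
  density floor so the upper σ bound stays finite), SCUBA transect
  census extrapolation, REEF abundance indices, and
  *N*<sub>e</sub>/*N*.
* **reserves** — reserve inclusion rules (outer coast, shallow habitat,
  full protection), edge-to-edge 1D spacing, network gaps, and
  connectivity classes (within σ / within its CI / isolated).
* **simdata** — a forward Wright–Fisher stepping-stone simulator with
  stepwise-mutating microsatellites and known σ and *D*<sub>e</sub>,
  used for end-to-end parameter-recovery tests; plus the packaged study
  tables for the black rockfish (*Sebastes melanops*) analysis the
  package reproduces.
* **pipeline / cli** — one-command orchestration with a versioned JSON
  report and a `coastibd` command-line tool
  (`stats | fst | hwe | ibd | dispersal | reserves | simulate | run`).

## Worked example

The packaged effective-size table (per-sample coalescent θ, linkage-
disequilibrium and ABC *N*<sub>e</sub> estimates for nine black rockfish
populations spanning ~1361 km of the Oregon–British Columbia coast),
combined with the published IBD slope m = 1.25×10⁻⁵ per km
(95% CI 7.35×10⁻⁶ – 2.15×10⁻⁵):

```python
from coastibd.pipeline import paper_mode

r = paper_mode()
s, o = r["sigma"]["migrate"], r["sigma"]["onesamp"]
print(f"coalescent: sigma = {s.point:.1f} km/gen (95% CI {s.low:.1f}-{s.high:.1f})")
print(f"ABC:        sigma = {o.point:.1f} km/gen (95% CI {o.low:.1f}-{o.high:.1f})")
```

prints

```
coalescent: sigma = 101.5 km/gen (95% CI 6.3-184.4)
ABC:        sigma = 8.2 km/gen (95% CI 5.8-125.0)
```

The two methods disagree on the point estimate (the coalescent estimator sees a
historical, much smaller *N*<sub>e</sub>; the ABC estimator a
contemporary, larger one) but their intervals overlap broadly: mean
dispersal is somewhere between ~6 and ~184 km per generation. Against a
census size of 2.85×10⁷ fish extrapolated from dive transects, the
implied *N*<sub>e</sub>/*N* is 9.2×10⁻⁵ (coalescent) to 0.014 (ABC).
A reserve whose nearest neighbour is within ~100 km is then plausibly
connected by average dispersal within one generation, and a 314-km gap
between two national networks takes roughly 1.7–50 generations to
bridge.

The same chain from the shell:

```sh
coastibd dispersal                 # paper-mode JSON report
coastibd simulate --seed 7         # synthetic stepping-stone dataset
coastibd reserves demo.csv --sigma 6.3 101 184
```

## Synthetic validation

`coastibd.simdata.simulate` runs a 60-deme stepping-stone lattice
(20 km spacing, 50 diploids per deme, nearest-neighbour migration 0.1
per side → σ = 8.94 km, eight stepwise-mutating loci at μ = 5×10⁻⁴,
3000 burn-in generations). The test suite regresses linearized
*F*<sub>ST</sub> on distance for twenty independent runs and checks that
the mean fitted slope is within 50% of 1/(4 *D*<sub>e</sub> σ²) and the
recovered σ within a factor of two of the truth — the desk-scale
analogue of the empirical inference. See `docs/methods.md` for the
model, its assumptions, and what these tests do and do not establish.
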