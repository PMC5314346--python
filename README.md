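# neutralscape

Spatially explicit neutral biodiversity theory: analytic species abundance
distributions on continuous landscapes, exact lattice simulators (forward and
backward in time), subsampling theory for census data, and a calibration
pipeline that turns continental-scale survey counts into bounds on total
species richness.

## The problem

In a neutral community all species are demographically identical: individuals
die at random and are replaced by offspring of their neighbours, and with a
small probability ν each birth founds a new species.  For a *well-mixed*
community of J individuals the stationary species abundance distribution
(SAD) is Fisher's log-series,

    n(m) = θ xᵐ / m,      x = 1 − ν,   θ = η ν J / (1 − ν),

with species richness SR = θ ln(1/ν) and θ (Fisher's α) equal to the expected
number of singleton species.  Real communities are not well mixed: offspring
recruit near their parents (recruitment length σ, in units of the mean
inter-individual spacing √(A/J)), conspecifics clump, and the per-capita
chance that a birth-death event is *inter*specific falls logarithmically with
abundance, I(m) = m / (1 + c ln m).  The stationary solution of the resulting
drift-diffusion description is

    n(m) = (A/m) (1 + c ln m) x^{g(m)},      g(m) = m (1 + c (ln m − 1)),

with A fixed by Σ m·n(m) = J and a single clustering coefficient

    c = 1 / (a (σ² − 1) + b),      a = 3.22,  b = 2.58,

calibrated against simulation.  With c → 0 (σ → ∞) every formula collapses
back to Fisher's log-series.  Spatial clustering *raises* diversity: the SAD
gains a slowly decaying correction and the exponential cutoff M — the
abundance scale of the hyperdominant species, solving ν′ g(M) = 1 — moves,
so SR grows as σ shrinks.  A species of abundance m occupies an expected
squared range ξ² = c₁ σ² m, and ξ evaluated at M is the correlation length of
the whole community.

Because a census samples a tiny fraction R of the community, the package also
carries the SAD through binomial thinning, n(s) = Σₘ n(m) Binom(s; m, R),
numerically stable at R ~ 10⁻⁶ and m ~ 10¹⁰.

Two simulators provide ground truth on lattices: an exact forward Moran
process and a backward-in-time coalescence sampler that draws stationary
samples directly (lineages jump by the shared recruitment kernel, merge on
common parenthood, and resolve at speciation events).  Their agreement —
verified by a chi-squared test in the suite — is the package's central
correctness check.

## Worked example: bounding Amazonian tree richness

A basin-wide census of 553,949 trees (of J = 4.3 × 10¹¹, sampling ratio
R ≈ 1.3 × 10⁻⁶) recorded 4962 species, and occupancy reports for two
hyperdominant species (abundance 3.7 × 10⁹ on 7.4% of the basin, 5 × 10⁹ on
48%) constrain σ through the range law.  The pipeline intersects the
sample-richness contours S(ν, σ) = 4962 and 5360 (an 8% allowance for the
spatial correlation of the sampled plots) with the σ interval from the range
constraints, then sweeps the region for extrema:

```bash
neutralscape amazon --config examples/amazon.yaml -o report.json
```

prints

```
sigma: 11.2-24.6 m | SR 12874-15796 | singletons 474-735
```

i.e. recruitment lengths of roughly 11–25 m, a metacommunity of
~12,900–15,800 tree species, and ~470–740 species expected to be represented
by a single tree in the entire basin — far below the ~15,000 species and
~750 singletons the well-mixed (σ → ∞) calibration would claim at matched
sample richness.  `report.json` carries every extremum with the (ν, σ, c₁)
at which it is attained plus a c₁ ∈ {0.8, 1.0, 1.2} sensitivity band.

The same machinery is available programmatically:

```python
import neutralscape as ns

p = ns.ModelParams(J=4.3e11, nu=1.3e-9, sigma=3.0)
sad = ns.spatial_sad(p)                  # metacommunity SAD
sad.richness, sad.singletons             # (14878.17..., 559.00...)
ns.sample_sad(sad, ns.SampleSpec(1.3e-6))  # expected census SAD
```

Other CLI commands: `neutralscape sad`, `sample-sad`, `simulate`,
`coalesce`, `fit-c`, `fit-ab` (see `--help`).

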