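# Methods

## Model structure and assumptions

The simulator is a deterministic, well-mixed compartment model of an
*Aedes aegypti* population structured by life stage (juvenile, adult male,
adult female) and by two-locus genotype. The female-killing (FK) locus
carries alleles K/k and the anti-pathogen (AP) locus A/a; the loci are
autosomal, unlinked and segregate independently, giving nine genotypes.
Eggs are implicit: "birth" is the production of viable larvae, and the
genotype-i larval production rate combines random mating with exact
Mendelian inheritance,

    B_i = w_i λ Σ_m Σ_n F_m (M_n / Σ_k M_k) Pr(i | m, n).

Mothers contribute by density and fathers by frequency, so female
reproduction is not male-limited; when no males are present, B = 0. This is
the standard reading of random mating with female-limited reproduction and
makes the zero-male limit well defined. Released, tetracycline-reared
females are assumed to mate and reproduce at the same rate λ as wild
females.

FK lethality acts at adult emergence: the female emergence flux is
multiplied by a 0/1 viability coefficient γ_i (zero for any K carrier).
Released FK-carrying females bypass this because they are reared with the
transgene repressed; since γ = 0 genotypes can never enter the female pool
by emergence, genotype alone distinguishes released females from native
ones, and "native female" metrics simply sum over the three kk genotypes.

Juvenile mortality has a density-independent part μ_J and a
density-dependent part α J^(β−1) acting on the *total* juvenile density
(larval competition is genotype-blind). Fitness costs of the transgenes
reduce egg-to-larva viability only: additive within a locus (heterozygotes
pay half) and multiplicative across loci.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| μ_J | density-independent juvenile mortality | 0.03 | day⁻¹ |
| μ_M | adult male mortality | 0.28 | day⁻¹ |
| μ_F | adult female mortality | 0.10 | day⁻¹ |
| λ | larval production per female | 8 | day⁻¹ |
| ν | emergence rate | 0.14 | day⁻¹ |
| α | density-dependence scale | 2×10⁻⁴ | — |
| β | density-dependence exponent | 3.4 | — |
| c_K, c_A | homozygote egg-viability costs | 0 | — |

β controls how fast the population returns to equilibrium after
perturbation; the default 3.4 is strong regulation, under which male-only
releases at moderate ratios cannot eliminate the population and instead
hold it at an intermediate plateau. Density units are abstract — every
reported density is relative to the pre-release total adult female density,
so the absolute scale of α never matters on its own.

## Equilibrium and release forcing

The wild-type equilibrium is computed analytically
(Ĵ = [(λν/(2μ_F) − μ_J − ν)/α]^(1/(β−1)), M̂ = νĴ/(2μ_M), F̂ = νĴ/(2μ_F));
a positive root exists iff λν/(2μ_F) > μ_J + ν, otherwise the constructor
signals that the population is not self-sustaining. Releases are anchored
to the *analytic* M̂, never to a simulated value, so the forcing is exactly
reproducible and independent of solver settings. A release of weekly ratio
r is applied as a constant daily rate r·M̂/7 over [start, start+T) —
continuous trickle, not weekly pulses; bi-sex releases split the same total
evenly between the sexes (r·M̂/14 each). The default release start is day
30. Optional wild-type juvenile immigration adds ι·Ĵ per day to the kkaa
juvenile compartment, subject to the same density-dependent mortality as
residents.

## Numerical choices

- The inheritance tensor is built once in exact rational arithmetic
  (per-locus transmission convolution) and converted to floats; every entry
  is a dyadic rational, so the conversion is lossless.
- Integration uses `scipy.integrate.solve_ivp` with LSODA, rtol 1e−8,
  atol 1e−10. Trajectories are inspected over six or more decades on log
  axes, so loose tolerances would distort the small-density tails.
- The integrator is restarted at each forcing discontinuity and the forcing
  is held exactly constant within a segment, so the release window
  boundaries never fall inside one solver step. Zero-rate schedules add no
  restart points, which keeps an r = 0 run bit-identical to the no-release
  control.
- Total juvenile density is clamped at zero before the non-integer power
  β − 1 = 2.4; female/male densities are clamped at zero inside the mating
  sum. Output states more negative than −1e−6 abort the run (tolerated
  solver undershoot is ~atol).
- Output is sampled daily by default: the experiments span hundreds to
  thousands of days and the argmin/threshold metrics need day resolution.

## Outcome metrics

- *Competent vector*: an adult female carrying no AP allele (refractoriness
  treated as dominant). The model's own accounting requires dominance —
  replacement drives competent density to negligible levels while kkAa
  females persist — but dominance of refractoriness is an assumption, so a
  recessive mode (only AA refractory) is provided as a sensitivity switch.
- *Recovery* is native female density returning to within 1 % of baseline;
  the approach is asymptotic, so an exact return never occurs. If recovery
  does not occur within the horizon the metric reports the horizon-end
  value, flagged as not recovered.
- *Allele extinction* is the frequency falling below 1e−6 and staying there
  to the horizon; deterministic densities never reach exact zero.
- Allele frequencies are reported for the juvenile pool, where they are not
  inflated by the released adults themselves.
- Ties in the native-female minimum break to the earliest day.

## Experiment designs

The bundled catalogue covers: the four-ratio year-long male-only comparison
of R&R vs FK-only strains; the duration comparison at r = 2; a fixed-budget
sweep at 80 ratio-days (r·T constant — equal effort because releases are
constant-rate; endpoints r = 4 × 20 d and r = 0.16 × 500 d, with 15
log-spaced durations in between, a grid density chosen here since only the
endpoints pin the design); the sex-mode comparison at r = 1, T = 100; AP
fitness costs c_A ∈ {0, 0.1, 0.2}; female-only durations 100–120 d at
r = 1; and immigration fractions {0, 0.001, 0.01, 0.05} of Ĵ per day.
Horizons are per-design (1 500–6 000 d; 4 000 d for the fitness-cost design
so that the costly AP allele's slow post-release purge completes) — long
enough for every metric to settle at daily resolution while keeping a full
catalogue run to seconds.

## What the tests do and do not show

All experiments run on model-generated data; there is no empirical input.
Passing tests show that the implementation reproduces the model's internal
logic — exact inheritance, the analytic equilibrium, conservation
properties, and the qualitative orderings across release designs
(deeper suppression at higher ratios; longer-gentler releases leaving fewer
competent vectors at equal effort for male-only releases; female-containing
releases outperforming male-only after an onset transient of roughly two
months during which female-only forcing leaves wild females untouched;
costly AP alleles peaking lower and purging sooner). They say nothing
about real populations: the model omits stochasticity, spatial structure,
seasonality, mating competitiveness differences and an explicit egg stage.

## Known limitations

- The total-density equivalence of R&R and FK releases holds only without
  AP fitness costs and is verified numerically to ~1e−8 relative, limited
  by solver tolerance, not by the mathematics.
- The suppression plateau during releases is approached on the slow
  timescale of the rising FK allele frequency: a 120-day release ends ~6 %
  above the settled plateau that 240- and 360-day releases reach (their
  end-of-release levels agree to 0.1 %).
- Near-extinction scenarios (female-containing releases at r = 1 beyond
  ~120 days) drive densities to numerically tiny values where "extinction"
  is a modelling convention, not an ODE outcome.
- With immigration, the no-release equilibrium exceeds the analytic Ĵ
  slightly (the influx is a new source term); baselines are always taken
  from the immigration-free equilibrium, matching how the designs are
  framed.
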