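# Methods

## Model

A period life table is treated as a complete description of a mortality
regime on integer ages `0..ω` (default ω = 100, matching the 101-age grid
the matrix exports use; configurable). Intervals are half-open `[x, x+1)`;
"age x" means completed age x. The terminal age is absorbing: `q_ω = 1`.
Closure follows the standard single-year conventions:

- `q_x = 1 − l_{x+1}/l_x`, `l` from `q` by cumulative survival;
- `d_x = l_x − l_{x+1}`, `d_ω = l_ω`, so `Σ d_x = l_0`;
- person-years by the midpoint rule `L_x = (l_x + l_{x+1})/2` with
  `L_ω = a_ω·l_ω` (`a_ω = 0.5` by default and configurable, since `e_ω`
  depends on it; single-year intervals make `a_x = 0.5` the standard
  approximation everywhere else);
- `e_x = (Σ_{y≥x} L_y)/l_x`.

When a file supplies its own `e_x` the supplied column wins (published
expectancies rest on finer within-year detail than the midpoint rule) and a
disagreement beyond 0.5 years with the value derived from `l` is surfaced
as a warning.

The **stationary counterpart** of an observed population is built from its
life table with zero growth and the observed total. Its age weights are
`l_x` by default ("survivorship" weighting); `L_x` ("person-years") is
available as an option. The survivorship choice is deliberate: under it the
discrete stationary identities are *exact* on the integer grid. The
projected remaining-years distribution of an `l`-weighted population
telescopes back to `l` itself (`Σ_a l_a·d_{a+y}/l_a = Σ_a d_{a+y} = l_y`),
so its age and remaining-years distributions coincide age-for-age, the
death matrix has equal row and column sums and exactly constant
anti-diagonals, the Stationarity Gap is zero to machine precision and the
Lifespan Parity Ratio is exactly 1. Under `L_x` weighting the same
identities hold only to O(q_x) per age (LPR ≈ 1.01 for human-like tables),
which blurs the very benchmark the pair is meant to provide.

The **cohort death matrix** projects every living cohort to extinction
holding the period table fixed: `m[a, y] = n_a (l_{a+y} − l_{a+y+1})/l_a`
for `a + y ≤ ω`. Deaths in year y after the reference time get
thanatological age y (completed years), keeping both axes on the same
integer grid. Row sums reproduce the cohort counts identically (the inner
sum telescopes), so total deaths D equal the population N; column sums are
the remaining-years distribution `d(x)`. Migration and mortality
improvement within the projection window are out of scope by construction.

## Time conventions and estimators

Mean age uses completed years (a midpoint variant adds 0.5). Mean years
remaining has three estimators:

- `expectancy`: `Σ n_x e_x / N` — the published-table route;
- `matrix`: the mean of `d(x)` — completed years;
- `survivorship`: `Σ l_x e_x / Σ l_x` — the stationary population's own
  value, independent of `n`.

Under the midpoint rule the matrix estimator equals the expectancy
estimator minus exactly 0.5 years for *any* population — the completed-years
vs exact-age offset, nothing more. The LPR therefore defaults to the matrix
estimator so numerator and denominator share one convention and
stationarity lands exactly on 1.0; reports that quote R̄ itself use the
expectancy estimator, the convention of published comparisons. The two
statements ("R̄ = 44-ish by expectancy" and "LPR via matrix") differ only by
that constant half-year.

The Stationarity Gap is exposed in both readings discussed in the
literature: `remaining_years_gap` (age vs remaining-years distribution of
one population — the dissimilarity-index definition) and `structural_gap`
(observed vs stationary age structure). Both vanish exactly at stationarity
but measure different departures from it; the metric records carry the
first, and callers wanting the second have it by name.

The Terminal Dependency Ratio multiplies counts by the five-year death
probability `1 − Π_{i=0..4}(1 − q_{x+i})` with `q ≡ 1` beyond ω (the top
age absorbs), over the population aged 20–64. Note the denominator is
deliberately narrower than the OADR's 15–64 working-age band; both follow
their respective printed definitions. OADR is a raw ratio internally with a
×100 display convention in table output.

SO and NSA are plain first differences over a user-chosen interval (default
50 years): SO = ΔR̄ (expectancy estimator), NSA = ΔĀ − SO, so SO + NSA = ΔĀ
holds to rounding. Between two stationary populations NSA is identically 0
regardless of how different the two life tables are, because Ā and R̄ move
together at stationarity — the stationary column's signature.

## Typology

Stages partition positive LPR with upper-inclusive boundaries exactly as
stated (no epsilon snapping): (1.75, ∞), (1.10, 1.75], (0.90, 1.10],
(0.85, 0.90], (0, 0.85]. Crossover detection returns the first grid year
where Ā ≥ R̄ after a year with Ā < R̄, with the linear root of Ā − R̄
between the bracketing years; exact grid equality is a degenerate crossover
at that year (a stationary series reports its first year, flagged).
SO×NSA quadrant labels follow the four open quadrants; exact zeros get a
dedicated `stationary-change` boundary label rather than an arbitrary
assignment. Stage summaries use medians and 25th/75th percentiles with
linear interpolation (the common type-7 rule; no alternative is asserted).
A `demographic vortex` flag (Age Dominance at every supplied time point) is
provided as a descriptive extrapolation of the qualitative endpoint; it is
a flag on supplied history, not a projection, and nothing downstream
depends on it.

## Synthetic data

The generator emulates what the readers expect from real single-age data:

- **Mortality**: Gompertz–Makeham hazard `μ(x) = λ + α e^{βx}`, with
  `q_x = 1 − exp(−∫_x^{x+1} μ)` in closed form. Two knobs (background λ,
  senescence α, β) span e(0) ≈ 45–86 years, covering the range real period
  tables occupy; the test family sweeps 24 such regimes.
- **Age structure**: Lotka stable populations `n_x ∝ e^{−rx} w_x` with the
  same weighting switch as the stationary builder, so r = 0 reduces to the
  stationary counterpart exactly. r in ±0.03/yr brackets observed national
  growth rates.
- **Noise**: optional i.i.d. multiplicative log-normal perturbation per age
  (preserves non-negativity), seeded and reproducible; generation without
  noise is deterministic.
- **Fixtures**: writers emit the same CSV dialect the readers parse, so
  file round trips are part of the test surface.

What the generator does *not* emulate: cohort-specific history (baby booms,
wars, migration waves), heaping and enumeration error, mortality shocks,
and fertility dynamics (structures are imposed, not evolved). Passing tests
therefore demonstrate the correctness of the machinery and the exactness of
the stationary benchmarks, not calibration to any real country; analyses of
real populations inherit whatever biases the supplied life tables and
counts carry.

## Numerical choices and edge cases

- Survivorship-weighted stationarity makes the identity suite exact; all
  stationarity tolerances (LPR within 1e-3, SG ≤ 0.01, |Ā − R̄| ≤ 0.5,
  matrix identities at 1e-9 relative) are then honest upper bounds rather
  than tuned slack.
- A cohort at an age with `l_x = 0` has no conditional death distribution;
  the matrix builder refuses it by name rather than renormalising.
- Zero-total distributions, empty denominators (no 15–64 or 20–64
  population), equal timestamps in SO/NSA, non-finite or non-positive LPR
  all raise typed errors; the CLI maps them to stable exit codes.
- Population ages above ω are folded into ω (the matrix needs a hard top
  age); counts may be in any unit (a scale factor is a reader option) and
  every reported metric except raw matrix/bar exports is scale-invariant.
- Problem sizes: the default grid is 101 ages; test suites sweep 24
  mortality regimes, 13-point growth grids and property-test batches, and
  the whole suite plus the acceptance script run in seconds on one core.
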