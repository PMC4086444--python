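# Methods

## Problem and model

geodeid treats spatial de-identification as a transportation-style linear
program.  The universe is a set *A* of areal units (postal codes),
each with a centroid and a resident population `n_i`; `N = Σ n_i`.  A
cohort of `s` patients is to be published with area-level locations.  The
decision variables `P_ij` are the probabilities that a patient truly in
area *i* is reported in area *j*; rows are stochastic (`Σ_j P_ij = 1`,
self-transition allowed).  The objective is the population-weighted
expected displacement `Σ_ij (n_i/N) d_ij P_ij` in meters — the
information-loss measure — where `d_ij` is the great-circle distance
between centroids.

The privacy constraint bounds, for every pair (i, j), the probability
that a record reported in *j* is traced to a specific individual of *i*:

    r_ij = min(s/n_i, 1) · (n_i P_ij) / (Σ_k n_k P_kj) ≤ ε.

`s/n_i` is the worst-case share of area *i*'s residents who are cohort
members, capped at 1 because an area cannot host more patients than
residents.  Clearing the denominator turns each bound into the linear
row `Σ_k (n_k/N) P_kj − ν_i P_ij ≥ 0` with `ν_i = min(s, n_i)/(N ε)`
(the **revised** variant).  Dropping the cap gives `ν = s/(N ε)` — the
original worst-case (**wcmb**) variant, kept for comparison: it is sound
but infeasible whenever small areas cannot absorb the fictitious
exposure of all `s` patients.  Since `ν(revised) ≤ ν(wcmb)`, every
revised constraint is implied by the worst-case one, so the revised
feasible region contains the worst-case region and its optimum is never
more costly.

## Constraint redundancy

Rewriting a risk row as `Σ_{k≠i} (n_k/N) P_kj + g(n_i) P_ij ≥ 0` with

    g(n) = (n/N)(1 − 1/ε)   for n ≤ s,
    g(n) = (n − s/ε)/N      for n > s,

every coefficient is non-negative when `g(n_i) ≥ 0`, i.e. `n_i ≥ s/ε`,
and the row follows from `P ≥ 0`.  `g` is continuous, minimal at
`n = s` with value `(s/N)(1 − 1/ε)`, and crosses zero at `n = s/ε`.
`build_lp(prune=True)` (the default) drops those rows; pruned and
unpruned instances are verified to produce identical statuses and
objectives.  The pruning test `n_i ≥ s/ε` is used for both variants —
it is exact for the revised model when ε < 1 and always sufficient for
the worst-case model.  (For ε ≥ 1 the revised rows with `n_i ≤ s` are
also redundant; that regime is impractical — the risk ceiling exceeds
certainty — and the solver handles the few extra rows at no cost.)

## Sparsification and problem size

Full transitions need `|A|²` variables (137,827,600 at 11,740 areas) and
`|A|(1 + |A|)` constraints, counting one row-sum equality per origin and
one risk inequality per variable, with non-negativity as variable
bounds.  Restricting each origin to its *k* nearest areas — self
included, since `d_ii = 0` makes the origin trivially nearest, and ties
broken by area id for reproducible builds — reduces this to `|A|·k`
variables and `|A|(1 + k)` constraints (117,400 / 129,140 at k = 10).
The column sum in a risk row then runs only over origins whose neighbor
set contains *j*: other `P_kj` do not exist as variables, which is the
only consistent sparse reading.  Distances use the Haversine formula on
a sphere of radius 6,371,000 m; ellipsoidal effects are ignored.

## Solving, tolerances, degeneracy

`solve()` wraps scipy's HiGHS interface (dual simplex by default;
interior point available, and used as the second backend in oracle
cross-checks).  Infeasibility is a reported status, not an error — it is
a scientifically meaningful outcome.  The two methods have
complementary failure modes (dual simplex can stall with an "unknown"
status on instances whose infeasibility interior point certifies
immediately), so a numeric failure triggers one automatic retry on the
alternate method before the status is reported.  On an optimal solve the objective
is recomputed as `c·x` independently of the solver's own value.
Post-processing clips negatives within 1e−6, zeroes entries below 1e−9,
and renormalizes rows: the audited risk ratio is scale-invariant within
a column, so a stray 1e−13 solver artifact in an otherwise unused
destination would otherwise masquerade as a high-risk pair.  Degenerate
optima may differ in `P` between backends or runs; only the objective is
contract-bound.  The audit recomputes `r_ij` from first principles
rather than trusting LP feasibility, so it catches tolerance violations
and pruning bugs; destinations receiving no transition mass are skipped
(a 0/0 has no risk interpretation and an unused destination poses no
risk), and the audit passes iff the maximum audited risk is ≤ ε + 1e−6.

## Relocation

Given the solved matrix, the `s_i` patients of each origin are assigned
destination counts drawn from `Multinomial(s_i, {P_ij})`, then matched
to individual patients by a uniform shuffle — patients within an origin
are exchangeable.  A single root seed spawns one substream per origin,
keyed by a hash of the area id, so adding or removing an origin leaves
all other origins' draws unchanged and every run is reproducible from
its seed.

## Synthetic cities

The generator emulates the small-area structure of an amalgamated
mid-size city: a few hundred to a few thousand postal-code-scale areas,
city-wide median population 10, a long right tail, and ~99% of areas
smaller than a few-hundred-patient cohort.  Two components:

* **Core** (75% of areas): centroids uniform in the central half of the
  bounding box; populations `1 + ⌊LogNormal(μ_core, 1.3)⌋` with `μ_core`
  calibrated in closed form so the *city-wide* sample median hits the
  target.
* **Villages** (25%): tight Gaussian clusters (~70 areas each, spatial
  σ ≈ 2% of the half-extent) on an outer ring, populations
  `1 + ⌊LogNormal(ln 2, 1.0)⌋` (median ≈ 2.5, mean ≈ 4).

The villages are structural, not decorative.  A worst-case risk row
forces `Σ_k n_k P_kj ≥ (s/ε) P_ij`, so an origin is only starved when
*every* destination it can reach draws on surroundings whose total
population is too small to commit `s/ε` of coverage mass.  With
spatially independent populations each nearest-30 window holds roughly
30 × mean ≈ 600 people ≫ s, and even a steep smooth density gradient
leaves every window a richer inward direction — the worst-case model
then stays feasible no matter how small individual areas are.  Only an
isolated cluster larger than the neighbor-set size *k* with mean
population below `s/k` (≈ 7.5 at s = 224, k = 30) reproduces the
small-area failure mode, which is precisely the geography of outlying
rural villages.  Patient origins are drawn by a multivariate
hypergeometric over area populations (sampling individuals without
replacement), so per-origin counts can never exceed populations.

What the generator does **not** emulate: real postal-code adjacency and
shape, road-network rather than great-circle proximity, within-city
correlation between population and cohort membership beyond
proportionality, and multiple cities or nested geographies.  Passing
tests therefore demonstrate the method's behaviour on the *statistical*
structure of small-area urban data, not on any particular real geography.

## Study sizes and defaults

| parameter | default | why |
|---|---|---|
| ε | 0.2 | common "very small risk" working threshold for expert-determination disclosure |
| k | 30 | smallest neighbor set that kept the revised model feasible at ε = 0.2 in the demonstration regime; k = 10 is the cheap alternative |
| s | 224 | cohort size of the demonstration study (≈ 5% of a month's emergency-department visits) |
| city size | 1,000 areas | large enough to contain isolated villages and a dense core; solves in seconds |
| sweep city | 200 areas | five-threshold ε sweep at interactive speed |

Test and acceptance runs use 150–1,000-area cities: the LP at 1,000
areas and k = 30 has 30,000 variables and ≤ 31,000 constraints and
solves in a few seconds with dual simplex.

## Known limitations

* Only the spatial attribute is transformed; ages, dates and other
  quasi-identifiers are out of scope.
* The destination universe equals the origin universe; publishing into a
  coarser or different geography is not supported.
* Transition counts are expectations under the multinomial draw; no
  integer post-processing is applied.
* At national scale (10⁵–10⁶ areas) the dense distance matrix and the
  one-shot LP would both need replacing (spatial indexing,
  decomposition); this implementation targets metropolitan problems.
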