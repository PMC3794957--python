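# Methods

## Supply process

Each donor's daily recoverable food is modelled as a zero-inflated
peaks-over-threshold process: with probability `rate` a donation occurs, and
its size is Generalized Pareto with threshold 0, scale σ (lbs) and shape ξ.
Two uniforms drive each donor-day — the first decides occurrence
(`u1 < rate`), the second feeds the GPD inverse CDF — so a draw always
consumes exactly two stream values and substreams stay aligned whatever the
outcome. Days and donors are independent: the donation records this model was
built for show no exploitable autocorrelation, so no time-series structure is
imposed.

The shipped category parameters (`DEFAULT_CATEGORY_PARAMS`) are MLE fits to a
year of food-bank donation records, pooled (`all`) and per category. Grocers
donate on ~30% of days with a conditional mean of ~369 lbs; farms donate on
~2% of days but average ~6,900 lbs. Shape values below 1 everywhere keep
conditional means finite (σ/(1−ξ)); the `individuals` row's printed mean
disagrees with its own scale/shape at the ~10⁻⁴ level (parameter rounding in
the source fit), so consistency checks use a 0.5% tolerance.

`fit_gpd_mle` optimises the GPD log-likelihood over (log σ, ξ) by Nelder-Mead
— the log parameterisation keeps σ positive without constraints — and reports
standard errors from the inverse observed information (central-difference
Hessian at the optimum, steps 10⁻⁵ relative in σ and 10⁻⁵ absolute in ξ).
Fits on fewer than 30 positive samples are refused rather than returned
unstable. `scipy.stats.genpareto.fit` is used only as an independent
cross-check in the test suite.

## Size scaling and extrapolation to non-donors

Mean daily supply follows a power law in store square footage.
`fit_size_scaling` is ordinary least squares of log₁₀(mean lbs/day) on
log₁₀(ft²) with additive category offsets; the most populous category is the
reference (ties alphabetical), base-10 logs throughout. A non-donating store
is given its category's rate and shape — these are category properties — with
the scale rescaled so the conditional mean matches the size-predicted mean
(`rescale_to_mean`, exact inverse of σ/(1−ξ)).

## Demand

Demand goals come from `individuals × per_capita × share`, floored to whole
pounds; weekly individual counts round to the nearest person. These are the
only conventions that reproduce all the published demand figures
simultaneously (5,491 / 10,260 / 19,465 / 48,600 lbs/day and 5,781 weekly
individuals from the printed inputs). The default per-capita intake is
2.85 lbs/person-day and the default covered share one third. Day-to-day
demand is constant by default — the headline experiments fix a goal — with an
optional Gaussian mode (sd = cv × mean, truncated at 0, default cv 0.1, an
engineering default since no dispersion is published).

## Perishability and the warehouse

`survival` is the fraction of un-recovered food remaining after one night:
0.5 means half expires per night, 0.8 means 20% expires. Donor stock follows
`available′ = draw + survival × available` (a geometric sum between pickups);
warehouse stock decays at the same rate — all food is assumed to expire
uniformly regardless of storage — and is floored at zero on shortage days (a
food bank cannot store negative food). Warehouse capacity is unlimited by
default and exposed as a config knob. Day 0 starts with an empty ledger and
warehouse.

## Spatial model

Synthetic driving distances are straight-line distances times a circuity
factor (default 1.3, a typical road-network detour ratio); planar rosters use
Euclidean geometry and geographic ones the haversine formula. Donors are
batched by k-means with a centroid-radius constraint: k is searched
incrementally from 1 and the first k whose clusters all fit within the radius
(default 10 km) is kept — the smallest k maximises batching. Initialisation
is deterministic farthest-point seeding (first center nearest the grand
centroid), so clustering needs no random state. Clusters are computed once
from geometry and held fixed across days.

A cluster visit costs `2 × mean(member-to-warehouse km) + MST(members)`: the
averaged out-and-back trip plus the minimum spanning tree of the intra-cluster
distance graph. The MST is a deliberate lower-bound surrogate for the open
route a driver would thread between members; computing optimal tours would be
a travelling-salesman problem and would not change the qualitative dynamics.

## Day scheduling

Each day a 0/1 selection over clusters is solved (fractional pickups are
physically meaningless): lexicographically minimise (1) shortfall against
demand net of surviving warehouse carryover, (2) total cost, (3) number of
clusters, (4) the sorted tuple of cluster ids. Stages 1 is analytic (picking
everything minimises shortfall); stage 2 is a covering MILP solved with HiGHS
through `scipy.optimize.milp`; a uniqueness probe (no-good cut) detects cost
ties, and only then do the count and lexicographic stages run, the latter as
a greedy sequence of feasibility MILPs. Relative tolerance 10⁻⁷ separates
genuine ties from float noise. An exhaustive enumerator with identical
tie-breaking (`brute_force_day`, ≤ 20 clusters) guards the implementation in
tests. The schedule is one day at a time — food quantities are not knowable
in advance — so multi-day optimality is intentionally out of scope.

## Randomness and common random numbers

Every donor owns a Philox substream keyed by `(seed, crc32(donor_id))`,
yielding its (n_days, 2) uniforms independently of every other donor; demand
and participation-subset draws use separate tagged streams. Consequently
sweeps over survival or participation reuse identical donation histories
(common random numbers), removing or renaming one donor never perturbs
another's draws, and identical (roster, config, seed) gives bit-identical
output.

## Synthetic regions

`generate_donors` emulates a mixed rural/urban service area: a central
warehouse, town centers uniform over a square extent (default 60 km, 6
towns), donors scattered normally (sd 3 km) around towns, categories
allocated by largest-remainder rounding of a grocer-dominated mix
(70/20/10 grocers/manufacturers/bakeries), and store sizes lognormal per
category (log₁₀ ft² means 4.5/4.3/3.5, sds 0.30/0.35/0.25). Each donor gets
its category's rate and shape with the scale set through a calibrated power
law (slope 0.8; offsets pinned so a category-median store has the category's
fitted conditional mean). Bakeries have no fitted category of their own and
inherit the pooled all-donor parameters. These defaults are fixtures chosen
to produce a region of realistic food-bank scale — the default 156-donor
roster rescues ~2.4M lbs/year at a 5,454 lbs/day goal — not estimates of any
actual county.

What the generator does **not** emulate: seasonality and day-of-week cycles,
correlated donation shocks across donors, real road networks and traffic,
per-food-type composition and differential expiry, agency-level demand
structure. Passing tests therefore demonstrate the internal consistency and
qualitative dynamics of the model, not calibration to any particular region.

## Problem sizes in the shipped checks

The test-suite experiments use sizes chosen to pin each property with modest
compute: 10⁶ donor-days for sampler fidelity (binomial/LLN tolerances), 10⁴
samples for parameter recovery (3-SE bands), 500 random instances of ≤ 12
clusters for scheduler optimality, and a 156-donor, 365-day region for the
sweep-shape checks (5-point survival grid; participation fractions 0.2–1.0
with 2–3 common-random-number replicates).

## Known limitations

- The MST visit cost underestimates true route length; costs are comparable
  across scenarios but not literal odometer kilometres.
- Single-vehicle, capacity-free logistics; no intra-day routing order.
- The GPD shape SE from the observed information is asymptotic; for very
  heavy tails (ξ near 1, e.g. farms) finite-sample coverage degrades.
- Demand dispersion (cv) is an assumption, not an estimate.
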