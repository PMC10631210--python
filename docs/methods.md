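# Methods

## The two catchment computations

Both indices are built from the same sparse kernel matrix
`W[i, j] = f(d_ij)` over mesh–facility pairs, where
`f(d) = exp(-beta * d)` for `d < d0` and `0` otherwise. Pairs at or beyond
`d0` are never stored, so the kernel's zero branch is structural: adding a
pair at 150 minutes to an input file changes nothing except a logged drop
count.

- Forward (accessibility): `R = S / (W' D)` per facility, `A = W R` per mesh.
- Inverted (crowdedness): `r = D / (W S)` per mesh, `C = W' r` per facility.

Two exact identities follow from the algebra and are checked continuously:
`D' A = sum(S)` over facilities with nonempty catchments, and
`S' C = sum(D)` over served meshes. They hold for every beta, which makes
them a cheap end-to-end integrity check on any instance; the pipeline
manifest records both residuals on every run.

Degenerate cases are resolved explicitly rather than propagated:

- A facility whose catchment contains no weighted demand gets `R_j = 0`
  (its supply is unreachable), is reported, and is barred from receiving
  staff in the optimization (upper bound forced to 0).
- A mesh with zero decay-weighted supply in reach has no defined demand
  ratio; it is flagged unserved (NaN), excluded from every crowdedness sum,
  and its count and population are reported. Infinities never enter the sums.
- An uncovered mesh (no facility inside `d0`) has accessibility exactly 0 and
  is listed, so zero minima in the reported ranges are attributable.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `beta` | 0.07 | per minute | anchors the kernel at weight ~0.5 for a 10-minute trip, the median pre-hospital transport time for thrombectomy patients |
| `threshold_minutes` (`d0`) | 120 | min | catchment bound for car transport |
| `scale` | 100 000 | persons | accessibility reported as physicians per 100,000; raw per-capita values are ~1e-5 and unreadable. The underlying national ratio (1,605 specialists over tens of millions aged >= 65) only matches conventional index magnitudes under a per-100k scale |
| `upper_bound` | 5 | physicians/facility | reallocation cap per facility |
| `staffed_threshold` | 0.01 | physicians | a facility "has staff" when its (possibly fractional) allocation is at least this |
| `betas_for_sweep` | 0.07..0.02 step 0.01 | per minute | sensitivity sweep; smaller beta flattens the kernel and widens effective catchments |
| `ridge` | 1e-9 | — | diagonal regularizer on the QP quadratic form (see below) |

## The reallocation QP

With the catchment denominators `V_j = sum_i D_i f(d_ij)` held at their
demand-side values, accessibility is linear in the staffing vector:
`A = M s` with `M[i, j] = f(d_ij) / V_j`. The program

```
minimize  sum_i D_i (A_i - a)^2
subject to  sum_j s_j = S_total,  0 <= s_j <= cap
```

uses the equal-access level `a = S_total / sum_i D_i`. That choice is not
arbitrary: by the conservation identity the demand-weighted mean of `A` equals
`a` under *every* feasible staffing, so the objective is exactly the
demand-weighted variance of accessibility, and any other constant target would
only add a constant to the objective. Allocations are continuous (fractional
physicians); a staffed-facility count at the 0.01 threshold is reported
because a hard integer notion of "staffed" no longer applies after
optimization.

### Solver

The QP is strictly convex after adding `ridge * I` (default 1e-9, several
orders below the typical diagonal of `M' diag(D) M`) and is solved by a dense
primal active-set method specialized to one equality constraint plus simple
bounds:

1. Factor the Hessian once and form its inverse (a few hundred facilities,
   so this is cheap and done once per solve).
2. Start from the water-filling projection of the uniform allocation onto the
   feasible set.
3. At each iteration solve the working-set subproblem through the Schur
   complement of the active bound rows against the precomputed inverse
   (`O(n*k + k^3)` for `k` active bounds), step to the first blocking bound,
   or drop the bound with the most wrong-signed multiplier; stop when no
   multiplier violates its sign condition.

The method is deterministic, monotone in the objective, and exact up to
linear-algebra precision: stationarity, primal feasibility, bound violation
and complementarity residuals are computed for every solve (`verify_kkt`) and
are typically below 1e-9 at the national scale — the accepted tolerance is
1e-6. A rank-deficiency flag is raised when the unregularized quadratic form
is singular (possible when facilities outnumber meshes); the ridge then picks
the minimum-norm-flavored optimum deterministically.

Facilities with empty catchments enter the program with upper bound 0, so
unreachable supply can never absorb part of the total. Post-optimization
surfaces (both accessibility and crowdedness) are recomputed in full from the
two-step sums with the new staffing, not read off the QP's internal linear map.

### Tie-breaks and tolerances

Equality feasibility is enforced to ~1e-12 relative by construction
(active-set steps solve the constraint exactly); the acceptance tolerance is
1e-8. Bound activity is detected at 1e-9 slack. Weighted-median ties resolve
to the lower median; urbanicity rank ties resolve by region identifier; both
are deterministic.

## Summary statistics

- **Weighted median**: lower weighted median — the smallest value whose
  cumulative weight reaches half the total. With equal weights this is the
  ordinary lower median.
- **Weighted SD**: population form, `sqrt(sum w (v - mean_w)^2 / sum w)`.
- Accessibility is summarized demand-weighted (weights `D_i`), matching the
  QP objective's weighting; ranges are unweighted over all meshes including
  uncovered ones.
- Crowdedness is summarized unweighted over facilities at or above the
  staffed threshold (the Table-style summary); the disparity-direction checks
  in the acceptance tests compare the SD over *all* facilities, since the
  crowdedness index is defined for every facility regardless of its own staff
  and the staffed subset changes between scenarios.
- Regional aggregation: unweighted mean crowdedness over a region's
  facilities, summed staff, and their deltas; urbanicity classes split
  regions by urban-population proportion into top quarter (high), bottom
  quarter (low, both `floor(n/4)`) and the middle (medium) — 47 regions give
  the 11/25/11 split used for prefecture-style reporting.

## The synthetic-region generator

The generator emulates the statistical structure of the real inputs, which
are proprietary (census mesh populations, certified-facility addresses, a
commercial road network):

- **Demand**: mesh locations cluster bivariate-normally (`cluster_sd_km`,
  default 15 km) around `n_urban_centers` urban centers whose sizes are
  heavy-tailed (log-normal weights); mesh populations are log-normal
  (`mean_log_population` 5.0, `sd_log_population` 1.2 — median ~148 persons
  aged >= 65 per mesh). The defaults describe a country-scale instance at
  reduced resolution: each synthetic mesh stands for a coarser demand cell
  than a 500 m census mesh, so per-mesh populations are correspondingly
  larger while national totals stay realistic.
- **Supply**: facilities are placed at demand-mesh locations sampled with
  probability proportional to population raised to
  `facility_demand_affinity` (default 1), plus ~1 km jitter. Current staffing
  distributes `total_staff` by repeated unit increments over facilities below
  the cap — exact conservation by construction.
- **Travel times**: planar Euclidean distance at `travel_speed_km_per_min`
  (default 0.75, ~45 km/h effective door-to-door), thresholded at `d0`.
- **Regions**: Voronoi cells of uniform seed points; a region's urban
  proportion is the share of its population within one cluster radius of an
  urban center.
- The national-scale fixture uses 662 facilities, 1,605 specialists, cap 5,
  47 regions and (by default) 5,000 meshes.

Everything is drawn from a single `numpy` generator seeded by the required
`seed`; identical parameters and seed give bit-identical instances, and no
global random state is touched.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: road-network topology (ferries, mountain passes, urban
congestion), coastline and terrain constraints on settlement, the empirical
distribution of specialists per facility (unpublished; the unit-increment
scheme is a modeling choice), daytime/nighttime population differences, and
regional variation in stroke incidence. Conclusions about *magnitudes* of
disparity on real systems require real inputs; the synthetic instances
validate the machinery and the *direction* of the optimization effect.

## Problem sizes

Unit tests run on instances of up to a few hundred meshes; the acceptance
tests and script use the national-scale fixture (5,000 meshes x 662
facilities, ~3.3 M candidate pairs) where one full pipeline pass — generate,
both surfaces, QP solve with certificate, re-evaluation — takes a few seconds
on one CPU, and the direction-of-effect check repeats it over 20 seeds.

## Known limitations

- Euclidean travel times understate true drive times asymmetrically
  (worse in mountainous or insular geography).
- The demand-side denominators `V_j` are held fixed during optimization (the
  construction that makes the QP linear in staffing); a fully endogenous
  model would re-equilibrate choice behavior with staffing.
- Only one resource type is reallocated; equipment, beds and team
  constraints are out of scope, as is siting new facilities.
- Accessibility of exactly 0 for uncovered meshes is a hard catchment
  artifact: people beyond 120 minutes are not "slightly" served.
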