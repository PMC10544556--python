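# Methods

This note documents the models and procedures implemented in `sympatry`, the
choices made where the methodology is genuinely open, and what the synthetic
validation does and does not establish.

## Data model and projection

A trajectory is the time-ordered fix series (UTC timestamp, lon/lat) of one
animal-season; all geometry is computed in planar metres.  The default
projection is a spherical transverse Mercator centred on the data centroid
(mean lon/lat).  Over a study window under 200 km the sphere-vs-ellipsoid
scale error is below ~0.3% and the projection round-trips to better than
1e-6 degrees, so areas and distances are metric to well within GPS error.
Duplicate (id, timestamp) rows with identical coordinates are collapsed;
with differing coordinates they are an error rather than being averaged,
because a collar emits one fix per schedule slot.  Rows with missing
coordinates are dropped and reported.

The per-animal movement constant `v_max` is the maximum observed velocity
between consecutive fixes, excluding pairs closer than `min_dt` = 300 s: the
collars' ~5-minute location-timing jitter makes shorter intervals
uninformative for speed and numerically explosive.

## Screening

**Residency.** The empirical variogram accumulates half squared
displacements of all fix pairs into time-lag bins (default 24 h wide).  A
track is called resident when the pair-weighted mean semivariance in a tail
window (default 25–40 day lags) is at most (1 + tol) times the mean in a
plateau window (default 5–10 day lags), with tol = 0.5.  The windows and
tolerance are configuration: the underlying judgement is a by-eye asymptote
call, and these defaults simply make it reproducible.

**Range shift.** A single-change-point least-squares heuristic: the split
minimising total within-segment squared distance to segment centroids
declares a shift only when the between-centroid distance exceeds the larger
segment RMS radius.  This is a deliberate simplification of likelihood-based
range-shift models; it is only used to decide whether to truncate a track.

**Excursion filter.** Distances to the track centroid are transformed by
the Tukey ladder of powers (x^λ for λ>0, ln x for λ=0, −x^λ for λ<0 — a
monotone family), with λ chosen on the grid [−5, 5] in steps of 0.025 to
maximise Shapiro–Wilk W, the transformTukey convention.  The one-sided
Hampel bound is `median + 3·MAD` with the MAD deliberately *unscaled* (no
1.4826 consistency factor): the definition is three median absolute
deviations, taken literally.  Only the upper bound is applied — short
distances are legitimate den attendance.  Runs of consecutive flagged fixes
become excursion segments; the kept trajectory is re-centroided once (a
single pass, no iteration — iterating would re-flag progressively and has no
defined stopping rule).  If the MAD degenerates to 0 the bound collapses to
the median, which is documented behaviour; a >50%-flagged guard raises an
error as a safety net for non-resident input.  Zero distances are replaced
by half the smallest positive distance so the log branch is defined.

With a near-normal transformed sample the one-sided 3-MAD bound sits at
about the 2% upper tail, which is the filter's designed specificity; the
validation suite checks a median false-flag rate ≤ 2% on clean resident
tracks and full recovery of injected excursions at ≥ 5× the 95% range
radius.

## T-LoCoH

The time-scaled distance between fixes i and j is

    TSD = sqrt(Δx² + Δy² + (s · v_max · Δt)²)

with `s` dimensionless; s = 0 ignores time entirely.  Neighbours of each
parent fix are selected by the adaptive method: fixes sorted by TSD are
accepted while their cumulative TSD stays ≤ `a` (metres), with at least the
2 nearest always retained because a hull needs three points.  Each hull is
the planar convex hull of parent + neighbours.  Degenerate neighbourhoods
(coincident or collinear points, e.g. repeated den fixes) are skipped and
reported; more than 20% skipped aborts the hullset.

Enclosure (`n_enclosed`) counts **all** trajectory fixes covered by the hull
polygon, boundary inclusive — parents sitting on their own hull boundary
must count.  Where the source methodology is ambiguous between counting all
enclosed fixes and only nearest neighbours when ordering hulls, this package
counts all enclosed fixes; the alternative weights identically for compact
hulls and diverges only for very elongated ones.

Time-use metrics partition each hull's enclosed fixes into visits: a new
visit starts when the gap since the previous enclosed fix is ≥ the
inter-visit gap (default 43,200 s = 12 h, matching a 12-h period of
interest for a 12–16 fix/day schedule).  NSV is the number of visits, MNLV
the mean fixes per visit; NSV × MNLV equals the enclosed count by
construction.

Isopleths sort hulls by the ordering metric (density = n_enclosed, NSV, or
MNLV) descending, breaking ties by smaller area first and then earlier
parent time — fixed purely for determinism — and take cumulative polygon
unions until the fraction of *unique* fixes enclosed reaches each level
(a fix in several hulls counts once).  Levels computed from one sorted pass
nest by construction; 0.95 is the home range, 0.50 the core area.
Unreachable levels are returned flagged partial rather than silently short.

**Choosing s and a.**  Per-individual s and a are analyst choices made with
graphical diagnostics in the original workflow and cannot be automated
faithfully.  `suggest_s` returns the balance point where the median time
term s·v_max·Δt equals the median spatial separation over pairs near the
period of interest (clamped to [0.001, 1]); `suggest_a` returns the median
cumulative TSD to the 15 nearest fixes; `enclosed_fraction_curve` exposes
the coverage-vs-a curve for inspection.  All three are starting points, not
replacements for judgement.

## Dyadic interactions

Animals are neighbours when their 95%-isopleth boundaries are closer than
3,200 m (the radius of a red-fox home range in the system this pipeline was
built around; configurable, and whether that radius was a mean or median
circular equivalent is not recoverable).  Static overlap is
`sqrt((area_AB/area_A)·(area_AB/area_B))` — symmetric, in [0, 1], and
bounded by the larger directed fraction.

Simultaneous fixes are matched greedily one-to-one in time order within a
300 s buffer; greediness prevents double-pairing when schedules drift
within the buffer.

**Spatial coefficient.**  For one animal, with q the shared fraction of its
home-range area, k fixes in the shared zone and m elsewhere in range,
`L = ln((k(1−q))/(m q))`; p from an exact binomial test of k in k+m trials
at probability q.  k = 0 (or m = 0) produces a ∓∞ sentinel that is carried,
never dropped: published odds tables print raw zeros and so does this
package (no continuity correction).

**Temporal coefficient.**  Simultaneous pairs are cross-classified by each
animal's shared-zone presence; expected cell probabilities are products of
each animal's own marginal presence frequency *among the pairs* (an
independence null, which is what reproduces published odds tables
internally — areal proportions are not used here).  With per-cell odds
obs/(n·expected), `L_ixn = ln((odds_AB + odds_00)/(odds_A0 + odds_0B))`.

Two significance procedures are provided.  The default is a chi-square
goodness of fit with df = 1, appropriate for exchangeable pairs.  For
sub-daily fix schedules the presence indicators are strongly autocorrelated
and the chi-square null is anticonservative — in simulation its type-I rate
at α = 0.05 is ~30% under full independence.  The rotation test (cyclic
random time-shifts of one animal's indicator sequence, chi-square statistic,
(1+count)/(n+1) p-value) preserves each series' autocorrelation and is
calibrated (~5%); it is what the validation suite uses and what analysts
should prefer on real collar data.  The label rules: significant ⇒
simultaneous/solitary by the sign of L_ixn; non-significant with
|L_ixn| ≥ 0.2 ⇒ the same word with a "trend" suffix; otherwise random.  The
0.2 threshold separates the near-zero coefficients reported as random from
the moderate ones reported as trends in published tables and is
configuration, not inference.

Dyad spatial labels: symmetric (both animals significant, same sign),
asymmetric (both, opposite signs), singular attraction/avoidance (exactly
one significant, named for it), random (neither).

## Habitat

Rasters are integer class grids in ESRI ASCII format.  Reclassification
maps every present value or fails loudly naming the unmapped ids.
Composition uses the deterministic cell-centre rule (a cell counts iff its
centre intersects the polygon, boundary inclusive) and renormalises over
non-excluded classes (water/infrastructure exclusion is an excluded-class
set in configuration).  The long-format composition table carries the full
class roster per animal × ordering (absent classes at 0) so it feeds
multivariate tests directly; the multivariate tests themselves (MANOVA and
relatives) are standard library statistics and out of scope here.

## Resampling statistics

The permutation two-sample test permutes group labels n_perm = 999 times
over the pooled sample and compares Welch t statistics two-sidedly with
p = (1 + count)/(n_perm + 1), which can never return 0.  The pooled sample
is sorted and always split smaller-group-first so the p-value is exactly
symmetric in the arguments.  Rank tests use exact enumeration of the
signed-rank / rank-sum null for n ≤ 25 without ties and the tie-corrected
normal approximation otherwise.  Fisher tests use the closed-form
hypergeometric enumeration for 2×2 tables and fixed-margin Monte Carlo
(table-probability ordering, seeded) for r×c; a zero margin is degenerate
and returns p = 1 with a warning.  Everything resampling-based takes a seed
and is reproducible.

## Synthetic data generator

`simulate_forager` is a discrete-time mean-reverting walk: position steps by
`attraction · (den − position)` plus isotropic Gaussian noise, initialised
at the stationary distribution.  Defaults — attraction 0.15/step, step SD
500 m, fixes every 1.5–2 h for 92 days — give a stationary positional SD of
~900 m per axis and a 95% range radius near 2 km, the scale of the fox
territories the pipeline targets, and produce plateauing variograms (the
residency property the analysis assumes).

Excursions displace runs of fixes along a random bearing with a
`sin(π(i+1)/(k+1))^0.25` out-and-back profile: the shallow power keeps the
animal near the far point for essentially the whole excursion, as a
fast-travelling forager sampled every 1.5–2 h would appear.

Dyads place dens 3 km apart with a 1.5 km-radius shared disc at the
midpoint and give B the same schedule as A plus ±2 min jitter (inside the
5-min simultaneity buffer, so every fix pairs).  Regimes rewire B's
shared-disc presence only — schedules, not step dynamics — so the ground
truth is unambiguous: *cohesive* places B uniformly in the disc whenever A
is there (compliance 0.9); *exclusive* reflects B radially out of the disc
whenever A occupies it; *independent* leaves both walks untouched.

Habitat rasters are nearest-nucleus mosaics: class nuclei scattered in
numbers proportional to configured shares, cells labelled by nearest
nucleus, which yields contiguous patches with realized areas near the
shares.

**What the generator does not emulate:** GPS measurement error, habitat- or
memory-driven movement, behavioural states (resting vs travelling), collar
dropouts, and landscape-coupled dyad dynamics.  Passing the validation
suites therefore demonstrates that the estimators recover the structure
they are defined on, not that they are robust to every artefact of real
collar data.

## Validation problem sizes

The validation suites run at: 20 random ≤ 12-point configurations against a
brute-force convex-hull oracle; 100 two-week simulated seasons for isopleth
nesting; 200 simulated seasons each for excursion recovery (multiplier 5)
and clean-track specificity; 500 independent-regime dyads (rotation test,
199 shifts) for type-I calibration plus 100 dyads per coupled regime for
sign recovery; and 500 null replicates (199 permutations) for permutation-p
uniformity.  These sizes put binomial standard errors on the checked rates
at roughly one percentage point.

## Known limitations

- The range-shift detector handles a single shift and is a heuristic, not a
  likelihood model.
- `suggest_s` / `suggest_a` are documented surrogates for what is an
  interactive, graphical choice; per-animal values in the run configuration
  always take precedence.
- The chi-square temporal p-value is anticonservative under autocorrelation
  (see above); it is retained as the default for comparability with odds
  tables computed the classical way, but the rotation test is the defensible
  choice and one flag away.
- Hull construction is O(n²) in fixes per animal (pairwise TSD); seasons of
  a few thousand fixes are comfortable, multi-year tracks at minute
  resolution are not the target.
- Only the Minta family of interaction statistics is implemented; no
  proximity, correlation, or association-index metrics.
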