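# sympatry

Dyadic space-use and spatio-temporal interaction analysis for territorial
central-place foragers tracked by satellite collar — built around the
question of how two similar carnivores (e.g. red foxes and Arctic foxes at
the tundra edge) share space, time, and habitat.

The pipeline takes relocation tables (Movebank-dialect CSV) through:

1. **Screening** — empirical-variogram residency triage, a least-squares
   range-shift check, and excursion removal with a one-sided Hampel filter,
   `upper bound = median(Tukey-transformed distance) + 3·MAD`,
   on distances to the track centroid;
2. **T-LoCoH home ranges** — local convex hulls whose neighbours are chosen
   by the time-scaled distance
   `TSD = sqrt(Δx² + Δy² + (s·v_max·Δt)²)` under the adaptive (cumulative
   TSD ≤ *a*) rule, aggregated into density isopleths (95% home range, 50%
   core) and time-use isopleths ordered by revisitation (NSV) and duration
   (MNLV) with a 12-h inter-visit gap;
3. **Dyadic interactions** — neighbours (< 3.2 km between home-range
   boundaries), the overlap index
   `sqrt((area_AB/HR_A)·(area_AB/HR_B))`, and Minta's coefficients: spatial
   `L = ln((k(1−q))/(mq))` per animal and temporal
   `L_ixn = ln((odds_AB+odds_00)/(odds_A0+odds_0B))` from simultaneous
   fixes (5-min buffer), with exact-binomial, chi-square, and
   autocorrelation-robust rotation tests;
4. **Habitat composition** — landcover reclassification and cell-centre
   composition of the 50% NSV/MNLV isopleths;
5. **Statistics** — native permutation *t*-tests, exact rank tests, and
   Fisher exact / fixed-margin Monte Carlo tests for the small-sample group
   comparisons such data support.

A first-class synthetic-data module simulates range-resident mean-reverting
foragers on a realistic collar schedule (12–16 fixes/day), injects
ground-truth excursions, generates dyads in independent / cohesive /
exclusive regimes, and builds patch-mosaic habitat rasters — so the whole
pipeline is testable end to end without any field data.

## Worked example

Each script in `examples/` exercises one capability.  Computing a dyad's
interaction structure (`examples/03_dyad_interactions.py`):

```sh
$ python examples/03_dyad_interactions.py
simulated regime: cohesive (expected L_ixn sign +1)
home ranges 16.4 and 16.9 km^2, overlap index 0.30
simultaneous pairs n=1259; cells AB=258 A0=116 0B=202 00=683
observed/expected odds: [1.89 0.49 0.62 1.22]
L_A +0.06 (p=0.328), L_B +0.42 (p=0.000)
L_ixn +1.03 (rotation p=0.001)
dyad response: spatial 'singular attraction', temporal 'simultaneous'
```

The two simulated neighbours were in their shared area together 258 times
against ~137 expected under independent schedules (odds 1.89), and alone
there far less than expected (odds 0.49 and 0.62) — a positive L_ixn with a
small rotation-test p-value, recovering the cohesive regime the generator
imposed.  Animal B is also spatially attracted to the shared area
(L_B > 0, binomial p < 0.001), while A uses it in proportion to its size.

The full configuration-driven pipeline (screening → home ranges → dyads →
habitat, with CSV/GeoJSON outputs and a reproducibility manifest) is shown
in `examples/05_full_pipeline.py`, and the same stages are available from a
shell via the `sympatry` command (`simulate`, `screen`, `homerange`,
`dyads`, `habitat`, `run`, `report`).

## Layout

- `src/sympatry/` — the library (`trajectory`, `screening`, `tlocoh`,
  `interactions`, `habitat`, `stats`, `synthetic`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameter choices, and limitations
- `tests/` — unit, property, and validation suites
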