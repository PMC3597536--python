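# Methods

## Model overview

`ebsim` models an embryoid body (EB) as a packed aggregate of incompressible
rigid spheres carrying a binary pluripotency state (Oct4+ / Oct4−).  The
model has three layers: structure formation (packing spheres into a
spheroid), state dynamics (probabilistic, irreversible Oct4 loss driven by
contact-graph neighbourhoods), and an optional growth layer (mass-spring
mechanics with symmetric, unsynchronised cell division).  All positions are
in µm, time in hours (dynamic model) or discrete steps (static model).

## Structure formation

Cell radii are drawn from a diameter distribution with mean 6.6 µm and SD
0.33 µm, lognormal by default (Coulter-counter histograms of dissociated
cells are right-skewed; a truncated normal is available).  Spheres are
seeded uniformly at random without overlap in a cube (default volume 8× the
total sphere volume) and driven toward a point attractor under an
overdamped scheme: each iteration every cell moves `step_size` (default
1 µm) along the unit vector to the attractor, then all pairwise overlaps
are resolved by symmetric projection along the centre line.  Overlap
resolution corrects all violating pairs simultaneously per pass
(accumulated displacements), which is free of ordering bias by
construction; a seeded RNG only breaks ties for coincident centres.

Convergence is declared when the largest net per-iteration displacement
falls below `convergence_displacement` (default 0.01 µm).  Because a hard
projection scheme at finite step size otherwise enters a limit cycle
(attraction recompresses pairs that resolution just separated), the
attraction step is annealed: full strength while the cloud is in transit,
then geometric decay to zero once every centre is inside ~1.3× the
close-packed radius.  Cells in contact-graph components disconnected from
the core keep feeling the full attraction during annealing, which
guarantees a single connected aggregate.  Non-convergence within
`max_iterations` returns the best state with a warning and a
`converged=False` flag.

Two spheres may interpenetrate by at most 1% of the smaller radius after
relaxation.  "Adjacent" (a contact-graph edge) means centre distance within
`(r_i + r_j)(1 + contact_slack)` with `contact_slack = 0.05`; the 5% slack
tolerates relaxation residuals, and on equal-sphere lattices it reproduces
the exact kissing geometry (12 contacts for interior FCC spheres).

Structural read-outs mimic the image-based experimental ones: the
projected footprint (union of projected disks) is rasterised at
0.25 µm/pixel; aggregate radius is that of the equal-area circle;
circularity is the minor/major axis ratio of the footprint's
second-moment-equivalent ellipse.  Note that for strongly non-elliptical
footprints the moment-equivalent ratio differs from a bounding-box ratio
(two touching disks give √(0.2) ≈ 0.447, not 0.5).  Virtual sections take
all cells whose centres lie in a 10 µm slab (default placement 25 µm below
the aggregate top, mimicking confocal practice) and project them to 2D.

## Differentiation rules

Cells decide synchronously once per step; only Oct4+ cells may transition
and transitions are instantaneous and irreversible.  With β the number of
Oct4− neighbours, γ the number of Oct4+ neighbours, ε = 12 the maximum
possible neighbour count, α = 0.01 the basal probability, and
`or_gate(p, q) = 1 − (1−p)(1−q)`:

- random: `P = α`
- positive feedback: `P = or_gate(α, min(β/ε, 1))`
- competing feedback: `P = or_gate(α, w · β^k / (β^k + γ^k))`, `k = 2`

The competing form is sigmoidal in the neighbour composition without a
separate half-saturation constant; `f(0, 0) = 0` so an isolated cell feels
only the basal rate.  β/ε clamps to 1 in the rare case contact slack
admits more than ε contacts.  The weight `w` is 1.0 in static-structure
runs and 0.01 in the growing model (where the rule is evaluated every
simulated hour rather than per abstract step).  Both feedback expressions
are ordinary functions and can be swapped out by supplying different
`RuleParams`.

Static simulations start from a homogeneous Oct4+ population and stop when
no Oct4+ cells remain or at a 500-step cutoff; each run records per-step
state vectors, %Oct4+, and the cluster metrics below.  Exactly one uniform
variate is drawn per cell per step, in index order, so any run can be
replayed bit-for-bit from its seed.

## Pattern analytics

UCN / DCN are the numbers of connected components, restricted to cells of
one state, containing at least two cells (a lone cell is not a cluster).
Trajectories are compared on a normalised time axis τ = step / K where K
is the completion step (or the cutoff for incomplete runs, flagged).
Replicate summaries report per-τ mean and sample variance of UCN/DCN and
their summed (cumulative) variance over the grid.

Classification into the six pattern classes proceeds as:

1. fraction Oct4+ ≥ 0.90 → **Oct4+**; ≤ 0.10 → **Oct4−** (boundaries
   inclusive);
2. otherwise, if the mean centroid-normalised radial positions of the two
   states differ by more than `radial_delta = 0.15` while each state forms
   at most 2 clusters → **inside-out** (Oct4− nearer the core) or
   **outside-in** (Oct4− nearer the rim);
3. otherwise the minority state is tested for spatial aggregation:
   **connected** if aggregated, **random** if not.

For step 3 the default statistic is chance-corrected: the observed number
of minority-state components (singletons included) is compared with its
null distribution under random relabelling of the same number of cells on
the same contact graph (30 seeded permutations); the pattern is connected
when the observed count lies more than 2 null SDs below the null mean.
The simpler alternative — the fraction of minority cells in clusters of
size ≥ 2, threshold 0.6 (`method="clustered_fraction"`) — is retained but
is not the default because it saturates on dense 3D contact graphs: with
~10 contacts per cell, even i.i.d. coin-flip states leave almost no cell
without a same-state neighbour, so nearly every mid-transition snapshot of
*any* rule would read as connected and the random class would be
unreachable.  The chance-corrected statistic restores the intended
distinction (i.i.d. states → random; rule-grown or constructed clusters →
connected) and is invariant to rigid motions, as is the rest of the
classifier.  Sections are classified on the 3D contact graph restricted to
the section's members.

## Growth model

In the dynamic model, contacting cells are joined by springs with rest
length `spring_rest_length_factor · (r_i + r_j)` (default factor 1.0).
Mechanics advance every `mechanics_dt = 0.1 h`: each contact spring moves
its endpoints a fraction `spring_stiffness · mechanics_dt` (default
stiffness 5 /h, an overdamped relaxation rate) of the way to rest length,
then complete pairwise collision detection projects residual overlaps
apart.  Division is symmetric — the daughter inherits the parent's state
and radius (cell size does not change on differentiation) — and placed one
parent radius away in a uniform random direction, with mechanics resolving
the overlap.  Waiting times are exponential with rate ln2/T for
state-specific doubling times (T = 18 h Oct4+, 51 h Oct4−): memoryless
waiting keeps divisions unsynchronised and makes population growth exactly
exponential with doubling time T, consistent with the growth-rate algebra
`r = ln(N₂/N₁)/Δt`, `T = ln2/r` used to calibrate the rates from aggregate
sizes (cell counts from radii assume close packing, constant 0.7408 — kept
as printed even though the analytic FCC value is π/√18 ≈ 0.74048, which is
tested separately).  Rules are evaluated every `rule_dt = 1 h` with their
static per-step probabilities; runs stop at 144 h, at 99% differentiated,
or at 40,000 cells, whichever is first.  No cell death or active migration
is modelled.

## Synthetic data and what passing tests show

All test inputs are generated programmatically: FCC lattices (exact
12-neighbour geometry), relaxed random packings, and labelled pattern
fixtures built on those packings (Oct4− core, Oct4− rim, two contiguous
blobs, i.i.d. checkerboard, uniform states).  These capture the geometry
and composition of the patterns but none of the imaging noise,
segmentation error, or biological heterogeneity of real confocal data, so
passing tests demonstrate the internal consistency of the model and
classifier, not agreement with any particular experimental image set.

## Problem sizes and numerical choices

Default study conditions are 250- and 1000-cell aggregates, 10 replicates
per condition, 500-step static cutoff.  Heavier checks in the test suite
use deliberately scaled problem sizes chosen for a laptop-class single
core: the division-only doubling-time recovery grows 250 → 4,000 cells;
the structural-stationarity control grows 250 → 2,000 over 54 h with ten
replicates; the static-versus-dynamic comparison uses 100-cell aggregates
over 72 h.  In stationarity checks the first 10–20 h are discarded as
mechanical equilibration: the force-aggregated initial packing is denser
than the spring steady state, and the transition between the two is an
initial-condition transient, not a division bias.  Connection-count
stationarity is assessed on interior cells (deeper than 10 µm below the
surface): the whole-aggregate mean degree necessarily rises as the surface
fraction shrinks like N^(−1/3) during growth, which is a finite-size
geometry effect rather than a structural bias.

Other numerical details: footprint rasters at 0.25 µm/px bound radius and
circularity errors well below the assertion tolerances; cluster counting
uses sparse connected components; all randomness flows through
`numpy.random.Generator` objects seeded from a single master seed per run
(replicate seeds spawned via `SeedSequence`), and every output artefact
records its seed in the run manifest.

## Known limitations

- The aggregation scheme reproduces the steady-state packed structure, not
  the physical transient of a real physics engine; trajectory-level
  mechanics are out of scope.
- Mean contact number in grown aggregates (~5 interior) is lower than in
  force-aggregated static packings (~6.6): insertion-driven packings are
  looser.  Both are below the crystalline maximum of 12; rule dynamics are
  robust to this difference (the static-versus-dynamic comparison passes),
  but absolute cluster counts do depend on graph density.
- The classifier's transition subtypes depend on declared thresholds
  (`radial_delta`, permutation z-threshold); defaults were validated
  against the constructed fixtures, not fit to experimental images.
- No diffusion gradients, soluble factors, cell death, or migration.
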