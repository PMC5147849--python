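# Methods

## Model

The simulator is a discrete-time, continuous-space agent-based model of
competitive binding of three growth-factor affinity classes (LA, MA, HA —
stimulators, stabilizers, inhibitors of angiogenesis) to heparan-sulfate
binding sites on stromal cells, under stochastic heparinase turnover.

**Space.** A `grid_width × grid_height` lattice of microenvironments
(default 51×51 = 2601 patches) with toroidal topology. Agents live in
continuous coordinates; a patch is the unit cell containing a position.
The torus removes boundary artifacts and matches the default world-wrap of
the platform family this model style comes from; it is the one boundary
rule that needs no extra parameters.

**Cells.** `n_cells` (default 200) non-motile cells at uniform random
positions; several cells may share a patch. Each cell's binding-site count
is drawn once from a normal distribution with mean `site_mean` (default 5)
and SD `site_sd` (default 2), rounded to the nearest integer and clamped at
zero; `total_sites` is immutable, `free_sites` tracks occupancy.

**Growth factors.** A factor is `free`, `bound`, or `cleaved`. Free factors
take unit-length steps in uniformly random headings. A free factor
co-located with at least one cell that has a free site picks one such cell
uniformly at random and binds with its class's `attach_prob` (default 0.5
for all classes — affinity differences are deliberately expressed through
detachment only, since the elution data constrain the *release* ordering,
not attachment). Binding occupies one site; the factor stays with the cell.

**Cleavage.** A bound factor of class c detaches as soon as the heparinase
in its cell's patch satisfies h ≥ θ_c. Thresholds default to 0.25, 0.50,
0.75 × `heparinase_max` for LA, MA, HA; any configuration must satisfy
θ_LA < θ_MA < θ_HA strictly. The threshold rule is the minimal reading of
"released at the lowest / intermediate / highest heparinase concentration";
stochasticity in detachment times comes entirely from the heparinase flux.
The fate of a cleaved factor is `degrade` (removed from the active pool;
the default — the published wound-healing curves decay toward zero after
their peaks, which indefinite recycling in a closed system cannot produce)
or `recycle` (returns to the free pool).

**Heparinase.** Initialized i.i.d. uniform on [0, `heparinase_max`]
(default max 1.0). Each step, each patch independently is perturbed with
probability `flux_prob` (default 0.2) by a uniform increment on
[−`flux_magnitude`, +`flux_magnitude`] (default 0.1 × max), clamped to
[0, max]. The clamped symmetric walk is the simplest process that is both
continuously "removed and replenished" and homeostatically balanced (its
time-average is max/2; verified by a batch-means test).

**Schedule.** Per step, in fixed order: (1) tumor inflow (`inflow_per_step`
new free factors per class at uniform positions; all-zero = wound-healing
mode, whose single release of `initial_release` per class — default 300 —
happens at initialization); (2) every free factor moves; (3) every free
factor makes one binding attempt, the free factors being processed in a
freshly shuffled uniform random order (movement is per-factor independent,
so moving all before binding is identical to interleaving); (4) every bound
factor is checked for cleavage; (5) heparinase flux. Newly released factors
act in the step they appear; several factors may bind one cell in one step,
subject to `free_sites`. A seeded golden-trajectory regression test pins
this event order. Bound and free counts per class are recorded at every
step boundary including t = 0, so series have length `n_steps + 1`.

**Replicates and seeding.** Replicate i draws its generator from
`SeedSequence([seed, i])`: reproducible and independent streams. The
default experiment averages 10 replicates pointwise (arithmetic mean).

## Parameters without stated values

The source material leaves several quantities open; they were fixed once,
as follows, and are all exposed in the configuration:

| parameter | default | rationale |
|---|---|---|
| `initial_release` | 300/class | the published setup adjusted unprinted literature values and notes the adjustment changes only time scale, not dynamics; 300 against ~1000 total sites (200 cells × mean 5) makes the three classes jointly saturating |
| `n_cells`, `site_mean`, `site_sd` | 200, 5, 2 | ~0.08 cells/patch keeps encounters, not diffusion, rate-limiting; mean/SD parameterization as specified |
| `attach_prob` | 0.5 all classes | detachment ordering is the only empirically constrained asymmetry |
| `n_steps` | 500 | long enough for the default wound-healing run to pass the HA-dominated quasi-steady state well before the recording ends |
| `flux_prob`, `flux_magnitude` | 0.2, 0.1·max | slow flux relative to thresholds, so bound inhibitors persist for hundreds of steps while stimulators turn over quickly |

## Observables and classification

`peak_time` is the earliest index attaining a series' maximum (stable,
order-independent tie-break). `terminal_occupancy` reports each class's
share of the mean bound count over the final `tail_fraction` of timepoints
(default 0.2; window ⌈tail_fraction · T⌉, minimum 1). The classifier calls
a summary `sequential_resolved` when peaks are ordered
LA ≤ MA ≤ HA in time *and* the tail-window HA mean is at least
`dominance_ratio` (default 1.0) times the tail LA+MA mean;
`unresolved_stimulation` when the tail LA+MA mean exceeds the tail HA mean;
`no_signal` for identically zero series; any residual case falls to the
nearer side of the dominance comparison, and the diagnostics (peak times,
tail means, shares) are always reported alongside the label. "Out-competed"
has no quantitative definition in the source; this dominance criterion is a
declared operationalization, reported with its thresholds.

## Numerical and degenerate-input choices

- Binding-site counts use round-half-to-even then clamp at 0; `site_sd=0`
  yields exactly `site_mean` for every cell.
- `n_cells=0` or an all-zero release is legal and yields all-zero bound
  series (`no_signal`), not an error.
- `n_steps=0` records only the initial state (series of length 1).
- Unknown configuration keys are rejected by name; the affinity-ordering
  constraint is enforced at construction, so no simulation can start from
  an invalid ordering. A tie in thresholds is a violation (strictness).
- CSV output is comma-separated UTF-8 with a fixed column set and
  deterministic row order (step-major, classes LA, MA, HA), written via
  write-then-rename so failures never leave partial files.

## The single-site analytic cross-check

On a 1×1 grid with one cell, one binding site, one factor, recycle fate and
*constant* heparinase (flux off), occupancy at the step boundary is a
two-state Markov chain. Because cleavage is a deterministic threshold, the
per-step detachment probability is the indicator 1[h ≥ θ]: below the
threshold the bound state is absorbing (stationary occupancy 1), at or
above it a factor that binds in event 3 is cleaved in event 4 of the same
step, so recorded occupancy is identically 0. The test suite derives the
stationary vector independently by eigen-decomposition of the end-of-step
transition matrix [[1−p+pq, p(1−q)], [q, 1−q]] and compares the simulated
50,000-step occupancy fraction against it; the only stochastic deviation is
the geometric first-binding time in the absorbing case. A non-degenerate
detachment probability would require either stochastic cleavage or varying
heparinase, both outside the model's stated cleavage rule.

## What the synthetic conditions do and do not show

All inputs are synthetic: the model's purpose is a proof of concept that
affinity-ordered detachment plus site competition reproduces (a) the
sequential resolved pattern under a one-shot release and (b) persistent
stimulator occupancy under continuous inflow. Passing tests show the
mechanism suffices under the default conditions; they do not calibrate real
affinities (the elution data constrain only the ordering — NaCl molarity is
a proxy, so exact heparinase affinities are unretrievable), do not model
vessel formation, platelet biology, diffusion gradients, pH or hypoxia, and
the absolute curve magnitudes and time scales are not comparable to tissue
measurements. Inflow never stops: tumor resolution is out of scope.

## Problem sizes used in the automated checks

The regime checks run the full default conditions (51×51 grid, 10
replicates, 500 steps) for wound healing and tumor presets D and E, with
conservation asserted at every step of every replicate; the Markov
cross-check runs 50,000 steps; unit tests use smaller grids chosen for
clarity of the property under test.
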