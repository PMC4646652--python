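# Methods

## Overview

`grassbird` couples two models. A landowner choice model maps a policy
alternative and a landowner archetype to a land-cover distribution; a
spatially explicit annual-cycle population model maps a set of five
land-cover landscapes to a mean annual growth rate for a migratory
grassland bird population. The pipeline for one consequence-table cell is

policy → preference weights → multi-attribute utilities → softmax cover
distribution → five random landscapes → 30-year population simulation →
geometric mean annual growth rate,

repeated over seeded replicates and averaged.

## Landowner choice model

Each archetype's value system is a weight vector over five objectives
(grassland birds, carbon storage, water quality, financial profit,
biodiversity). The packaged weight table (one row per archetype per
policy, transcribed as elicited) sums to 1 within ±0.02 per row because
the elicited rows carry rounding; rows are renormalized to sum exactly to
1 before use, preserving proportions.

A land cover's score is the weighted sum of per-objective utilities in
[0, 1]. Scores become a per-pixel cover distribution through a softmax
with temperature τ. We expose both behaviors a rational-choice reading
admits — strict utility maximization (deterministic argmax, ties split
uniformly) and probabilistic choice — and make argmax the τ → 0 limit of
the softmax. The default is softmax with τ = 0.02: sharp enough that the
highest-utility cover dominates each archetype's landscape, soft enough
that landscapes remain cover mixtures rather than monocultures.

Each simulated landscape is owned entirely by one archetype; mixed
mosaics are expressible only by editing the weight table via the config's
`weights:` override.

## Landscapes

A landscape is a 40 × 40 grid of 30-m pixels (1.44 km²), each pixel
independently drawn from the cover distribution in row-major order from a
single seeded stream. Five landscapes carry the annual cycle: one
breeding, three stopover, one wintering, all drawn from the same
policy-conditioned distribution (a per-stage distribution hook exists in
the scenario builder's API surface but stage-specific defaults are not
provided, since the consequence analysis does not distinguish stages).

The "one-hectare patch" used for forage quality is the 3 × 3 window of
30-m pixels (0.81 ha), the closest odd-sided square to one hectare.
Neighborhoods are Moore neighborhoods (Chebyshev radius), truncated at
grid edges — no wraparound, because the grids represent bounded tracts.

## Population model

Census point is the start of the breeding season:

N_t = N_{t−1} (1 + R_b) S_f S_w S_s.

Events run breed → fall migrate (3 stopovers in order) → winter → spring
migrate (same stopovers reversed).

**Reproduction.** Each grassland pixel contributes
`nest_density × fledglings_per_successful_nest × nest_survival_base ×
(1 − edge_penalty × f_nonGrass)` expected fledglings at saturation, where
`f_nonGrass` is the non-grassland fraction of its radius-1 Moore
neighborhood. Summed over pixels this gives the landscape's fledgling
potential F_pot; breeding capacity is K_b = k_breeding × (#grass pixels).
Only min(N, K_b) birds breed — overflow simply does not breed — each
producing F_pot/K_b fledglings, so the per-capita rate R_b is constant
below capacity and declines as F_pot/N above it. The constant-below-
capacity form is deliberate: it makes the no-capacity trajectory exactly
geometric, which the test suite uses as a closed-form oracle.

**Stopover survival.** A pixel's occupancy weight is its own per-cover
occupancy times the mean occupancy of its Moore neighborhood (a pixel
must be both found and worth using). Birds settle across pixels in
proportion to occupancy weight up to the stopover capacity
k_stopover × (#grass pixels); settled birds survive with their patch's
forage quality (3 × 3 mean of per-cover survival values); overflow birds
survive at `matrix_survival_floor`. Capacity is an aggregate ceiling, not
a per-pixel one — the simplest form consistent with a habitat-limited
stopover — and abundance is updated between the three sequential stops,
so losses compound and stop order matters when capacity binds.

**Winter survival** is the same settlement scheme but strictly
pixel-level: occupancy has no neighborhood term and survival is the
pixel's own per-cover winter survival.

The soft capacity (overflow survives at a small floor rather than dying
outright) avoids the discontinuities a hard cull would create. A
consequence worth noting: with a nonzero floor, post-season abundance can
slightly exceed the seasonal ceiling when N is far above it; the ceiling
is exact when the floor is zero, and the suite tests it in that regime.

Demography is deterministic (expected values) by default, matching the
smooth replicate means the consequence table reports; Poisson births and
binomial phase survival can be switched on (`simulation.stochastic`).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| τ (choice temperature) | 0.02 | softmax sharpness |
| nest_density_per_grass_pixel | 0.30 | nests per saturated grassland pixel |
| nest_survival_base | 0.188 | egg → independence survival |
| edge_penalty | 0.34 | nest-survival loss per unit non-grass neighborhood |
| fledglings_per_successful_nest | 2.0 | young per successful nest |
| occupancy (G/A/F) | 1.0 / 0.8 / 0.9 | stopover & winter occupancy |
| stopover survival (G/A/F) | 0.9996 / 0.986 / 0.990 | per-stop forage survival |
| winter survival (G/A/F) | 0.965 / 0.929 / 0.940 | over-winter survival |
| k (breed/stop/winter) | 1 / 3 / 2 birds per grass pixel | seasonal capacities |
| matrix_survival_floor | 0.10 | survival of capacity overflow |
| N₀, horizon, replicates | 100, 30 yr, 100 | simulation scale |

The utility matrix, τ, edge penalty, nest survival, and the per-cover
survival levels are **calibrated defaults**: the underlying elicitation recorded only the weight table and
the reference consequence table, not the utilities or demographic rates,
so we fit them within [0, 1] boxes, with the ordering
grassland ≥ forest ≥ agriculture imposed on habitat value, to reproduce
the reference table. The fit preserves the intended ordinal structure:
agriculture dominates financial profit; grassland dominates bird and
biodiversity value; a pure profit-maximizer's landscape is ~84 %
agriculture while a conservationist's is ~78 % grassland. One artifact of
calibration is that grassland's carbon utility ends up marginally above
forest's; the carbon objective carries little weight in any archetype, so
this dimension is weakly identified.

`calibrate_defaults` exposes the same machinery at runtime: a bounded
Powell (derivative-free) search minimizing the Chebyshev (max absolute
cell) error of the 21-cell table against a target, with sign mismatches
penalized so no cell's direction is traded for another's magnitude, a
fixed evaluation budget, and common random numbers so the objective is
deterministic. Sign agreement is a hard requirement: a result that misses
any sign is reported as a failed calibration.

**Identifiability limit.** The weight table gives the profit-maximizing
producer identical weight vectors under public land acquisition, best
management practices, and status quo. Identical weights produce one
expected growth rate, while the reference table lists three distinct
values spanning 0.0148 for those cells; no parameterization of this model
can match all three more closely than half that spread (±0.0074). The
calibrated defaults center the shared value on the midpoint (≈ −0.079),
so the residual on those three cells is the structural floor, and every
other cell fits within ±0.002.

## Reproducibility and numerics

All randomness derives from one base seed through hashed seed sequences
keyed by (cell index, replicate index, landscape slot), so adding
replicates never changes earlier ones and every output is a pure function
of (config, replicates, base seed). Consequence tables and trajectories
are written as UTF-8, LF-terminated CSV with a fixed float format;
repeated runs are byte-identical. Grids round-trip bit-exactly through
the plain-text ESRI ASCII raster format (codes 1 = grassland,
2 = agriculture, 3 = forest).

Degenerate inputs are defined, not special-cased: R_b = 0 when N = 0 or
no grassland exists; survival at N = 0 returns the zero-abundance limit;
extinction gives growth rate −1; zero occupancy everywhere forces the
matrix floor. Ties in the deterministic choice rule split uniformly; ties
in policy ranking break by the canonical policy order.

## What the generator does and does not emulate

Synthetic landscapes are i.i.d. pixel draws — they carry realistic
composition but no spatial autocorrelation (no field-shaped patches,
roads, or riparian strips), and the five landscapes are statistically
identical rather than geographically distinct. The bird model has no age
structure, no density dependence beyond the capacity ceilings, no
between-year carryover effects, and no species-specific parameterization.
Passing tests therefore demonstrate the internal consistency of the
coupled policy → land cover → demography logic and the qualitative
policy ranking structure, not predictions for any real landscape or
species. The replicate dispersion reported alongside each cell reflects
landscape sampling variation only (and demographic stochasticity when
enabled), not parameter uncertainty.

## Problem sizes

Defaults throughout are the study scale: 40 × 40 landscapes, 30-year
horizon, 100 replicates per consequence-table cell, 11 × 50 sweeps for
the grassland response curve. Because rates on a static landscape reduce
to a handful of precomputed aggregates, a full 2100-replicate table runs
in a few seconds on one core.
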