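# Methods

## Model

Agents are individuals aged 65+ moving through the Transtheoretical Model's
stages of change for advance care planning, collapsed to four stages:
pre-contemplation (0), contemplation (1), preparation (2), and a merged
action-maintenance (3). Each agent carries an integer propensity score on a
0–100 scale within its current stage. One tick is one day; published runs
last 1825 ticks (five years).

### Stage machine

Three entry thresholds T₁, T₂, T₃ give the score required to enter
contemplation, preparation, and action-maintenance from the stage directly
below. Each stage has a baseline score b₀..b₃ assigned at initialization and
on every transition into the stage (up or down). Advancement uses s ≥ T:
with the population preset's pre-contemplation baseline of 100 and entry
threshold of 100, a strict inequality would freeze the whole population, so
the threshold is read as "reach", not "exceed". Advancement chains: an agent
entering contemplation at baseline 50 with T₂ = 50 continues immediately to
preparation within the same evaluation. Backsliding happens when an agent's
accumulated net delta would push its score below zero; it drops exactly one
stage per tick onto that stage's baseline, never chaining downward.

Transitions are evaluated only for agents that received a nonzero point
delta during the tick. The trigger is receipt of points, not a change in the
clamped score value: an agent pinned at the 0–100 clamp still re-evaluates
when it gains points. Evaluating unconditionally would be wrong — in the
population preset every pre-contemplator starts at its threshold and would
advance on tick one, susceptible or not, contradicting the frozen-trait
design.

### Within-tick order and delta accumulation

Each tick executes: stage snapshot → movement → patch events → social
influence (using the snapshot) → transition evaluation → recording. All
point deltas accrued in a tick (patch plus social) are summed and applied
with a single clamp; the backslide mark is set iff score + net < 0. Applying
deltas sequentially with intermediate clamps would make outcomes depend on
the order in which co-located partners are visited; the net-sum rule makes
the tick invariant under agent-order permutation, which also makes the whole
simulation vectorizable without changing its semantics. The scalar state
machine (`acpsim.ttm.apply_delta` / `evaluate_transitions`) is the reference
semantics; the vectorized path used by the engine is property-tested against
it exhaustively over all (stage, score, delta) combinations.

### Experiences

Three rectangular patches on a toroidal grid represent life events. Their
relative design follows the model's conception of the events: the personal
ICU stay is the rarest but highest-impact exposure (smallest footprint,
largest points), a loved one's critical illness or death is common but less
impactful (largest footprint, smaller points), and a primary-care visit is
frequent-contact/low-impact per encounter (probability 10%, 1 point). The
primary-care patch is placed nearer the ICU patch than the loved-one patch,
reflecting post-ICU referral into outpatient follow-up. An agent whose cell
lies in footprint k gains pts_k with probability p_k each tick, if
susceptible. Per-encounter probabilities are p_icu = 33%, p_loved = 67%,
p_pcp = 10% in both presets.

### Social influence

Agents sharing a cell interact pairwise. For a pair with stage gap g ≥ 1 the
lower-stage agent gains pts_up · g and the higher-stage agent loses
pts_down · g (gap scaling is linear by default — greater disparity, greater
influence — with a flat mode available). Pre-contemplators receive no upward
pull (they have never considered the behavior); only susceptible agents
receive outcomes; negative social points are the sole backsliding channel.
Stages are compared on the start-of-tick snapshot so results do not depend
on processing order. Interactions fire deterministically on co-location; no
additional probability roll is applied.

An optional annual-update relapse switch (off by default, and off in both
presets) lets susceptible action-maintenance agents drop to preparation with
probability p_skip_update every 365 ticks, modeling failure to review an
advance care plan yearly. The default keeps relapse purely social, which
already lets maintained behavior decay through contact with lower stages.

### Susceptibility

Each agent independently draws an immutable susceptible trait
(Bernoulli(susceptibility/100) at initialization). Non-susceptible agents
are unaffected by every influencing factor, so with annual relapse off their
(stage, score) never changes — the mechanism that pins the population
preset's residual pre-contemplation and contemplation shares near half their
initial values.

## Presets

| quantity | sim1 | sim2 |
|---|---|---|
| initial distribution (%) | 100/0/0/0 | 40/40/20/0 |
| baselines b₀..b₃ | 0,0,0,0 | 100,50,0,50 |
| thresholds T₁,T₂,T₃ | 60,20,100 | 100,50,100 |
| points icu/loved/pcp | 4/3/1 | 6/4/1 |
| social up/down | 3/1 | 2/2 |
| susceptibility (%) | 100 | 50 |
| movement | teleport | local walk, 0.15 cells/day |
| agents / ticks | 200 / 1825 | 200 / 1825 |

The single published action-maintenance threshold (100) is applied to both
presets.

### Geometry calibration

Grid size and footprint rectangles are free parameters (the published tables
fix only the ordinal size relations and the primary-care placement). They
were calibrated once, frozen into the presets, and are not run-time dials.
Two quantitative constraints drove the choice:

- **Patch income must dominate social drag.** A climbing agent entering a
  stage at a low baseline is knocked back whenever accumulated negative
  social points outpace its gains. Expected drag per tick scales with agent
  density (N / cells); expected patch income scales with footprint area ×
  probability × points. sim1's layout (33×33; loved-one 16×16, ICU 8×8,
  primary-care 8×8) gives ≈ 0.55 expected points/tick against ≈ 0.18
  drag/tick at density 0.18, so the idealized population escapes the early
  pre-contemplation/contemplation wavering and completes within five years.
- **Local movement is slow.** At 0.15 cells/day a random walker's five-year
  RMS displacement is ≈ 6 cells, so an agent only ever samples its starting
  neighborhood. For the population preset's susceptible half to complete at
  the observed ≈ 99% rate, beneficial exposure must cover nearly every
  neighborhood: sim2 uses a 50×50 grid whose loved-one patch spans 49×49
  cells, with a one-cell seam holding the ICU (1×3) and primary-care (1×2)
  patches, primary-care nearer the ICU across the torus seam. The low
  density (0.08 agents/cell) keeps social drag small enough that
  action-maintenance agents hover at the score clamp rather than churning.

Intermediate candidate geometries failed in two characteristic ways, both
informative about the model: small dense grids (e.g. 15×15–18×18 at density
0.6–0.9) lose up to 20 percentage points of action-maintenance to
social-drag churn, and sparse layouts strand walkers in empty regions,
inflating the residual early stages.

## Validation oracle

With social influence off and teleport movement, agents are independent and
identically distributed: a susceptible agent is an exact Markov chain on the
404 states (stage, score). The oracle builds the per-tick outcome set
{award from patch k with probability (area_k/cells)·p_k, else nothing}, maps
every state through the scalar transition rules, and iterates the
distribution by dynamic programming, mixing in the frozen non-susceptible
mass. Simulation frequencies at N = 2000 agree with the exact probabilities
within three binomial standard errors at ticks 100, 500, and 1825, which
validates movement, patch encounter, susceptibility gating, and the
transition rules end-to-end.

## Numerical and interface choices

- Scores and point awards are integers; no floating-point tolerances enter
  the dynamics. Stage counts are exact.
- Coordinates are continuous on the half-open torus [0, W) × [0, H); the
  occupied cell is the floor. Cell indices are reduced mod the grid size
  after flooring to guard against boundary rounding.
- Initial stage counts use largest-remainder apportionment with ties broken
  toward the lower stage, so the 40/40/20/0 distribution at N = 200 is the
  exact 80/80/40/0.
- One RNG stream (PCG64) per run with a fixed draw schedule (movement, then
  patch uniforms, each a fixed-size block); replicate r of a batch uses seed
  base + r. Identical (params, seed) give bit-identical trajectories.
- The patch-mate pair rule is evaluated in O(N) per tick from per-cell stage
  histograms; its equivalence to the literal pairwise rule is
  property-tested against brute-force pair enumeration.
- Config files are strict-schema YAML over a named preset base; unknown keys
  are rejected with their path so a misspelled parameter cannot silently
  revert to a default.

## What the model does and does not show

The synthetic population emulates the published study conditions: stage
thresholds, baselines, point awards, susceptibility, and movement are the
printed values, and the free geometry is calibrated to those conditions.
Agents have no families, persistent ties, or demographic attributes;
interactions are transient co-location; only three of the many influences on
advance care planning are represented. Reproducing the published end-state
distributions therefore shows the mechanism is *sufficient* under these
assumptions, not that it drives real ACP behavior — the model's value is
internal validity: controlled, observable, repeatable dynamics for reasoning
about where interventions might act.

Known limitations: outcomes depend on the calibrated geometry (the published
tables do not pin it down); the local-movement regime is diffusion-limited,
so results are sensitive to the movement rate; and the ratio-scale reading
of the threshold/baseline tables (per-stage scores rather than one global
cut-point scale) is one of two readings the source admits — the global-scale
reading cannot reproduce the non-monotone published thresholds (60, 20, 100)
and was rejected.
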