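# Methods

`distylsim` is an individual-based, stochastic simulation of distylous
plants in two parapatric patches. Pollen transfer is modeled grain by
grain, so the reproductive-organ heights that define reciprocal herkogamy
mechanically determine mating success, gene flow between patches, and —
through their genetic architecture — the response to selection.

## Model overview

Two patches of perennial plants sit side by side. Each patch has a
carrying capacity `K` and its own ecological optimum (`theta1 = 0`,
`theta2 = 1`) for a quantitative trait `z` under stabilizing selection of
width `omega`. The patches exchange genes only through pollinator-carried
pollen: during a pollination season, each of `v` events may, with
crossover probability `c`, carry a pollen load to the other patch.

Each plant carries:

- Two bounded floral traits on the corolla-tube axis `[0, 1]`: `x` and
  `y`, which position its stigma and anthers.
- The unbounded ecological trait `z`.
- A morph locus `S` with two states. For `S = 0` the stigma sits at `x`
  and the anthers at `y`; for `S = 1` the organs are swapped. All three
  quantitative traits are diploid (two allele values each; the phenotype
  is the allele mean).
- Seasonal resource budgets: `n_o` ovules, `n_p` pollen grains, and a
  style that saturates after `n_s` received grains.

Mating is governed by complete heteromorphic incompatibility: only
inter-morph, non-self pollen can fertilize. Reciprocal herkogamy — pin
stigmas level with thrum anthers and vice versa — is therefore favored
whenever pollen placement on the pollinator's body is positionally
faithful, and it *emerges* in the model rather than being imposed.

## The annual cycle

Each year runs four phases, in order:

1. **Germination.** Last year's seeds develop their full genotype (see
   *Inheritance*), survive ecological selection with probability
   `exp(-(z - theta)^2 / (2 omega^2))`, and fill the `K - adults` vacant
   slots by uniform lottery. Recruits flower the same year.
2. **Mortality.** Each adult dies independently with probability `m`.
3. **Flower reset.** Budgets return to `n_o`/`n_p`; styles unclog.
4. **Pollination season.** `v` pollination events (below).

There is no juvenile stage and generations overlap; one annual cycle is
the "generation" used in reporting.

## A pollination event

Each event picks a donor patch by fair coin and a donor plant uniformly,
then:

1. **Self-transfer.** The pollinator jostles the flower: each remaining
   grain lands on the plant's own stigma with probability
   `u_s * exp(-d^2 / (2 sigma_s^2))`, where `d` is the plant's
   anther–stigma separation. Selfed grains clog the style but can never
   fertilize (incompatibility); this is the cost of poor herkogamy, and
   it stays active in control mode.
2. **Uptake.** Each remaining grain is removed with probability `u_p`
   (lost to the donor regardless of what happens next). A removed grain's
   height is jittered by `N(0, sigma_j)`; grains jittered outside the
   corolla tube are discarded; surviving grains stick to the pollinator
   with probability `pi(h)`, the patch's pollinator stickiness function.
3. **Crossover.** With probability `c` the load is carried to the other
   patch; the recipient plant is uniform in the recipient patch.
4. **Delivery.** Each carried grain takes a second `N(0, sigma_j)` jitter
   in transit and is received with probability
   `exp(-(h - stigma)^2 / (2 sigma_p^2))` — positional delivery against
   the recipient's stigma height. Non-received grains are lost.
5. **Clogging and fertilization.** Every received grain increments the
   style's clogging count `s`, compatible or not. A compatible
   (inter-morph, non-self) grain fertilizes one ovule with probability
   `max(0, 1 - s0/n_s)` (`s0` = clogging before that grain) while
   unfertilized ovules remain. Each fertilizing grain is an independent
   paternal gamete of the donor.

**Control mode** removes all positional structure from transfer: no
height jitter, no out-of-tube discard, no stickiness filter, and every
carried grain is received regardless of stigma height. Self-transfer and
style clogging stay active. Control mode is therefore invariant to which
pollinator functions are configured (checked by the acceptance suite).

## Pollinator stickiness functions

`pi(h)` maps corolla height to the probability a grain sticks:

- `uniform`: 1 everywhere.
- `high_biased`: 0 at or below a threshold (0.5), rising linearly to 1
  at the tube top.
- `bimodal_low` / `bimodal_high`: two unit-amplitude Gaussian bumps
  (SD 0.06) at heights 0.20/0.65 and 0.35/0.80 respectively, summed and
  clipped to 1. The two bimodal pollinators offer the same two-band
  structure displaced by 0.15, creating divergent sexual selection on
  organ heights between patches.

Experimental designs pair patch-specific pollinators
(`uniform`/`high_biased` or `bimodal_low`/`bimodal_high`) against the
position-blind control.

## Inheritance

Every trait is diploid. A pollen grain carries one paternal allele per
trait, chosen uniformly from the father's pair at fertilization
(unmutated). At germination the maternal gamete is drawn the same way and
*both* transmitted allele sets are mutated: each allele independently
with probability `mu`, adding a `N(0, alpha)` deviation; `x` and `y`
alleles are clipped to the tube `[0, 1]`, `z` is unbounded. The morph of
the offspring is a fair coin between the parental morphs — under obligate
inter-morph mating this is exactly the Mendelian `Ss x ss` backcross of a
distylous S-locus, keeping the morph ratio at 1:1 (verified by an exact
binomial test at n = 10^4).

Explicit segregation makes the genetic system conserve additive variance
under random mating instead of eroding it as blending inheritance would;
this matters for whether divergence can proceed at realistic speed.

## Initialization

Both patches start monomorphic in organ position: every plant has
`x = y = 0.5` plus independent `N(0, var_xy_init)` allelic noise (clipped
to the tube), `z = 0.5` exactly, and a fair-coin morph. Reciprocal
herkogamy and ecological divergence must both emerge.

## Metrics

All metrics are evaluated on the final year of a realization:

- **Ecological divergence** `D = |zbar1 - zbar2|` (the optima gap is 1,
  so `D` is a fraction of the gap).
- **Isolation at fertilization** `I` = fraction of fertilized ovules
  sired by same-patch fathers, per patch.
- **Local adaptation** `A = 1 - 2|zbar - theta_own| / |gap|` (+1 at the
  local optimum, −1 at the foreign one, unclamped).
- **Female function** `F` = percentage of ovules fertilized by season's
  end, per patch.
- **Dimorphism index**: morph-conditioned mean stigma and anther heights;
  when the stigma difference and anther difference between morphs have
  opposite signs (reciprocity), the index is the smaller absolute
  difference, else 0. The emergence year `t_dim` is the first year the
  index exceeds 0.2. Polarity (which morph becomes the pin) is the sign
  of the stigma difference.
- **Organ mismatch** `M`: between-patch difference in the mean heights of
  corresponding organ levels (upper/lower), paired by level so the
  comparison is meaningful whatever polarity each patch settled on.

## Experimental design

`GridSpec` expands a Cartesian grid over `sigma_j`, `c`, `omega` and
pollinator setting with `replicates` seeds per combination. The full
design is 3 × 8 × 4 × 3 = 288 combinations × 150 replicates = 43,200
realizations of 10,000 years each — a cluster job, checked structurally
but not executed in the test suite. Per-realization seeds come from a
splitmix64-style hash of (base seed, combination index, replicate index):
reproducible, order-independent, and collision-free across the full grid
(verified). Treatment and control arms pair on (combination, replicate)
indices; comparisons are between arm means.

**Desk scale.** `scenario_presets(name, "desk")` shrinks the design so it
runs on one CPU in minutes: `K = 250`, `v = 2500` (preserving the
visits-per-plant rate `v/2K` and all per-flower budgets), 1500 years,
10 replicates, and the swept values restricted to each scenario's
best-case conditions. The `emergence` preset (dimorphism emergence) stays at
full size (`K = 1000`, `v = 10000`) because emergence happens within a
few hundred years.

## Numerical implementation

The whole realization loop is compiled with numba (`_engine.py`); the
object-level API in `lifecycle.py`/`pollination.py` drives the same
compiled kernels for small-scale and diagnostic work. Two RNG streams
are used inside the engine, both seeded from the realization seed:
numba's MT19937 for binomial counts and integer picks, and an inline
xoshiro256\*\* generator (splitmix64-seeded, with a ziggurat normal
sampler) for per-grain scalar draws, where call overhead dominates. The
xoshiro and ziggurat implementations are verified against reference
sequences and distributional tests in the suite. Trajectories are
bit-reproducible for a given seed and package version.

Two exact optimizations keep the inner loop cheap: per-grain binomial
thinning replaces explicit per-grain loops wherever a count suffices, and
germination draws the `x`/`y` alleles and morph only for lottery winners
(`z` and survival are drawn for every seed first; since `x`/`y` gametes
are independent of `z` and of survival, the recruited population's
distribution is unchanged).

## Limitations

- The desk-scale presets trade statistical power for runtime: at
  `K = 250`, genetic drift contributes more between-patch divergence in
  control arms, and 1500 years can leave slow treatment divergence
  incomplete. Effect *orderings* are preserved; effect *sizes* at desk
  scale can undershoot full-scale values.
- Patches are panmictic internally; there is no spatial structure below
  the patch, no seed dispersal between patches, and exactly one
  pollinator type per patch.
- The S-locus is modeled as a morph state with fair-coin inheritance,
  valid under strict inter-morph mating (which complete incompatibility
  guarantees); relaxing incompatibility would require explicit S-locus
  genetics.
- Selfed pollen clogs but never fertilizes; partial self-compatibility
  and inbreeding depression are out of scope.
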