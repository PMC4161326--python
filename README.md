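# distylsim

Individual-based simulation of distylous plants in two parapatric
patches, with pollen transfer modeled grain by grain.

## The scientific problem

Distylous plants come in two morphs — pins (high stigma, low anthers) and
thrums (the reverse) — with *reciprocal herkogamy*: each morph's anthers
sit level with the other morph's stigma. Combined with heteromorphic
incompatibility (only inter-morph pollen fertilizes), this makes floral
geometry a mechanical determinant of mating: where a pollen grain sits on
a pollinator's body decides whose stigma it can reach.

That mechanical coupling turns organ height into a potential "magic
trait". If two adjacent populations host pollinators that hold pollen at
different heights, sexual selection pushes their floral organs apart,
which reduces cross-population fertilization as a by-product — assortative
mating and local adaptation through one mechanism. Conversely, if pollen
placement is sloppy, positional information is destroyed and the same
machinery can *hinder* divergence maintained by ecological selection.

`distylsim` simulates this explicitly: every pollen grain is picked up,
jittered, filtered by pollinator stickiness, possibly carried to the
other patch, and delivered positionally against a stigma. Reciprocal
herkogamy is not imposed; it emerges. See `docs/methods.md` for the full
model and `notes` in each module docstring for implementation contracts.

## Worked example: distyly emerging from a monomorphic population

`examples/emergence_of_distyly.py` runs one full-size control
realization (K = 1000, v = 10000) from a monomorphic start (all organs
mid-tube) and prints the dimorphism index over time:

```
$ python examples/emergence_of_distyly.py
year   dim(patch1)  dim(patch2)
   1        0.000       0.000
  25        0.014       0.018
  50        0.054       0.047
  75        0.150       0.071
 100        0.252       0.101
 150        0.382       0.267
 200        0.460       0.392
 300        0.470       0.468

dimorphism criterion (index > 0.2) first met: patch 1 year 87, patch 2 year 132
final dimorphism index: 0.470 / 0.468
polarity (which morph is the pin): -1 / +1  (a fair coin across replicates)
```

Both patches evolve reciprocal herkogamy from scratch within one to two
hundred years; which morph becomes the pin is decided by drift.

Other examples: `examples/pollinator_driven_divergence.py` (paired
treatment/control sweep showing pollinator-driven ecological divergence)
and `examples/delivery_height_diagnostics.py` (how placement noise erases
positional information).

## Library in one glance

```python
from distylsim import Params, run_realization

params = Params(K=1000, v=10000, years=300, sigma_j=0.1, c=0.0,
                omega=0.3, control=True, seed=42)
res = run_realization(params, time_series=True)
print(res.metrics.dim1, res.metrics.t_dim1)   # 0.470..., 87
```

`GridSpec`/`run_sweep` run replicated parameter grids into tidy +
aggregated tables; `scenario_presets` provides the named experimental
designs at `"desk"` (minutes) or `"full"` (cluster job) scale.

## Command line

```bash
distylsim run --k 1000 --v 10000 --years 300 --seed 42 \
  --sigma-j 0.1 --c 0 --omega 0.3 --control --out metrics.json
distylsim preset scenario1 --scale desk --out s1     # tidy + aggregate CSV
distylsim sweep --spec grid.yaml --out mygrid
distylsim diagnose --sigma-j 0.5 --out heights.csv   # delivery histogram
```

## Reproduction

- `pytest -q` runs the full suite. Unit and property tests (conservation
  identities, exact Mendelian segregation, closed-form kernels, RNG
  reference vectors) run first; the acceptance tests
  (`tests/test_acceptance.py`) then rerun the scaled-down scenario
  designs end to end and check the headline effects at their stated
  thresholds.
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the dimorphism-emergence time (mean first year the
  dimorphism index exceeds 0.2, ten control realizations at K = 1000)
  from scratch and writes it as JSON.
- The full 43,200-realization design is expanded (and its seed policy
  verified collision-free) by the test suite, but executing it is a
  cluster job, deliberately outside the tests.
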