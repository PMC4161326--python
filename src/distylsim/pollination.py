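"""The per-event pollen transfer engine and the pollinator functions.

A pollination event runs: donor choice, self-transfer (the pollinator
jostling the flower), grain-by-grain uptake with height jitter and
stickiness, possible crossover to the other patch, positional delivery onto
the recipient's stigma, style clogging, and fertilization.  Control mode
disables the pollinator function, the height jitter/discard at pickup, and
positional delivery -- transfer becomes completely position-blind -- while
self-transfer and clogging stay active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _engine
from ._engine import (POL_UNIFORM, POL_HIGH_BIASED, POL_BIMODAL_LOW,
                      POL_BIMODAL_HIGH)
from .genetics import GameteContribution, SeedRecord, draw_gamete

_KIND_CODES = {
    "uniform": POL_UNIFORM,
    "high_biased": POL_HIGH_BIASED,
    "bimodal_low": POL_BIMODAL_LOW,
    "bimodal_high": POL_BIMODAL_HIGH,
}

# default shape parameters per kind: (q0, q1, q2)
#  - high_biased: q0 = threshold height below which stickiness is 0
#  - bimodal_*: q0, q1 = bump centers, q2 = bump SD (unit amplitude)
# The two bimodal pollinators each offer two well-separated sticky bands
# (supporting reciprocal herkogamy) offset by 0.15 between pollinators
# (creating divergent sexual selection on organ heights).
_KIND_DEFAULTS = {
    "uniform": (0.0, 0.0, 0.0),
    "high_biased": (0.5, 0.0, 0.0),
    "bimodal_low": (0.20, 0.65, 0.06),
    "bimodal_high": (0.35, 0.80, 0.06),
}


@dataclass(frozen=True)
class PollinatorFunction:
    """A stickiness function pi(h) on corolla-tube heights."""

    kind: str
    q0: float = 0.0
    q1: float = 0.0
    q2: float = 0.0

    @property
    def code(self) -> int:
        return _KIND_CODES[self.kind]

    def qvec(self) -> np.ndarray:
        return np.array([self.q0, self.q1, self.q2])

    def __call__(self, h: float) -> float:
        return stickiness(self, h)


def as_pollinator(spec, **overrides) -> PollinatorFunction:
    """Coerce a specifier ('uniform', 'high_biased', 'bimodal_low',
    'bimodal_high', or a PollinatorFunction) to a PollinatorFunction.

    Keyword overrides replace the decided shape parameters (``threshold``
    for high_biased; ``centers`` and ``width`` for the bimodal kinds).
    """
    if isinstance(spec, PollinatorFunction):
        return spec
    if spec not in _KIND_CODES:
        raise ValueError(
            f"unknown pollinator kind {spec!r}; expected one of "
            f"{sorted(_KIND_CODES)}")
    q0, q1, q2 = _KIND_DEFAULTS[spec]
    if "threshold" in overrides:
        q0 = overrides.pop("threshold")
    if "centers" in overrides:
        q0, q1 = overrides.pop("centers")
    if "width" in overrides:
        q2 = overrides.pop("width")
    if overrides:
        raise ValueError(f"unknown overrides {sorted(overrides)}")
    return PollinatorFunction(spec, q0, q1, q2)


def stickiness(pollinator, h: float) -> float:
    """Probability that a grain at height h sticks to the pollinator."""
    pf = as_pollinator(pollinator)
    return float(_engine.stickiness_core(pf.code, h, pf.q0, pf.q1, pf.q2))


def gaussian_kernel(delta: float, scale: float) -> float:
    """exp(-delta^2 / (2 scale^2)); positional transfer kernel."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return float(_engine.gaussian_kernel(delta, scale))


@dataclass
class PollenGrain:
    """A transported gamete: paternal values plus its current height."""

    father: GameteContribution
    height: float
    donor_id: int = -1


@dataclass
class EventLog:
    """Per-event bookkeeping (diagnostics; conservation checks)."""

    removed: int = 0
    discarded: int = 0
    not_stuck: int = 0
    stuck: int = 0
    delivered: int = 0   # received by the stigma
    fertilized: int = 0
    selfed: int = 0
    donor_patch: int = 0
    recipient_patch: int = 0


def _maybe_seed(seed: Optional[int]) -> None:
    if seed is not None:
        _engine.seed_rng(int(seed) % (2**31))


def self_transfer(plant, params, seed: Optional[int] = None) -> int:
    """Jostle ``count`` of the plant's remaining grains onto its own stigma.

    Per-grain probability u_s * exp(-sep^2 / (2 sigma_s^2)) where sep is the
    anther-stigma separation.  Decrements p, increments the clogging index
    s; never fertilizes.  Active in control mode too.
    """
    _maybe_seed(seed)
    from .model_core import anther_height, stigma_height
    sep = abs(anther_height(plant) - stigma_height(plant))
    n = int(_engine.self_transfer_count(plant.p, sep, params.u_s,
                                        params.sigma_s))
    plant.p -= n
    plant.s += n
    return n


def pollen_uptake(donor, pollinator, params,
                  seed: Optional[int] = None) -> list[PollenGrain]:
    """Remove grains from the donor and return those stuck to the pollinator.

    Every grain is removed independently with probability u_p and is lost
    to the donor whether or not it sticks.  Removed grains are jittered in
    height (SD sigma_j), discarded if they leave the corolla tube, and then
    stick with probability pi(height).  In control mode every removed grain
    is transported, with no jitter, discard, or stickiness filter.
    """
    _maybe_seed(seed)
    from .model_core import anther_height
    pf = as_pollinator(pollinator) if pollinator is not None \
        else as_pollinator("uniform")
    buf = np.empty(max(donor.p, 1))
    nrem, nstuck = _engine.uptake_core(
        donor.p, anther_height(donor), params.u_p, params.sigma_j,
        params.control, pf.code, pf.q0, pf.q1, pf.q2, buf, _engine.RS)
    donor.p -= int(nrem)
    # each grain is a distinct gamete of the donor
    return [PollenGrain(father=draw_gamete(donor), height=float(buf[k]),
                        donor_id=donor.id) for k in range(nstuck)]


def deliver_grain(grain: PollenGrain, recipient, params,
                  seed: Optional[int] = None) -> bool:
    """Second height jitter and positional receipt at the stigma.

    Received with probability exp(-(final - stigma)^2 / (2 sigma_p^2));
    always received in control mode.  Non-received grains are lost.
    """
    _maybe_seed(seed)
    from .model_core import stigma_height
    return bool(_engine.deliver_core(grain.height, stigma_height(recipient),
                                     params.sigma_j, params.sigma_p,
                                     params.control, _engine.RS))


def receive_on_stigma(recipient, grain: PollenGrain, params,
                      seed: Optional[int] = None) -> Optional[SeedRecord]:
    """Clog the style with one received grain and possibly fertilize.

    Every received grain increments the clogging index s, compatible or
    not.  A compatible grain fertilizes with probability
    max(0, 1 - s0/n_s) (s0 = clogging before this grain) while unfertilized
    ovules remain.
    """
    _maybe_seed(seed)
    s0 = recipient.s
    recipient.s += 1
    if not _engine.compatible_core(grain.father.S_f, recipient.S,
                                   grain.donor_id, recipient.id):
        return None
    if recipient.o <= 0:
        return None
    pf = _engine.fertilization_prob(s0, params.n_s)
    if pf <= 0.0 or _engine.runif() >= pf:
        return None
    recipient.o -= 1
    return SeedRecord(mother_id=recipient.id,
                      x_alleles=recipient.x_alleles,
                      y_alleles=recipient.y_alleles,
                      z_alleles=recipient.z_alleles,
                      S=recipient.S, father=grain.father,
                      resident_father=(grain.father.origin_patch
                                       == recipient.patch))


# --- array bridge: run the compiled event/season on Patch objects ---------

def _patches_to_arrays(patch1, patch2, params):
    n1, n2 = len(patch1.adults), len(patch2.adults)
    K = max(n1, n2, 1)
    arr = {}
    x1 = np.zeros((2, K))
    x2 = np.zeros((2, K))
    y1 = np.zeros((2, K))
    y2 = np.zeros((2, K))
    z1 = np.zeros((2, K))
    z2 = np.zeros((2, K))
    S = np.zeros((2, K), dtype=np.int8)
    o = np.zeros((2, K), dtype=np.int32)
    p = np.zeros((2, K), dtype=np.int32)
    s = np.zeros((2, K), dtype=np.int32)
    n = np.array([n1, n2], dtype=np.int64)
    for pt, patch in enumerate((patch1, patch2)):
        for i, pl in enumerate(patch.adults):
            x1[pt, i], x2[pt, i] = pl.x_alleles
            y1[pt, i], y2[pt, i] = pl.y_alleles
            z1[pt, i], z2[pt, i] = pl.z_alleles
            S[pt, i], o[pt, i], p[pt, i], s[pt, i] = pl.S, pl.o, pl.p, pl.s
    cap = K * params.n_o
    arr.update(x1=x1, x2=x2, y1=y1, y2=y2, z1=z1, z2=z2,
               S=S, o=o, p=p, s=s, n=n,
               smx1=np.zeros((2, cap)), smx2=np.zeros((2, cap)),
               smy1=np.zeros((2, cap)), smy2=np.zeros((2, cap)),
               smz1=np.zeros((2, cap)), smz2=np.zeros((2, cap)),
               smS=np.zeros((2, cap), dtype=np.int8),
               sfx=np.zeros((2, cap)), sfy=np.zeros((2, cap)),
               sfz=np.zeros((2, cap)),
               sfS=np.zeros((2, cap), dtype=np.int8),
               sres=np.zeros((2, cap), dtype=np.int8),
               smidx=np.zeros((2, cap), dtype=np.int32),
               nseeds=np.zeros(2, dtype=np.int64),
               fert_res=np.zeros(2, dtype=np.int64),
               fert_mig=np.zeros(2, dtype=np.int64),
               removed=np.zeros((2, K), dtype=np.int64),
               selfed=np.zeros((2, K), dtype=np.int64),
               received=np.zeros((2, K), dtype=np.int64),
               buf=np.empty(params.n_p))
    return arr


_STATE_KEYS = ("x1", "x2", "y1", "y2", "z1", "z2", "S", "o", "p", "s", "n",
               "smx1", "smx2", "smy1", "smy2", "smz1", "smz2", "smS",
               "sfx", "sfy", "sfz", "sfS", "sres", "smidx", "nseeds",
               "fert_res", "fert_mig", "removed", "selfed", "received",
               "buf")


def _sync_back(arr, patch1, patch2):
    for pt, patch in enumerate((patch1, patch2)):
        for i, pl in enumerate(patch.adults):
            pl.o = int(arr["o"][pt, i])
            pl.p = int(arr["p"][pt, i])
            pl.s = int(arr["s"][pt, i])
        for k in range(int(arr["nseeds"][pt])):
            mother = patch.adults[int(arr["smidx"][pt, k])]
            father = GameteContribution(
                x_f=float(arr["sfx"][pt, k]), y_f=float(arr["sfy"][pt, k]),
                z_f=float(arr["sfz"][pt, k]), S_f=int(arr["sfS"][pt, k]),
                origin_patch=(pt + 1) if arr["sres"][pt, k] else (2 - pt))
            patch.seeds.append(SeedRecord(
                mother_id=mother.id,
                x_alleles=(float(arr["smx1"][pt, k]),
                           float(arr["smx2"][pt, k])),
                y_alleles=(float(arr["smy1"][pt, k]),
                           float(arr["smy2"][pt, k])),
                z_alleles=(float(arr["smz1"][pt, k]),
                           float(arr["smz2"][pt, k])),
                S=int(arr["smS"][pt, k]), father=father,
                resident_father=bool(arr["sres"][pt, k])))
        patch.fert_resident += int(arr["fert_res"][pt])
        patch.fert_migrant += int(arr["fert_mig"][pt])


def pollination_event(patches, params, seed: Optional[int] = None) -> None:
    """Run a single pollination event on a (patch1, patch2) pair in place."""
    _maybe_seed(seed)
    patch1, patch2 = patches
    fp, ip, polkind, polq = params._pack()
    arr = _patches_to_arrays(patch1, patch2, params)
    state = tuple(arr[k] for k in _STATE_KEYS)
    _engine.event_core(fp, params.control, params.n_s, polkind, polq,
                       *state, _engine.RS)
    _sync_back(arr, patch1, patch2)


@dataclass
class SeasonSummary:
    """Per-patch outcome of one pollination season."""

    fert_resident: tuple
    fert_migrant: tuple
    mean_remaining_o: tuple
    seeds: tuple
    removed: tuple = field(default=(0, 0))
    selfed: tuple = field(default=(0, 0))
    received: tuple = field(default=(0, 0))


def run_season(patches, params, seed: Optional[int] = None) -> SeasonSummary:
    """Run the v pollination events of one season on a patch pair in place.

    Assumes flowers have been reset (o = n_o, p = n_p, s = 0) beforehand.
    """
    _maybe_seed(seed)
    patch1, patch2 = patches
    fp, ip, polkind, polq = params._pack()
    arr = _patches_to_arrays(patch1, patch2, params)
    state = tuple(arr[k] for k in _STATE_KEYS)
    _engine.season_core(fp, ip, polkind, polq, *state, _engine.RS)
    _sync_back(arr, patch1, patch2)
    n = arr["n"]
    mean_o = tuple(float(arr["o"][pt, :n[pt]].mean()) if n[pt] else float("nan")
                   for pt in range(2))
    return SeasonSummary(
        fert_resident=tuple(int(v) for v in arr["fert_res"]),
        fert_migrant=tuple(int(v) for v in arr["fert_mig"]),
        mean_remaining_o=mean_o,
        seeds=tuple(int(v) for v in arr["nseeds"]),
        removed=tuple(int(arr["removed"][pt, :n[pt]].sum()) for pt in range(2)),
        selfed=tuple(int(arr["selfed"][pt, :n[pt]].sum()) for pt in range(2)),
        received=tuple(int(arr["received"][pt, :n[pt]].sum())
                       for pt in range(2)))


def delivery_heights(anther: float, pollinator, sigma_j: float,
                     n_grains: int = 100000, seed: int = 0) -> np.ndarray:
    """Sample final delivery heights of grains picked up at a given anther.

    Implements the pickup-side pipeline independently of the compiled
    engine (numpy Generator): jitter at pickup, discard outside the tube,
    stickiness filter, second jitter in transit.  Used for delivery-height
    diagnostics and as a cross-check of the transfer pipeline.
    """
    rng = np.random.default_rng(seed)
    pf = as_pollinator(pollinator)
    h1 = anther + rng.normal(0.0, sigma_j, n_grains)
    h1 = h1[(h1 >= 0.0) & (h1 <= 1.0)]
    probs = np.array([stickiness(pf, h) for h in h1])
    h1 = h1[rng.random(h1.size) < probs]
    return h1 + rng.normal(0.0, sigma_j, h1.size)
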