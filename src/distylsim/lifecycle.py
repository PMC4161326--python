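"""The annual cycle and the full-realization loop.

Each year runs: germination (last year's seeds become seedlings, survive
stabilizing ecological selection, and fill vacant adult slots by lottery up
to the carrying capacity), adult mortality, a seasonal flower reset, and
the pollination season.  New recruits flower and face mortality the same
year; there is no juvenile stage.  A "generation" in reporting is one such
annual cycle -- the plants are perennial, so generations overlap.

`run_realization` executes the whole loop in compiled code; the op-level
functions below act on the Plant/Patch containers for small-scale and
diagnostic use and share the same compiled cores for every model rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _engine, metrics
from .genetics import _offspring_alleles
from .metrics import MetricsRecord
from .model_core import Params, Plant


def ecological_fitness(z: float, theta: float, omega: float) -> float:
    """Seedling survival probability exp(-(z-theta)^2 / (2 omega^2))."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    return float(_engine.eco_fitness(z, theta, omega))


def _maybe_seed(seed: Optional[int]) -> None:
    if seed is not None:
        _engine.seed_rng(int(seed) % (2**31))


def germination(patch, params: Params, seed: Optional[int] = None) -> int:
    """Recruit from the patch's stored seeds; returns the number recruited.

    Every seed becomes an offspring genotype, survives with its ecological
    fitness, and surviving seedlings fill the K - adults vacant slots by
    uniform lottery.  The seed store is cleared.
    """
    _maybe_seed(seed)
    survivors = []
    for seed_rec in patch.seeds:
        g = _offspring_alleles(seed_rec, seed_rec.father, params)
        cx1, cx2, cy1, cy2, cz1, cz2, cS = g
        w = _engine.eco_fitness(0.5 * (cz1 + cz2), patch.theta, params.omega)
        if _engine.runif() < w:
            survivors.append(g)
    patch.seeds = []
    free = params.K - len(patch.adults)
    take = min(free, len(survivors))
    # uniform lottery: partial Fisher-Yates driven by the engine stream
    for i in range(take):
        j = i + int(_engine.runif() * (len(survivors) - i))
        survivors[i], survivors[j] = survivors[j], survivors[i]
        cx1, cx2, cy1, cy2, cz1, cz2, cS = survivors[i]
        patch.adults.append(Plant(
            id=(patch.index - 1) * params.K * 1000 + len(patch.adults),
            patch=patch.index, x_alleles=(cx1, cx2), y_alleles=(cy1, cy2),
            z_alleles=(cz1, cz2), S=int(cS),
            o=params.n_o, p=params.n_p, s=0))
    return take


def mortality(patch, params: Params, seed: Optional[int] = None) -> int:
    """Kill each adult independently with probability m; returns deaths."""
    _maybe_seed(seed)
    deaths = 0
    for i in range(len(patch.adults) - 1, -1, -1):
        if _engine.runif() < params.m:
            patch.adults.pop(i)
            deaths += 1
    return deaths


def reset_flowers(patch, params: Params) -> None:
    """Start a new season: full ovule and pollen budgets, unclogged styles."""
    for pl in patch.adults:
        pl.o = params.n_o
        pl.p = params.n_p
        pl.s = 0
    patch.fert_resident = 0
    patch.fert_migrant = 0


_TS_COLUMNS = ["adults", "seeds", "zbar", "stigma_S0", "stigma_S1",
               "anther_S0", "anther_S1", "fert_resident", "fert_migrant",
               "mean_o", "dim_index"]


@dataclass
class RealizationResult:
    """Everything `run_realization` measures."""

    metrics: MetricsRecord
    census: dict                      # final adult arrays per patch
    time_series: Optional[pd.DataFrame] = None


def run_realization(params: Params, *, time_series: bool = False,
                    dim_threshold: float = 0.2,
                    early_stop_on_dimorphism: bool = False
                    ) -> RealizationResult:
    """Run one full realization in compiled code and evaluate the metrics.

    Metrics are computed on the final year: isolation and female function
    from the final season's tallies, trait-based metrics from the final
    adult census.  `dim_threshold` is the reciprocal-dimorphism criterion
    used for the t_dim timing fields; with `early_stop_on_dimorphism` the
    run ends as soon as both patches have met it.
    """
    fp, ip, polkind, polq = params._pack()
    ip = ip.copy()
    ip[_engine.I_EARLY] = 1 if early_stop_on_dimorphism else 0
    (x, y, z, S, o, p, s, n, ts, tdim, extinct, years_run, nclip,
     fert_res, fert_mig, removed, selfed, received, smidx, sres,
     nseeds) = _engine.simulate(fp, ip, polkind, polq, dim_threshold)

    census = {}
    for pt in range(2):
        census[pt + 1] = dict(
            x=x[pt, :n[pt]].copy(), y=y[pt, :n[pt]].copy(),
            z=z[pt, :n[pt]].copy(), S=S[pt, :n[pt]].copy(),
            o=o[pt, :n[pt]].copy(), p=p[pt, :n[pt]].copy(),
            s=s[pt, :n[pt]].copy(),
            removed=removed[pt, :n[pt]].copy(),
            selfed=selfed[pt, :n[pt]].copy(),
            received=received[pt, :n[pt]].copy())
    census["n_clipped_at_init"] = int(nclip)
    census["seed_mother_idx"] = tuple(
        smidx[pt, :nseeds[pt]].copy() for pt in range(2))
    census["seed_resident"] = tuple(
        sres[pt, :nseeds[pt]].copy() for pt in range(2))

    nan = float("nan")
    alive = extinct == 0 and n[0] > 0 and n[1] > 0
    morphs_lost = False
    dims = [nan, nan]
    pols = [0, 0]
    if alive:
        for pt in range(2):
            cen = census[pt + 1]
            try:
                dims[pt], pols[pt] = metrics.dimorphism_index(
                    cen["x"], cen["y"], cen["S"])
            except ValueError:
                morphs_lost = True
        zbar = [float(z[pt, :n[pt]].mean()) for pt in range(2)]
        D = metrics.ecological_divergence(zbar[0], zbar[1])
        A1 = metrics.local_adaptation(zbar[0], params.theta1, params.theta2)
        A2 = metrics.local_adaptation(zbar[1], params.theta2, params.theta1)
        iso = [nan, nan]
        for pt in range(2):
            try:
                iso[pt] = metrics.isolation_at_fertilization(
                    int(fert_res[pt]), int(fert_mig[pt]))
            except ValueError:
                pass
        F = [metrics.female_function(float(o[pt, :n[pt]].mean()), params.n_o)
             for pt in range(2)]
        if not morphs_lost:
            M = metrics.organ_mismatch(
                (census[1]["x"], census[1]["y"], census[1]["S"]),
                (census[2]["x"], census[2]["y"], census[2]["S"]))
        else:
            M = nan
    else:
        D = A1 = A2 = M = nan
        iso = [nan, nan]
        F = [nan, nan]

    record = MetricsRecord(
        D=D, I1=iso[0], I2=iso[1], M=M, A1=A1, A2=A2, F1=F[0], F2=F[1],
        dim1=dims[0], dim2=dims[1],
        t_dim1=int(tdim[0]) if tdim[0] > 0 else None,
        t_dim2=int(tdim[1]) if tdim[1] > 0 else None,
        polarity1=pols[0], polarity2=pols[1],
        extinct=int(extinct), morphs_lost=morphs_lost,
        years_run=int(years_run),
        params=dict(K=params.K, v=params.v, years=params.years,
                    sigma_j=params.sigma_j, c=params.c, omega=params.omega,
                    control=params.control, seed=params.seed))

    frame = None
    if time_series:
        rows = []
        for yr in range(ts.shape[0]):
            for pt in range(2):
                row = {"year": yr + 1, "patch": pt + 1}
                row.update({col: ts[yr, pt, k]
                            for k, col in enumerate(_TS_COLUMNS)})
                rows.append(row)
        frame = pd.DataFrame(rows)
    return RealizationResult(metrics=record, census=census, time_series=frame)
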