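"""Outcome statistics computed from realization state.

All functions here are pure: they consume a final-year census (trait
arrays) or the final season's fertilization tallies and return numbers,
with no randomness involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class MetricsRecord:
    """Per-realization outcomes evaluated on the final year."""

    D: float                 # ecological divergence |zbar1 - zbar2|
    I1: float                # isolation at fertilization, patch 1
    I2: float
    M: float                 # organ mismatch (height units)
    A1: float                # local adaptation, patch 1 (<= +1)
    A2: float
    F1: float                # female function, % ovules filled
    F2: float
    dim1: float              # dimorphism index per patch
    dim2: float
    t_dim1: Optional[int]    # first year the dimorphism criterion was met
    t_dim2: Optional[int]
    polarity1: int           # sign of the stigma-height difference S0 - S1
    polarity2: int
    extinct: int             # 0 none; 1 or 2: that patch emptied
    morphs_lost: bool        # some patch ended without both morphs
    years_run: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("D", "I1", "I2", "M", "A1", "A2", "F1", "F2", "dim1", "dim2",
              "t_dim1", "t_dim2", "polarity1", "polarity2", "extinct",
              "morphs_lost", "years_run")}
        d.update(self.params)
        return d


def ecological_divergence(zbar1: float, zbar2: float) -> float:
    """|zbar1 - zbar2|: with unit optima gap, the fraction of the gap."""
    return abs(zbar1 - zbar2)


def isolation_at_fertilization(resident_ferts: int, migrant_ferts: int) -> float:
    """Fraction of fertilized ovules sired by resident (same-patch) pollen."""
    total = resident_ferts + migrant_ferts
    if total <= 0:
        raise ValueError("no fertilizations: isolation undefined")
    return resident_ferts / total


def local_adaptation(zbar: float, theta_own: float, theta_other: float) -> float:
    """Scaled adaptation: +1 at the local optimum, -1 at the other patch's.

    1 - 2|zbar - theta_own| / |theta_other - theta_own|, not clamped
    (overshoot past the foreign optimum reports < -1 as-is).
    """
    gap = abs(theta_other - theta_own)
    if gap == 0:
        raise ValueError("identical optima: local adaptation undefined")
    return 1.0 - 2.0 * abs(zbar - theta_own) / gap


def female_function(mean_remaining_o: float, n_o: int) -> float:
    """Percentage of available ovules filled by season's end."""
    if n_o <= 0:
        raise ValueError("n_o must be positive")
    return 100.0 * (n_o - mean_remaining_o) / n_o


def _morph_means(x, y, S):
    """Morph-conditioned mean organ heights.

    Returns (stigma_mean_S0, anther_mean_S0, stigma_mean_S1, anther_mean_S1).
    Stigma sits at x for S=0 and at y for S=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    S = np.asarray(S)
    m0 = S == 0
    m1 = S == 1
    if not m0.any() or not m1.any():
        raise ValueError("both morphs required")
    return (x[m0].mean(), y[m0].mean(), y[m1].mean(), x[m1].mean())


def dimorphism_index(x, y, S) -> tuple[float, int]:
    """Reciprocal-herkogamy dimorphism index of one census.

    dstigma = mean stigma height of morph S=0 minus that of S=1; danther
    likewise for anthers.  When the two differences have opposite signs
    (the morphs are reciprocal) the index is min(|dstigma|, |danther|),
    else 0.  Returns (index, polarity) with polarity = sign(dstigma);
    polarity +1 means S=0 is the pin (high-stigma) morph.
    """
    stig0, anth0, stig1, anth1 = _morph_means(x, y, S)
    dstig = stig0 - stig1
    danth = anth0 - anth1
    if dstig * danth < 0:
        idx = min(abs(dstig), abs(danth))
    else:
        idx = 0.0
    return idx, int(np.sign(dstig))


def _organ_levels(x, y, S):
    """Mean upper- and lower-organ heights of one patch.

    Pools the pin morph's stigma with the thrum morph's anthers (the upper
    level) and vice versa; the pin is the morph with the higher stigma
    mean, so pairing across patches is by level under emergent polarity.
    """
    stig0, anth0, stig1, anth1 = _morph_means(x, y, S)
    if stig0 >= stig1:       # S=0 is pin
        upper = 0.5 * (stig0 + anth1)
        lower = 0.5 * (anth0 + stig1)
    else:                    # S=1 is pin
        upper = 0.5 * (stig1 + anth0)
        lower = 0.5 * (anth1 + stig0)
    return upper, lower


def organ_mismatch(census1, census2) -> float:
    """Between-patch divergence in mean heights of corresponding organs.

    Each census is an (x, y, S) triple of arrays.  M = (|U1-U2| + |L1-L2|)/2
    over the mean upper (U) and lower (L) organ levels of the two patches.
    """
    u1, l1 = _organ_levels(*census1)
    u2, l2 = _organ_levels(*census2)
    return 0.5 * (abs(u1 - u2) + abs(l1 - l2))


def adaptation_increase(treatment: pd.DataFrame, control: pd.DataFrame,
                        keys=("sigma_j", "c", "omega")) -> pd.DataFrame:
    """Mean local-adaptation difference, treatment minus matched control.

    Both frames need one row per realization with A1/A2 columns plus the
    grouping keys.  Returns one row per parameter combination with dA1,
    dA2 and their standard errors; raises if the combinations do not
    match between arms.
    """
    keys = list(keys)

    def agg(df, tag):
        g = df.groupby(keys)[["A1", "A2"]]
        out = g.mean().rename(columns={"A1": f"A1_{tag}", "A2": f"A2_{tag}"})
        se = g.sem().rename(columns={"A1": f"se_A1_{tag}", "A2": f"se_A2_{tag}"})
        return out.join(se)

    t = agg(treatment, "t")
    ctrl = agg(control, "c")
    if set(t.index) != set(ctrl.index):
        raise ValueError("treatment and control parameter combos do not match")
    j = t.join(ctrl)
    j["dA1"] = j["A1_t"] - j["A1_c"]
    j["dA2"] = j["A2_t"] - j["A2_c"]
    j["se_dA1"] = np.hypot(j["se_A1_t"], j["se_A1_c"])
    j["se_dA2"] = np.hypot(j["se_A2_t"], j["se_A2_c"])
    return j.reset_index()
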