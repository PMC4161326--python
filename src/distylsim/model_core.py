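"""Parameters, state containers, and initialization.

All heights live in corolla-tube units on [0, 1] (0 = tube bottom, 1 = tube
top).  A plant carries three heritable quantitative traits -- the two
reproductive-organ height traits ``x`` and ``y`` (bounded to the tube) and an
unbounded ecological trait ``z`` -- plus the diallelic morph locus ``S``.
``S`` sets the *polarity* of the height traits: the stigma sits at ``x`` and
the anthers at ``y`` when ``S = 0``, and vice versa when ``S = 1``.  Which
allele ends up "pin" (high stigma) and which "thrum" is emergent, not built
in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _engine
from ._engine import (NF, NI, F_XI, F_YI, F_ZI, F_VARXY, F_MU, F_ALPHA, F_UP,
                      F_US, F_M, F_TH1, F_TH2, F_SJ, F_C, F_OMEGA, F_SP,
                      F_SS, I_K, I_NO, I_NP, I_NS, I_V, I_YEARS, I_CONTROL,
                      I_EARLY, I_SEED)
from .pollination import PollinatorFunction, as_pollinator

PollinatorSpec = Union[str, "PollinatorFunction", None]


class ConfigurationError(ValueError):
    """Raised for invalid or incomplete parameter sets."""


@dataclass
class Params:
    """Full parameter set for one realization.

    Defaults are the model's standard values; ``sigma_j``, ``c``, ``omega``
    and the two pollinator specifiers are the swept quantities and must be
    supplied per realization (or ``control=True`` set, which makes the
    pollinator specifiers irrelevant).
    """

    K: int = 1000            # adult carrying capacity per patch
    x_init: float = 0.5      # initial mean of the height traits
    y_init: float = 0.5
    z_init: float = 0.5      # initial ecological trait (midway between optima)
    var_xy_init: float = 0.006  # initial genetic variance of x and y
    mu: float = 0.1          # mutation probability per trait per offspring
    alpha: float = 0.1       # mutation effect-size SD
    n_o: int = 50            # ovules per flower per year
    n_p: int = 1000          # pollen grains per flower per year
    n_s: int = 250           # received grains giving complete style clogging
    u_p: float = 0.1         # per-grain uptake probability
    u_s: float = 0.1         # base per-grain self-transfer probability
    m: float = 0.25          # adult mortality probability per year
    theta1: float = 0.0      # ecological optimum, patch 1
    theta2: float = 1.0      # ecological optimum, patch 2
    v: int = 10000           # pollination events per year (season length)
    sigma_p: float = 0.1     # Gaussian pollen transfer gap
    sigma_s: float = 0.1     # Gaussian self-transfer gap
    l_g: float = 0.2         # lognormal-variant gap (housed, unused)
    l_sigma: float = 1.0     # lognormal-variant shape (housed, unused)
    years: int = 10000       # run length in annual cycles
    sigma_j: Optional[float] = None   # pollen-height jitter SD
    c: Optional[float] = None         # pollinator crossover probability
    omega: Optional[float] = None     # stabilizing-selection SD
    pollinator1: PollinatorSpec = None
    pollinator2: PollinatorSpec = None
    control: bool = False    # disable stickiness/jitter/positional delivery
    seed: int = 0

    def validate(self) -> "Params":
        probs = dict(mu=self.mu, u_p=self.u_p, u_s=self.u_s, m=self.m)
        if self.c is not None:
            probs["c"] = self.c
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} not a probability")
        for name in ("K", "n_o", "n_p", "n_s", "v", "years"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigurationError(f"{name}={v} must be a non-negative integer")
        for name in ("K", "n_o", "n_p", "n_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("alpha", "sigma_p", "sigma_s", "var_xy_init"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("sigma_j", "c", "omega"):
            if getattr(self, name) is None:
                raise ConfigurationError(f"{name} must be supplied per realization")
        if self.sigma_j <= 0 or self.omega <= 0:
            raise ConfigurationError("sigma_j and omega must be > 0")
        if not self.control:
            if self.pollinator1 is None or self.pollinator2 is None:
                raise ConfigurationError(
                    "pollinator1/pollinator2 required unless control=True")
        return self

    def replace(self, **kw) -> "Params":
        return dataclasses.replace(self, **kw)

    # --- engine packing -------------------------------------------------

    def _pack(self):
        self.validate()
        fp = np.zeros(NF)
        fp[F_XI] = self.x_init
        fp[F_YI] = self.y_init
        fp[F_ZI] = self.z_init
        fp[F_VARXY] = self.var_xy_init
        fp[F_MU] = self.mu
        fp[F_ALPHA] = self.alpha
        fp[F_UP] = self.u_p
        fp[F_US] = self.u_s
        fp[F_M] = self.m
        fp[F_TH1] = self.theta1
        fp[F_TH2] = self.theta2
        fp[F_SJ] = self.sigma_j
        fp[F_C] = self.c
        fp[F_OMEGA] = self.omega
        fp[F_SP] = self.sigma_p
        fp[F_SS] = self.sigma_s
        ip = np.zeros(NI, dtype=np.int64)
        ip[I_K] = self.K
        ip[I_NO] = self.n_o
        ip[I_NP] = self.n_p
        ip[I_NS] = self.n_s
        ip[I_V] = self.v
        ip[I_YEARS] = self.years
        ip[I_CONTROL] = 1 if self.control else 0
        ip[I_SEED] = int(self.seed) % (2**31)
        polkind = np.zeros(2, dtype=np.int64)
        polq = np.zeros((2, 3))
        if self.control:
            specs = (as_pollinator("uniform"), as_pollinator("uniform"))
        else:
            specs = (as_pollinator(self.pollinator1),
                     as_pollinator(self.pollinator2))
        for i, pf in enumerate(specs):
            polkind[i] = pf.code
            polq[i] = pf.qvec()
        return fp, ip, polkind, polq


def default_params() -> Params:
    """The standard parameter set, with the swept quantities left unset."""
    return Params()


def params_from_dict(d: dict) -> Params:
    """Build Params from a flat mapping (e.g., a parsed YAML config)."""
    known = {f.name for f in dataclasses.fields(Params)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
    return Params(**d)


class Plant:
    """One adult plant (equivalently one flower).

    Quantitative traits are diploid: two allele values per trait, phenotype
    = allele mean.  Constructing with a bare phenotype value makes the
    plant homozygous for it; pass ``x_alleles``/``y_alleles``/``z_alleles``
    pairs for heterozygotes.
    """

    __slots__ = ("id", "patch", "S", "o", "p", "s",
                 "x_alleles", "y_alleles", "z_alleles")

    def __init__(self, id: int, patch: int, x: float = None, y: float = None,
                 z: float = None, S: int = 0, o: int = 0, p: int = 0,
                 s: int = 0, x_alleles=None, y_alleles=None, z_alleles=None):
        self.id = id
        self.patch = patch
        self.S = S
        self.o = o
        self.p = p
        self.s = s
        self.x_alleles = tuple(x_alleles) if x_alleles is not None else (x, x)
        self.y_alleles = tuple(y_alleles) if y_alleles is not None else (y, y)
        self.z_alleles = tuple(z_alleles) if z_alleles is not None else (z, z)

    @property
    def x(self) -> float:
        return 0.5 * (self.x_alleles[0] + self.x_alleles[1])

    @property
    def y(self) -> float:
        return 0.5 * (self.y_alleles[0] + self.y_alleles[1])

    @property
    def z(self) -> float:
        return 0.5 * (self.z_alleles[0] + self.z_alleles[1])

    def __repr__(self):
        return (f"Plant(id={self.id}, patch={self.patch}, x={self.x:.3f}, "
                f"y={self.y:.3f}, z={self.z:.3f}, S={self.S}, o={self.o}, "
                f"p={self.p}, s={self.s})")


def anther_height(plant: Plant) -> float:
    """Anther height: trait x if S=1, trait y if S=0."""
    return _engine.anther_height_core(plant.x, plant.y, plant.S)


def stigma_height(plant: Plant) -> float:
    """Stigma height: trait x if S=0, trait y if S=1."""
    return _engine.stigma_height_core(plant.x, plant.y, plant.S)


@dataclass
class Patch:
    """One of the two parapatric patches."""

    index: int                       # 1 or 2
    theta: float                     # local ecological optimum
    pollinator: PollinatorSpec
    adults: list = field(default_factory=list)
    seeds: list = field(default_factory=list)
    fert_resident: int = 0
    fert_migrant: int = 0


def init_population(params: Params, seed: Optional[int] = None):
    """Draw the founder populations of both patches.

    x and y phenotypes are centered on x_init with variance var_xy_init
    (alleles Normal with twice that variance, clipped to the corolla
    tube); z is exactly z_init for every plant; S is a fair coin; seasonal
    state starts full (o = n_o, p = n_p, s = 0).  Returns (patch1, patch2).
    """
    params.validate()
    if seed is None:
        seed = params.seed
    _engine.seed_rng(int(seed) % (2**31))
    K = params.K
    x1 = np.empty((2, K))
    x2 = np.empty((2, K))
    y1 = np.empty((2, K))
    y2 = np.empty((2, K))
    z1 = np.empty((2, K))
    z2 = np.empty((2, K))
    S = np.empty((2, K), dtype=np.int8)
    o = np.empty((2, K), dtype=np.int32)
    p = np.empty((2, K), dtype=np.int32)
    s = np.empty((2, K), dtype=np.int32)
    n = np.zeros(2, dtype=np.int64)
    fp, ip, _, _ = params._pack()
    nclip = _engine.init_arrays(fp, K, x1, x2, y1, y2, z1, z2, S, o, p, s,
                                n, params.n_o, params.n_p, _engine.RS)
    patches = []
    for pt, (theta, pol) in enumerate(
            [(params.theta1, params.pollinator1),
             (params.theta2, params.pollinator2)]):
        patch = Patch(index=pt + 1, theta=theta, pollinator=pol)
        for i in range(K):
            patch.adults.append(Plant(
                id=pt * K + i, patch=pt + 1,
                x_alleles=(float(x1[pt, i]), float(x2[pt, i])),
                y_alleles=(float(y1[pt, i]), float(y2[pt, i])),
                z_alleles=(float(z1[pt, i]), float(z2[pt, i])),
                S=int(S[pt, i]), o=int(o[pt, i]), p=int(p[pt, i]),
                s=int(s[pt, i])))
        patches.append(patch)
    patches[0].n_clipped = patches[1].n_clipped = int(nclip)
    return patches[0], patches[1]
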