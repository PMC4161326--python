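"""Inheritance, mutation, and the compatibility rule.

Quantitative traits are diploid: two allele values per trait, phenotype =
allele mean.  Each parent transmits one uniformly chosen allele per trait,
and mutation strikes each transmitted allele with probability mu and effect
SD alpha (x and y alleles are clipped to the corolla tube; z is unbounded).
Random mating therefore conserves additive variance (segregation variance
is explicit) instead of eroding it as blending inheritance would.

The morph locus ``S`` is tracked at the morph level; offspring take one
parental morph with a fair coin, which under obligate inter-morph mating is
exactly the Mendelian Ss x ss backcross of a distylous S-locus.  Crossing
is governed by complete heteromorphic incompatibility: only inter-morph,
non-self pollen can fertilize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import _engine


@dataclass
class GameteContribution:
    """Paternal side of a cross: one gamete, as carried by a pollen grain."""

    x_f: float         # one allele value per trait
    y_f: float
    z_f: float
    S_f: int           # paternal morph
    origin_patch: int  # 1 or 2


@dataclass
class SeedRecord:
    """A fertilized ovule, held until next year's germination phase.

    Stores the mother's diploid genotype (her gamete is drawn at
    germination) and the paternal gamete drawn at fertilization.
    """

    mother_id: int
    x_alleles: tuple
    y_alleles: tuple
    z_alleles: tuple
    S: int
    father: GameteContribution
    resident_father: bool

    @property
    def x(self) -> float:
        return 0.5 * (self.x_alleles[0] + self.x_alleles[1])

    @property
    def y(self) -> float:
        return 0.5 * (self.y_alleles[0] + self.y_alleles[1])

    @property
    def z(self) -> float:
        return 0.5 * (self.z_alleles[0] + self.z_alleles[1])


def compatible(donor_S: int, recipient_S: int,
               donor_id, recipient_id) -> bool:
    """True iff the cross is inter-morph and not self-pollination."""
    return bool(_engine.compatible_core(donor_S, recipient_S,
                                        hash(donor_id), hash(recipient_id)))


def _maybe_seed(seed: Optional[int]) -> None:
    if seed is not None:
        _engine.seed_rng(int(seed) % (2**31))


def mutate_trait(value: float, mu: float, alpha: float, bounded: bool,
                 seed: Optional[int] = None) -> float:
    """With probability mu, perturb by N(0, alpha); clip bounded values to [0,1].

    Applied to each transmitted allele.  ``seed`` re-seeds the engine RNG
    stream; None continues the current stream.
    """
    _maybe_seed(seed)
    return float(_engine.mutate_core(value, mu, alpha, bounded, _engine.RS))


def draw_gamete(plant, seed: Optional[int] = None) -> GameteContribution:
    """One unmutated gamete of a plant: a random allele per trait.

    Mutation is applied later, when the seed germinates.
    """
    _maybe_seed(seed)
    pick = lambda pair: pair[0] if _engine.runif() < 0.5 else pair[1]
    return GameteContribution(
        x_f=pick(plant.x_alleles), y_f=pick(plant.y_alleles),
        z_f=pick(plant.z_alleles), S_f=plant.S, origin_patch=plant.patch)


def _offspring_alleles(mother, father: GameteContribution, params,
                       seed: Optional[int] = None):
    """Full offspring genotype: allele pairs per trait plus the morph."""
    _maybe_seed(seed)
    return _engine.offspring_core(
        mother.x_alleles[0], mother.x_alleles[1],
        mother.y_alleles[0], mother.y_alleles[1],
        mother.z_alleles[0], mother.z_alleles[1], mother.S,
        father.x_f, father.y_f, father.z_f, father.S_f,
        params.mu, params.alpha, _engine.RS)


def make_offspring(mother, father: GameteContribution, params,
                   seed: Optional[int] = None):
    """Offspring phenotype (x, y, z, S) from a compatible cross.

    The maternal gamete is drawn from the mother's genotype, both
    transmitted allele sets are mutated, and the phenotype is the allele
    mean per trait; S is drawn uniformly from the two parental morphs.
    With mutation off and homozygous parents this reduces to the
    midparent value.
    """
    cx1, cx2, cy1, cy2, cz1, cz2, cS = _offspring_alleles(
        mother, father, params, seed)
    return (0.5 * (cx1 + cx2), 0.5 * (cy1 + cy2), 0.5 * (cz1 + cz2),
            int(cS))
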