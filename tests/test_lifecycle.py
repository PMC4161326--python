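"""Unit tests: annual cycle operations and the full realization loop."""

import math

import pytest
from scipy import stats

from distylsim import (GameteContribution, Params, Patch, Plant, SeedRecord,
                       ecological_fitness, germination, init_population,
                       mortality, reset_flowers, run_realization)


def base_params(**kw):
    d = dict(sigma_j=0.1, c=0.0, omega=0.3, control=True)
    d.update(kw)
    return Params(**d)


class TestEcologicalFitness:
    def test_closed_form(self):
        assert ecological_fitness(0.0, 0.0, 0.3) == 1.0
        # one omega of displacement: exactly exp(-1/2)
        assert ecological_fitness(0.3, 0.0, 0.3) == pytest.approx(
            math.exp(-0.5), abs=1e-12)
        assert ecological_fitness(1.0, 0.0, 0.5) == pytest.approx(
            math.exp(-2.0), rel=1e-12)

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            ecological_fitness(0.5, 0.0, 0.0)


def make_seed(mother_id=0, z=0.0, patch=1):
    father = GameteContribution(x_f=0.5, y_f=0.5, z_f=z, S_f=1,
                                origin_patch=patch)
    return SeedRecord(mother_id=mother_id, x_alleles=(0.5, 0.5),
                      y_alleles=(0.5, 0.5), z_alleles=(z, z), S=0,
                      father=father, resident_father=True)


class TestGermination:
    def test_fills_to_capacity_and_clears_store(self):
        params = base_params(K=20, mu=0.0)
        patch = Patch(index=1, theta=0.0, pollinator=None)
        patch.seeds = [make_seed(z=0.0) for _ in range(500)]
        took = germination(patch, params, seed=41)
        assert took == 20                       # seeds at the optimum
        assert len(patch.adults) == 20
        assert patch.seeds == []
        for pl in patch.adults:
            assert pl.o == params.n_o and pl.p == params.n_p and pl.s == 0
            assert pl.z == pytest.approx(0.0)

    def test_survival_probability(self):
        # seeds one omega from the optimum survive with exp(-1/2)
        params = base_params(K=10**9, mu=0.0, omega=0.3)
        survived = 0
        n = 5000
        for i in range(10):
            patch = Patch(index=1, theta=0.0, pollinator=None)
            patch.seeds = [make_seed(z=0.3) for _ in range(n // 10)]
            survived += germination(patch, params,
                                    seed=(42 if i == 0 else None))
        lo, hi = stats.binom.ppf([5e-7, 1 - 5e-7], n, math.exp(-0.5))
        assert lo <= survived <= hi

    def test_no_vacancy_no_recruits(self):
        params = base_params(K=5, mu=0.0)
        patch = Patch(index=1, theta=0.0, pollinator=None)
        patch.adults = [Plant(id=i, patch=1, x=0.5, y=0.5, z=0.0, S=i % 2)
                        for i in range(5)]
        patch.seeds = [make_seed(z=0.0) for _ in range(50)]
        assert germination(patch, params, seed=43) == 0
        assert len(patch.adults) == 5


class TestMortality:
    def patch(self, n=400):
        patch = Patch(index=1, theta=0.0, pollinator=None)
        patch.adults = [Plant(id=i, patch=1, x=0.5, y=0.5, z=0.0, S=i % 2)
                        for i in range(n)]
        return patch

    def test_rate(self):
        params = base_params(m=0.25)
        deaths = 0
        for i in range(25):
            deaths += mortality(self.patch(), params,
                                seed=(44 if i == 0 else None))
        lo, hi = stats.binom.ppf([5e-7, 1 - 5e-7], 25 * 400, 0.25)
        assert lo <= deaths <= hi

    def test_certain_death(self):
        patch = self.patch(50)
        assert mortality(patch, base_params(m=1.0), seed=45) == 50
        assert patch.adults == []


class TestResetFlowers:
    def test_reset(self):
        params = base_params()
        patch = Patch(index=1, theta=0.0, pollinator=None)
        pl = Plant(id=0, patch=1, x=0.5, y=0.5, z=0.0, S=0)
        pl.o, pl.p, pl.s = 3, 7, 99
        patch.adults = [pl]
        patch.fert_resident = 5
        reset_flowers(patch, params)
        assert (pl.o, pl.p, pl.s) == (params.n_o, params.n_p, 0)
        assert patch.fert_resident == 0


class TestRunRealization:
    def small(self, seed=51, years=15, **kw):
        return base_params(K=40, v=300, years=years, seed=seed, **kw)

    def test_determinism(self):
        a = run_realization(self.small()).metrics.to_dict()
        b = run_realization(self.small()).metrics.to_dict()
        assert a == b

    def test_control_invariant_to_pollinator_specifiers(self):
        """Control results ignore which pollinator names are attached."""
        a = run_realization(self.small(pollinator1="uniform",
                                       pollinator2="uniform"))
        b = run_realization(self.small(pollinator1="bimodal_low",
                                       pollinator2="high_biased"))
        assert a.metrics.to_dict() == b.metrics.to_dict()

    def test_isolation_complete_without_crossover(self):
        res = run_realization(self.small(c=0.0)).metrics
        assert res.I1 == 1.0 and res.I2 == 1.0

    def test_crossover_breaks_isolation(self):
        res = run_realization(self.small(c=0.5, seed=52)).metrics
        assert res.I1 < 1.0 or res.I2 < 1.0

    def test_certain_mortality_extinction(self):
        res = run_realization(self.small(m=1.0)).metrics
        assert res.extinct in (1, 2)
        assert res.years_run <= 2

    def test_time_series_shape(self):
        out = run_realization(self.small(years=8), time_series=True)
        ts = out.time_series
        assert len(ts) == 8 * 2
        for col in ("year", "patch", "adults", "zbar", "dim_index",
                    "fert_resident", "fert_migrant"):
            assert col in ts.columns
        assert (ts["adults"] > 0).all()

    def test_census_structure(self):
        out = run_realization(self.small())
        for pt in (1, 2):
            cen = out.census[pt]
            n = len(cen["x"])
            assert n > 0
            for k in ("y", "z", "S", "o", "p", "s"):
                assert len(cen[k]) == n

    def test_population_at_capacity(self):
        # m=0: nobody dies, population stays pinned at K after year 1
        out = run_realization(self.small(m=0.0))
        for pt in (1, 2):
            assert len(out.census[pt]["x"]) == 40
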