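"""Unit tests: pollinator functions and the grain-level transfer pipeline."""

import math

import numpy as np
import pytest
from scipy import stats

from distylsim import (GameteContribution, Params, Plant, PollenGrain,
                       PollinatorFunction, as_pollinator, deliver_grain,
                       gaussian_kernel, init_population, pollen_uptake,
                       receive_on_stigma, reset_flowers, run_season,
                       self_transfer, stickiness)


def base_params(**kw):
    d = dict(sigma_j=0.1, c=0.0, omega=0.3, control=True)
    d.update(kw)
    return Params(**d)


class TestPollinatorFunctions:
    def test_uniform_is_flat_one(self):
        for h in (0.0, 0.25, 0.5, 1.0):
            assert stickiness("uniform", h) == 1.0

    def test_high_biased_ramp(self):
        # zero at/below the threshold, linear ramp to 1 at the tube top
        assert stickiness("high_biased", 0.49) == 0.0
        assert stickiness("high_biased", 0.5) == 0.0
        assert stickiness("high_biased", 0.75) == pytest.approx(0.5)
        assert stickiness("high_biased", 1.0) == pytest.approx(1.0)
        pf = as_pollinator("high_biased", threshold=0.8)
        assert stickiness(pf, 0.7) == 0.0
        assert stickiness(pf, 0.9) == pytest.approx(0.5)

    def test_bimodal_shapes(self):
        # unit amplitude at each bump center, clipped sum, SD 0.06
        for kind, (c1, c2) in (("bimodal_low", (0.20, 0.65)),
                               ("bimodal_high", (0.35, 0.80))):
            assert stickiness(kind, c1) == pytest.approx(1.0, abs=1e-9)
            assert stickiness(kind, c2) == pytest.approx(1.0, abs=1e-9)
            # one SD off a center: exp(-1/2) plus the far-bump tail
            assert stickiness(kind, c1 + 0.06) == pytest.approx(
                math.exp(-0.5), abs=1e-3)
            # between bumps: near zero
            assert stickiness(kind, 0.5 * (c1 + c2)) < 0.01

    def test_bimodal_overrides(self):
        pf = as_pollinator("bimodal_low", centers=(0.3, 0.7), width=0.1)
        assert stickiness(pf, 0.3) == pytest.approx(1.0, abs=1e-6)
        # exp(-1/2) from the near bump plus the far bump's tail at 3 SD
        assert stickiness(pf, 0.4) == pytest.approx(
            math.exp(-0.5) + math.exp(-4.5), abs=1e-6)

    def test_bounds_everywhere(self):
        for kind in ("uniform", "high_biased", "bimodal_low", "bimodal_high"):
            for h in np.linspace(0, 1, 101):
                v = stickiness(kind, float(h))
                assert 0.0 <= v <= 1.0

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            as_pollinator("nope")
        with pytest.raises(ValueError):
            as_pollinator("uniform", bogus=3)


class TestGaussianKernel:
    def test_closed_form(self):
        # one scale of displacement gives exactly exp(-1/2)
        assert gaussian_kernel(0.1, 0.1) == pytest.approx(
            math.exp(-0.5), abs=1e-12)
        assert gaussian_kernel(0.0, 0.3) == 1.0
        assert gaussian_kernel(-0.2, 0.1) == pytest.approx(
            math.exp(-2.0), rel=1e-12)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.1, 0.0)


def make_plant(S=0, x=0.5, y=0.5, p=1000, o=50, s=0, pid=1, patch=1):
    pl = Plant(id=pid, patch=patch, x=x, y=y, z=0.5, S=S)
    pl.p, pl.o, pl.s = p, o, s
    return pl


class TestSelfTransfer:
    def test_rate_at_one_sd_separation(self):
        """Per-grain probability u_s * exp(-sep^2/(2 sigma_s^2))."""
        params = base_params(u_s=0.1, sigma_s=0.1)
        # S=0: stigma at x, anthers at y -> separation 0.1 = one sigma_s
        total = 0
        n_trials, budget = 200, 1000
        for i in range(n_trials):
            pl = make_plant(S=0, x=0.6, y=0.5, p=budget)
            total += self_transfer(pl, params, seed=(21 if i == 0 else None))
            assert pl.p + pl.s == budget
        p_grain = 0.1 * math.exp(-0.5)
        lo, hi = stats.binom.ppf([5e-7, 1 - 5e-7], n_trials * budget, p_grain)
        assert lo <= total <= hi

    def test_never_fertilizes(self):
        params = base_params()
        pl = make_plant(x=0.5, y=0.5)
        self_transfer(pl, params, seed=22)
        assert pl.o == 50


class TestPollenUptake:
    def test_removal_rate_and_conservation(self):
        params = base_params(u_p=0.1, control=True)
        removed = 0
        n_trials, budget = 100, 1000
        for i in range(n_trials):
            donor = make_plant(p=budget)
            grains = pollen_uptake(donor, None, params,
                                   seed=(23 if i == 0 else None))
            removed += budget - donor.p
            # control: every removed grain is transported
            assert len(grains) == budget - donor.p
        lo, hi = stats.binom.ppf([5e-7, 1 - 5e-7], n_trials * budget, 0.1)
        assert lo <= removed <= hi

    def test_treatment_filters_by_stickiness(self):
        # anther far below a high_biased pollinator's band, tight jitter:
        # grains are removed but essentially never stick
        params = base_params(u_p=0.5, sigma_j=0.01, control=False,
                             pollinator1="high_biased",
                             pollinator2="high_biased")
        donor = make_plant(y=0.2, p=2000)
        grains = pollen_uptake(donor, "high_biased", params, seed=24)
        assert donor.p < 2000
        assert grains == []

    def test_grain_heights_near_anther(self):
        params = base_params(sigma_j=0.05, control=False,
                             pollinator1="uniform", pollinator2="uniform")
        donor = make_plant(S=1, x=0.7, p=5000)   # S=1: anthers at x
        grains = pollen_uptake(donor, "uniform", params, seed=25)
        h = np.array([g.height for g in grains])
        assert len(grains) > 100
        assert np.all((h >= 0) & (h <= 1))
        assert abs(h.mean() - 0.7) < 0.01
        assert h.std() == pytest.approx(0.05, rel=0.15)


class TestDeliverGrain:
    def grain(self, height):
        father = GameteContribution(x_f=0.5, y_f=0.5, z_f=0.5, S_f=1,
                                    origin_patch=1)
        return PollenGrain(father=father, height=height, donor_id=9)

    def test_control_always_received(self):
        params = base_params(control=True)
        rec = make_plant(S=0, x=0.9)
        assert all(deliver_grain(self.grain(0.1), rec, params,
                                 seed=(26 if i == 0 else None))
                   for i in range(200))

    def test_positional_kernel_rate(self):
        # final height ~ N(stigma + delta0, sigma_j); acceptance prob is the
        # Gaussian kernel of the final offset.  With delta0 = sigma_p and
        # tiny jitter the rate is close to exp(-1/2).
        params = base_params(sigma_j=1e-6, sigma_p=0.1, control=False,
                             pollinator1="uniform", pollinator2="uniform")
        rec = make_plant(S=0, x=0.5)
        hits = sum(deliver_grain(self.grain(0.6), rec, params,
                                 seed=(27 if i == 0 else None))
                   for i in range(20000))
        lo, hi = stats.binom.ppf([5e-7, 1 - 5e-7], 20000, math.exp(-0.5))
        assert lo <= hits <= hi


class TestReceiveOnStigma:
    def setup_pair(self, s=0, o=50):
        rec = make_plant(S=0, s=s, o=o, pid=1)
        father = GameteContribution(x_f=0.5, y_f=0.5, z_f=0.5, S_f=1,
                                    origin_patch=1)
        grain = PollenGrain(father=father, height=0.5, donor_id=2)
        return rec, grain

    def test_fertilization_blocked_at_full_clogging(self):
        """At s = n_s the fertilization probability is exactly zero."""
        params = base_params(n_s=250)
        for i in range(500):
            rec, grain = self.setup_pair(s=250)
            out = receive_on_stigma(rec, grain, params,
                                    seed=(28 if i == 0 else None))
            assert out is None
            assert rec.s == 251      # still clogs
            assert rec.o == 50

    def test_unclogged_compatible_always_fertilizes(self):
        params = base_params()
        rec, grain = self.setup_pair(s=0)
        out = receive_on_stigma(rec, grain, params, seed=29)
        assert out is not None
        assert rec.o == 49 and rec.s == 1
        assert out.resident_father and out.S == 0

    def test_incompatible_clogs_without_fertilizing(self):
        params = base_params()
        rec, grain = self.setup_pair()
        grain.father.S_f = 0          # same morph as recipient
        assert receive_on_stigma(rec, grain, params, seed=30) is None
        assert rec.s == 1 and rec.o == 50

    def test_clogging_rate_linear(self):
        # fertilization probability max(0, 1 - s0/n_s) at half clogging
        params = base_params(n_s=250)
        hits = 0
        for i in range(10000):
            rec, grain = self.setup_pair(s=125)
            if receive_on_stigma(rec, grain, params,
                                 seed=(31 if i == 0 else None)):
                hits += 1
        lo, hi = stats.binom.ppf([5e-7, 1 - 5e-7], 10000, 0.5)
        assert lo <= hits <= hi


class TestRunSeason:
    def run(self, seed=33, **kw):
        params = base_params(K=60, v=400, seed=seed, **kw)
        patches = init_population(params)
        for patch in patches:
            reset_flowers(patch, params)
        summary = run_season(patches, params, seed=seed)
        return params, patches, summary

    def test_pollen_conservation(self):
        """Initial pollen = remaining + removed-by-pollinator + selfed."""
        params, patches, summary = self.run()
        for pt, patch in enumerate(patches):
            initial = len(patch.adults) * params.n_p
            remaining = sum(pl.p for pl in patch.adults)
            assert initial == remaining + summary.removed[pt] + \
                summary.selfed[pt]

    def test_ovule_and_seed_conservation(self):
        params, patches, summary = self.run()
        for pt, patch in enumerate(patches):
            spent = len(patch.adults) * params.n_o - \
                sum(pl.o for pl in patch.adults)
            assert spent == summary.seeds[pt] == len(patch.seeds)
            assert summary.seeds[pt] == summary.fert_resident[pt] + \
                summary.fert_migrant[pt]
            assert summary.fert_resident[pt] == patch.fert_resident
            assert summary.fert_migrant[pt] == patch.fert_migrant

    def test_clogging_tally(self):
        """Style clogging = self-transferred + received grains."""
        params, patches, summary = self.run()
        for pt, patch in enumerate(patches):
            assert sum(pl.s for pl in patch.adults) == \
                summary.selfed[pt] + summary.received[pt]

    def test_no_migrant_fathers_without_crossover(self):
        params, patches, summary = self.run(c=0.0)
        assert summary.fert_migrant == (0, 0)
        for patch in patches:
            assert all(s.resident_father for s in patch.seeds)

    def test_crossover_produces_migrants(self):
        _, patches, summary = self.run(c=0.5)
        assert sum(summary.fert_migrant) > 0

    def test_determinism(self):
        a = self.run(seed=34)[2]
        b = self.run(seed=34)[2]
        assert a == b

    def test_seed_records_are_intermorph(self):
        _, patches, _ = self.run()
        for patch in patches:
            for s in patch.seeds:
                assert s.S != s.father.S_f
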