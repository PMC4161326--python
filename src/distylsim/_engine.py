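"""Compiled simulation kernels.

Everything stochastic in the model runs through the njit cores below; see
the "random numbers" section for the two deterministic RNG streams.  The full-realization loop (`simulate`) and the
object-level API wrappers in :mod:`distylsim.pollination` /
:mod:`distylsim.lifecycle` call the *same* cores, so there is a single source
of truth for every model rule.

Genetics: each quantitative trait (x, y, z) is diploid -- two allele values
per plant, phenotype = allele mean.  Each parent transmits one uniformly
chosen allele per trait; mutation strikes each transmitted allele with
probability mu and effect SD alpha (x, y alleles clipped to the corolla
tube).  This maintains segregation variance under random mating.  The morph
locus S is tracked at the morph level; under obligate inter-morph mating a
fair coin between the parental morphs is exactly Mendelian Ss x ss
segregation.

State layout: struct-of-arrays with a leading patch axis of length 2 and a
fixed capacity of K adults per patch; ``n[patch]`` holds the live count.
Dead adults are removed by swap-with-last compaction.

RNG draw order within a realization is fixed: initialization, then per
year: germination (patch 1, patch 2), mortality (patch 1, patch 2),
pollination events 1..v.  Both RNG streams are seeded from the realization
seed, so identical Params (including the seed) give bit-identical
trajectories.
"""

import numpy as np
from numba import njit

# float parameter vector indices
F_XI, F_YI, F_ZI, F_VARXY, F_MU, F_ALPHA, F_UP, F_US, F_M, F_TH1, F_TH2, \
    F_SJ, F_C, F_OMEGA, F_SP, F_SS = range(16)
NF = 16

# int parameter vector indices
I_K, I_NO, I_NP, I_NS, I_V, I_YEARS, I_CONTROL, I_EARLY, I_SEED = range(9)
NI = 9

# pollinator kind codes
POL_UNIFORM, POL_HIGH_BIASED, POL_BIMODAL_LOW, POL_BIMODAL_HIGH = 0, 1, 2, 3

# time-series column indices (per patch)
TS_N, TS_SEEDS, TS_ZBAR, TS_STIG0, TS_STIG1, TS_ANTH0, TS_ANTH1, \
    TS_FERT_RES, TS_FERT_MIG, TS_MEAN_O, TS_DIM = range(11)
NTS = 11


# --- random numbers ----------------------------------------------------
# Two deterministic streams, both seeded from the same realization seed:
# numba's Mersenne-Twister stream supplies binomial counts and integer
# picks (np.random.binomial / np.random.randint), while scalar uniforms
# and normals come from an inline xoshiro256** generator whose 4-word
# state is threaded through the kernels as the ``rs`` argument.  The
# xoshiro path exists purely for speed: the per-grain jitter and
# stickiness draws dominate whole-realization runtimes, and the inline
# generator is roughly an order of magnitude faster per draw than the
# library calls.  Normals use a 128-strip ziggurat (Doornik's ZIGNOR
# layout) on top of the xoshiro stream.


@njit(cache=True)
def _seed_mt(seed):
    np.random.seed(seed)


@njit(cache=True)
def xs_seed(rs, seed):
    """Fill a xoshiro256** state vector from a seed via splitmix64."""
    s = np.uint64(seed)
    for i in range(4):
        s = s + np.uint64(0x9E3779B97F4A7C15)
        z = s
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        rs[i] = z ^ (z >> np.uint64(31))
    if (rs[0] | rs[1] | rs[2] | rs[3]) == np.uint64(0):
        rs[0] = np.uint64(1)


@njit(cache=True, inline="always")
def _rotl(x, k):
    return (x << np.uint64(k)) | (x >> (np.uint64(64 - k)))


@njit(cache=True, inline="always")
def xs_next(rs):
    """One xoshiro256** step: returns a uint64, advances the state."""
    s1 = rs[1]
    result = _rotl(s1 * np.uint64(5), 7) * np.uint64(9)
    t = s1 << np.uint64(17)
    s2 = rs[2] ^ rs[0]
    s3 = rs[3] ^ s1
    rs[1] = s1 ^ s2
    rs[0] = rs[0] ^ s3
    rs[2] = s2 ^ t
    rs[3] = _rotl(s3, 45)
    return result


@njit(cache=True, inline="always")
def xs_unif(rs):
    """Uniform double in [0, 1) from the top 53 bits of one xoshiro step."""
    return (xs_next(rs) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


_ZIG_R = 3.442619855899
_ZIG_V = 9.91256303526217e-3


def _build_ziggurat():
    X = np.empty(129)
    X[0] = _ZIG_V / np.exp(-0.5 * _ZIG_R * _ZIG_R)
    X[1] = _ZIG_R
    for i in range(2, 128):
        X[i] = np.sqrt(-2.0 * np.log(
            _ZIG_V / X[i - 1] + np.exp(-0.5 * X[i - 1] * X[i - 1])))
    X[128] = 0.0
    return X, X[1:] / X[:-1], np.exp(-0.5 * X * X)


_ZIG_X, _ZIG_RAT, _ZIG_F = _build_ziggurat()


@njit(cache=True, inline="always")
def xs_norm(rs):
    """Standard normal via the ziggurat on the xoshiro stream.

    One step supplies both the strip index (low 7 bits) and the mantissa
    (top 53 bits); the wedge and tail tests draw extra uniforms.
    """
    while True:
        b = xs_next(rs)
        i = int(b & np.uint64(127))
        u = 2.0 * ((b >> np.uint64(11)) * (1.0 / 9007199254740992.0)) - 1.0
        if abs(u) < _ZIG_RAT[i]:
            return u * _ZIG_X[i]          # inside the strip rectangle
        if i == 0:
            while True:                   # tail beyond R (Marsaglia)
                x = -np.log(xs_unif(rs)) / _ZIG_R
                y = -np.log(xs_unif(rs))
                if y + y > x * x:
                    return _ZIG_R + x if u > 0.0 else -(_ZIG_R + x)
        x = u * _ZIG_X[i]
        # wedge: accept w.p. (phi(x)-phi(X[i])) / (phi(X[i+1])-phi(X[i]))
        if _ZIG_F[i] + xs_unif(rs) * (_ZIG_F[i + 1] - _ZIG_F[i]) \
                < np.exp(-0.5 * x * x):
            return x


#: module-level state used by the op-level (object API) wrappers; the
#: whole-realization loop `simulate` carries its own local state instead.
RS = np.zeros(4, dtype=np.uint64)


def seed_rng(seed):
    """Seed both compiled-code RNG streams (MT and xoshiro)."""
    _seed_mt(seed)
    xs_seed(RS, seed)


def runif():
    """One uniform draw from the op-level xoshiro stream."""
    return xs_unif(RS)


@njit(cache=True, inline="always")
def gaussian_kernel(delta, scale):
    """exp(-delta^2 / (2 scale^2)): positional transfer/selfing kernel."""
    return np.exp(-(delta * delta) / (2.0 * scale * scale))


@njit(cache=True, inline="always")
def stickiness_core(kind, h, q0, q1, q2):
    """Probability that a grain at corolla height h sticks to the pollinator.

    kind 0 (uniform): 1 inside the tube. kind 1 (high-biased): 0 below the
    threshold q0, rising linearly to 1 at the tube top. kinds 2/3 (bimodal):
    two Gaussian bumps at q0 and q1 with SD q2, clipped to 1.
    """
    if kind == POL_UNIFORM:
        return 1.0
    if kind == POL_HIGH_BIASED:
        if h <= q0:
            return 0.0
        v = (h - q0) / (1.0 - q0)
        return v if v < 1.0 else 1.0
    # bimodal: sum of two unit-amplitude Gaussian bumps
    v = gaussian_kernel(h - q0, q2) + gaussian_kernel(h - q1, q2)
    return v if v < 1.0 else 1.0


@njit(cache=True, inline="always")
def eco_fitness(z, theta, omega):
    """Seedling survival probability under stabilizing selection."""
    return gaussian_kernel(z - theta, omega)


@njit(cache=True, inline="always")
def anther_height_core(x, y, S):
    return x if S == 1 else y


@njit(cache=True, inline="always")
def stigma_height_core(x, y, S):
    return x if S == 0 else y


@njit(cache=True, inline="always")
def compatible_core(donor_S, recipient_S, donor_id, recipient_id):
    """Heteromorphic incompatibility: only inter-morph, non-self crosses."""
    return donor_S != recipient_S and donor_id != recipient_id


@njit(cache=True, inline="always")
def mutate_core(value, mu, alpha, bounded, rs):
    """With probability mu, add a N(0, alpha) effect; clip bounded values."""
    if mu > 0.0 and xs_unif(rs) < mu:
        value = value + alpha * xs_norm(rs)
        if bounded:
            if value < 0.0:
                value = 0.0
            elif value > 1.0:
                value = 1.0
    return value


@njit(cache=True, inline="always")
def gamete_allele(a1, a2, mu, alpha, bounded, rs):
    """Transmit one uniformly chosen allele, possibly mutated."""
    a = a1 if xs_unif(rs) < 0.5 else a2
    return mutate_core(a, mu, alpha, bounded, rs)


@njit(cache=True, inline="always")
def offspring_core(mx1, mx2, my1, my2, mz1, mz2, mS,
                   fx, fy, fz, fS, mu, alpha, rs):
    """Combine a maternal genotype with a paternal gamete.

    The maternal gamete is drawn here (one allele per trait) and both
    transmitted allele sets are mutated; the paternal gamete (fx, fy, fz)
    was drawn, unmutated, at fertilization.  Returns the offspring's six
    allele values and morph: (x1, x2, y1, y2, z1, z2, S) with allele 1
    maternal and allele 2 paternal.
    """
    cx1 = gamete_allele(mx1, mx2, mu, alpha, True, rs)
    cy1 = gamete_allele(my1, my2, mu, alpha, True, rs)
    cz1 = gamete_allele(mz1, mz2, mu, alpha, False, rs)
    cx2 = mutate_core(fx, mu, alpha, True, rs)
    cy2 = mutate_core(fy, mu, alpha, True, rs)
    cz2 = mutate_core(fz, mu, alpha, False, rs)
    cS = mS if xs_unif(rs) < 0.5 else fS
    return cx1, cx2, cy1, cy2, cz1, cz2, cS


@njit(cache=True)
def self_transfer_count(pcount, separation, u_s, sigma_s):
    """Number of the donor's remaining grains jostled onto its own stigma."""
    if pcount <= 0:
        return 0
    pr = u_s * gaussian_kernel(separation, sigma_s)
    if pr <= 0.0:
        return 0
    return np.random.binomial(pcount, pr)


@njit(cache=True)
def uptake_core(pcount, anther, u_p, sigma_j, control,
                kind, q0, q1, q2, buf, rs):
    """Remove grains from a donor and decide which stick to the pollinator.

    Every removed grain is lost to the donor whether or not it sticks
    (pollen discounting).  Treatment mode jitters each removed grain's
    height, discards grains that leave the tube, then applies the
    stickiness function; control mode transports every removed grain.
    Returns (n_removed, n_stuck); stuck heights fill ``buf[:n_stuck]``.
    """
    if pcount <= 0:
        return 0, 0
    nrem = np.random.binomial(pcount, u_p)
    if nrem == 0:
        return 0, 0
    nstuck = 0
    if control:
        for k in range(nrem):
            buf[nstuck] = anther
            nstuck += 1
    else:
        for k in range(nrem):
            h = anther + sigma_j * xs_norm(rs)
            if h < 0.0 or h > 1.0:
                continue  # jittered out of the corolla tube at pickup
            st = stickiness_core(kind, h, q0, q1, q2)
            if st > 0.0 and xs_unif(rs) < st:
                buf[nstuck] = h
                nstuck += 1
    return nrem, nstuck


@njit(cache=True, inline="always")
def deliver_core(height, stigma, sigma_j, sigma_p, control, rs):
    """Final jitter and positional receipt of one transported grain."""
    if control:
        return True
    h2 = height + sigma_j * xs_norm(rs)
    pr = gaussian_kernel(h2 - stigma, sigma_p)
    return xs_unif(rs) < pr


@njit(cache=True, inline="always")
def fertilization_prob(s0, n_s):
    """Linear style-clogging factor: 1 at s=0, 0 at s>=n_s."""
    v = 1.0 - s0 / n_s
    return v if v > 0.0 else 0.0


@njit(cache=True, inline="always")
def clipped_normal(loc, sd, rs):
    v = loc + sd * xs_norm(rs)
    clipped = 0
    if v < 0.0:
        v = 0.0
        clipped = 1
    elif v > 1.0:
        v = 1.0
        clipped = 1
    return v, clipped


@njit(cache=True)
def init_arrays(fp, K, x1, x2, y1, y2, z1, z2, S, o, p, s, n, n_o, n_p, rs):
    """Fill both patches with K founders.

    x and y alleles ~ N(x_init, sqrt(2 var_xy_init)) clipped to [0,1], so
    the phenotype (allele mean) has variance var_xy_init; z alleles fixed
    at z_init (equally maladapted to both optima); S a fair coin.  Returns
    the number of clipped draws (a handful at most).
    """
    sd = np.sqrt(2.0 * fp[F_VARXY])
    nclip = 0
    for pt in range(2):
        for i in range(K):
            x1[pt, i], c = clipped_normal(fp[F_XI], sd, rs)
            nclip += c
            x2[pt, i], c = clipped_normal(fp[F_XI], sd, rs)
            nclip += c
            y1[pt, i], c = clipped_normal(fp[F_YI], sd, rs)
            nclip += c
            y2[pt, i], c = clipped_normal(fp[F_YI], sd, rs)
            nclip += c
            z1[pt, i] = fp[F_ZI]
            z2[pt, i] = fp[F_ZI]
            S[pt, i] = 1 if xs_unif(rs) < 0.5 else 0
            o[pt, i] = n_o
            p[pt, i] = n_p
            s[pt, i] = 0
        n[pt] = K
    return nclip


@njit(cache=True)
def germination_core(pt, theta, fp, K,
                     x1, x2, y1, y2, z1, z2, S, o, p, s, n,
                     smx1, smx2, smy1, smy2, smz1, smz2, smS,
                     sfx, sfy, sfz, sfS, sres, smidx,
                     nseeds, n_o, n_p,
                     tidx, tz1, tz2, rs):
    """Germinate one patch's stored seeds into vacant adult slots.

    Each seed becomes an offspring genotype (maternal gamete + stored
    paternal gamete, both mutated; Mendelian morph), survives with its
    ecological fitness, and surviving seedlings compete for the K - n
    vacant slots by uniform lottery.  Returns the number recruited.
    (x/y/morph draws are deferred to lottery winners; see Phase 1 note.)
    """
    free = K - n[pt]
    ns = nseeds[pt]
    if free <= 0 or ns <= 0:
        return 0
    cnt = 0
    mu = fp[F_MU]
    alpha = fp[F_ALPHA]
    omega = fp[F_OMEGA]
    # Phase 1: draw each seed's z genotype and apply ecological survival.
    # Only z determines survival, and the x/y gametes of seeds that are
    # not recruited never affect anything, so those (independent) draws
    # are deferred to the lottery winners below -- distributionally
    # identical to drawing the full genotype per seed, and much cheaper
    # when seeds vastly outnumber vacancies.
    for k in range(ns):
        cz1 = gamete_allele(smz1[pt, k], smz2[pt, k], mu, alpha, False, rs)
        cz2 = mutate_core(sfz[pt, k], mu, alpha, False, rs)
        w = eco_fitness(0.5 * (cz1 + cz2), theta, omega)
        if xs_unif(rs) < w:
            tidx[cnt] = k
            tz1[cnt] = cz1
            tz2[cnt] = cz2
            cnt += 1
    take = free if free < cnt else cnt
    # Phase 2: uniform lottery among survivors (partial Fisher-Yates),
    # then complete the winners' genotypes and recruit them.
    for i in range(take):
        j = i + np.random.randint(0, cnt - i)
        tidx[i], tidx[j] = tidx[j], tidx[i]
        tz1[i], tz1[j] = tz1[j], tz1[i]
        tz2[i], tz2[j] = tz2[j], tz2[i]
        k = tidx[i]
        idx = n[pt]
        x1[pt, idx] = gamete_allele(smx1[pt, k], smx2[pt, k],
                                    mu, alpha, True, rs)
        x2[pt, idx] = mutate_core(sfx[pt, k], mu, alpha, True, rs)
        y1[pt, idx] = gamete_allele(smy1[pt, k], smy2[pt, k],
                                    mu, alpha, True, rs)
        y2[pt, idx] = mutate_core(sfy[pt, k], mu, alpha, True, rs)
        z1[pt, idx] = tz1[i]
        z2[pt, idx] = tz2[i]
        S[pt, idx] = smS[pt, k] if xs_unif(rs) < 0.5 else sfS[pt, k]
        o[pt, idx] = n_o
        p[pt, idx] = n_p
        s[pt, idx] = 0
        n[pt] += 1
    return take


@njit(cache=True)
def mortality_core(pt, m, x1, x2, y1, y2, z1, z2, S, o, p, s, n, rs):
    """Random adult mortality with probability m; swap-remove compaction."""
    deaths = 0
    i = n[pt] - 1
    while i >= 0:
        if xs_unif(rs) < m:
            last = n[pt] - 1
            if i != last:
                x1[pt, i] = x1[pt, last]
                x2[pt, i] = x2[pt, last]
                y1[pt, i] = y1[pt, last]
                y2[pt, i] = y2[pt, last]
                z1[pt, i] = z1[pt, last]
                z2[pt, i] = z2[pt, last]
                S[pt, i] = S[pt, last]
                o[pt, i] = o[pt, last]
                p[pt, i] = p[pt, last]
                s[pt, i] = s[pt, last]
            n[pt] -= 1
            deaths += 1
        i -= 1
    return deaths


@njit(cache=True)
def event_core(fp, control, n_s,
               polkind, polq,
               x1, x2, y1, y2, z1, z2, S, o, p, s, n,
               smx1, smx2, smy1, smy2, smz1, smz2, smS,
               sfx, sfy, sfz, sfS, sres, smidx, nseeds,
               fert_res, fert_mig,
               removed, selfed, received,
               buf, rs):
    """One pollination event: donor choice, self-transfer, uptake, crossover,
    delivery, receipt, clogging, and fertilization.

    The paternal gamete stored in a new seed is drawn per fertilizing grain
    (one uniformly chosen donor allele per trait, unmutated here; mutation
    happens at germination).
    """
    dp = 1 if xs_unif(rs) < 0.5 else 0
    if n[dp] == 0:
        return
    di = np.random.randint(0, n[dp])
    xd = 0.5 * (x1[dp, di] + x2[dp, di])
    yd = 0.5 * (y1[dp, di] + y2[dp, di])
    a_d = anther_height_core(xd, yd, S[dp, di])
    g_d = stigma_height_core(xd, yd, S[dp, di])
    # self-transfer from the pollinator jostling the flower: wastes pollen
    # and clogs the style, never fertilizes
    nself = self_transfer_count(p[dp, di], abs(a_d - g_d), fp[F_US], fp[F_SS])
    if nself > 0:
        p[dp, di] -= nself
        s[dp, di] += nself
        selfed[dp, di] += nself
    nrem, nstuck = uptake_core(
        p[dp, di], a_d, fp[F_UP], fp[F_SJ], control,
        polkind[dp], polq[dp, 0], polq[dp, 1], polq[dp, 2], buf, rs)
    if nrem > 0:
        p[dp, di] -= nrem
        removed[dp, di] += nrem
    if nstuck == 0:
        return
    # crossover: the pollinator may carry its load to the other patch
    rp = dp
    if fp[F_C] > 0.0 and xs_unif(rs) < fp[F_C]:
        rp = 1 - dp
    if rp == dp:
        if n[rp] < 2:
            return
        ri = np.random.randint(0, n[rp] - 1)
        if ri >= di:
            ri += 1
    else:
        if n[rp] == 0:
            return
        ri = np.random.randint(0, n[rp])
    xr = 0.5 * (x1[rp, ri] + x2[rp, ri])
    yr_ = 0.5 * (y1[rp, ri] + y2[rp, ri])
    stig_r = stigma_height_core(xr, yr_, S[rp, ri])
    Sd = S[dp, di]
    Sr = S[rp, ri]
    inter_morph = Sd != Sr
    sigma_j = fp[F_SJ]
    sigma_p = fp[F_SP]
    # recipient's seasonal state, held in locals across the grain loop
    s_r = s[rp, ri]
    o_r = o[rp, ri]
    nrecv = 0
    nfert = 0
    for k in range(nstuck):
        if not deliver_core(buf[k], stig_r, sigma_j, sigma_p, control, rs):
            continue
        s0 = s_r
        s_r += 1
        nrecv += 1
        if inter_morph and o_r > 0:
            pf = fertilization_prob(s0, n_s)
            if pf > 0.0 and xs_unif(rs) < pf:
                o_r -= 1
                nfert += 1
                k2 = nseeds[rp]
                smx1[rp, k2] = x1[rp, ri]
                smx2[rp, k2] = x2[rp, ri]
                smy1[rp, k2] = y1[rp, ri]
                smy2[rp, k2] = y2[rp, ri]
                smz1[rp, k2] = z1[rp, ri]
                smz2[rp, k2] = z2[rp, ri]
                smS[rp, k2] = Sr
                # paternal gamete: one allele per trait from this grain
                sfx[rp, k2] = x1[dp, di] if xs_unif(rs) < 0.5 \
                    else x2[dp, di]
                sfy[rp, k2] = y1[dp, di] if xs_unif(rs) < 0.5 \
                    else y2[dp, di]
                sfz[rp, k2] = z1[dp, di] if xs_unif(rs) < 0.5 \
                    else z2[dp, di]
                sfS[rp, k2] = Sd
                sres[rp, k2] = 1 if dp == rp else 0
                smidx[rp, k2] = ri
                nseeds[rp] += 1
    s[rp, ri] = s_r
    o[rp, ri] = o_r
    received[rp, ri] += nrecv
    if nfert > 0:
        if dp == rp:
            fert_res[rp] += nfert
        else:
            fert_mig[rp] += nfert


@njit(cache=True)
def season_core(fp, ip, polkind, polq,
                x1, x2, y1, y2, z1, z2, S, o, p, s, n,
                smx1, smx2, smy1, smy2, smz1, smz2, smS,
                sfx, sfy, sfz, sfS, sres, smidx, nseeds,
                fert_res, fert_mig, removed, selfed, received, buf, rs):
    """Run v pollination events."""
    control = ip[I_CONTROL] == 1
    n_s = ip[I_NS]
    for _ in range(ip[I_V]):
        event_core(fp, control, n_s, polkind, polq,
                   x1, x2, y1, y2, z1, z2, S, o, p, s, n,
                   smx1, smx2, smy1, smy2, smz1, smz2, smS,
                   sfx, sfy, sfz, sfS, sres, smidx,
                   nseeds, fert_res, fert_mig, removed, selfed, received,
                   buf, rs)


@njit(cache=True)
def dimorphism_core(pt, x1, x2, y1, y2, S, n):
    """Reciprocal-herkogamy dimorphism index of one patch.

    Morph-conditioned mean organ heights: dstig = mean stigma height of
    S=0 minus that of S=1; danth likewise for anthers.  When the two
    differences have opposite signs the morphs are reciprocal and the
    index is min(|dstig|, |danth|); otherwise 0.  Returns
    (index, dstig, n_S0, n_S1).
    """
    s0x = 0.0
    s0y = 0.0
    s1x = 0.0
    s1y = 0.0
    n0 = 0
    n1 = 0
    for i in range(n[pt]):
        px = 0.5 * (x1[pt, i] + x2[pt, i])
        py = 0.5 * (y1[pt, i] + y2[pt, i])
        if S[pt, i] == 0:
            s0x += px
            s0y += py
            n0 += 1
        else:
            s1x += px
            s1y += py
            n1 += 1
    if n0 == 0 or n1 == 0:
        return 0.0, 0.0, n0, n1
    stig0 = s0x / n0   # S=0: stigma at x
    anth0 = s0y / n0
    stig1 = s1y / n1   # S=1: stigma at y
    anth1 = s1x / n1
    dstig = stig0 - stig1
    danth = anth0 - anth1
    if dstig * danth < 0.0:
        a = abs(dstig)
        b = abs(danth)
        idx = a if a < b else b
    else:
        idx = 0.0
    return idx, dstig, n0, n1


@njit(cache=True)
def simulate(fp, ip, polkind, polq, dim_threshold):
    """Run one full realization; see module docstring for the RNG contract.

    Returns final phenotype census, per-year time series, and diagnostics.
    """
    _seed_mt(ip[I_SEED])
    rs = np.zeros(4, dtype=np.uint64)
    xs_seed(rs, ip[I_SEED])
    K = ip[I_K]
    n_o = ip[I_NO]
    n_p = ip[I_NP]
    years = ip[I_YEARS]
    seedcap = K * n_o

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

    smx1 = np.empty((2, seedcap))
    smx2 = np.empty((2, seedcap))
    smy1 = np.empty((2, seedcap))
    smy2 = np.empty((2, seedcap))
    smz1 = np.empty((2, seedcap))
    smz2 = np.empty((2, seedcap))
    smS = np.empty((2, seedcap), dtype=np.int8)
    sfx = np.empty((2, seedcap))
    sfy = np.empty((2, seedcap))
    sfz = np.empty((2, seedcap))
    sfS = np.empty((2, seedcap), dtype=np.int8)
    sres = np.empty((2, seedcap), dtype=np.int8)
    smidx = np.empty((2, seedcap), dtype=np.int32)
    nseeds = np.zeros(2, dtype=np.int64)

    fert_res = np.zeros(2, dtype=np.int64)
    fert_mig = np.zeros(2, dtype=np.int64)
    removed = np.zeros((2, K), dtype=np.int64)
    selfed = np.zeros((2, K), dtype=np.int64)
    received = np.zeros((2, K), dtype=np.int64)
    buf = np.empty(n_p)

    tidx = np.empty(seedcap, dtype=np.int64)
    tz1 = np.empty(seedcap)
    tz2 = np.empty(seedcap)

    ts = np.zeros((years, 2, NTS))
    tdim = np.zeros(2, dtype=np.int64)   # 0 = criterion never met
    theta = np.empty(2)
    theta[0] = fp[F_TH1]
    theta[1] = fp[F_TH2]

    nclip = init_arrays(fp, K, x1, x2, y1, y2, z1, z2, S, o, p, s, n,
                        n_o, n_p, rs)

    extinct = 0
    years_run = 0
    for year in range(1, years + 1):
        for pt in range(2):
            germination_core(pt, theta[pt], fp, K,
                             x1, x2, y1, y2, z1, z2, S, o, p, s, n,
                             smx1, smx2, smy1, smy2, smz1, smz2, smS,
                             sfx, sfy, sfz, sfS, sres, smidx, nseeds,
                             n_o, n_p, tidx, tz1, tz2, rs)
        for pt in range(2):
            mortality_core(pt, fp[F_M], x1, x2, y1, y2, z1, z2,
                           S, o, p, s, n, rs)
        if n[0] == 0 or n[1] == 0:
            extinct = 1 if n[0] == 0 else 2
            years_run = year
            break
        # seasonal reset: new flowers, seed stores and tallies cleared
        for pt in range(2):
            for i in range(n[pt]):
                o[pt, i] = n_o
                p[pt, i] = n_p
                s[pt, i] = 0
                removed[pt, i] = 0
                selfed[pt, i] = 0
                received[pt, i] = 0
            nseeds[pt] = 0
            fert_res[pt] = 0
            fert_mig[pt] = 0
        season_core(fp, ip, polkind, polq,
                    x1, x2, y1, y2, z1, z2, S, o, p, s, n,
                    smx1, smx2, smy1, smy2, smz1, smz2, smS,
                    sfx, sfy, sfz, sfS, sres, smidx,
                    nseeds, fert_res, fert_mig, removed, selfed, received,
                    buf, rs)
        yr = year - 1
        for pt in range(2):
            idx, dstig, n0, n1 = dimorphism_core(pt, x1, x2, y1, y2, S, n)
            zsum = 0.0
            osum = 0.0
            for i in range(n[pt]):
                zsum += 0.5 * (z1[pt, i] + z2[pt, i])
                osum += o[pt, i]
            ts[yr, pt, TS_N] = n[pt]
            ts[yr, pt, TS_SEEDS] = nseeds[pt]
            ts[yr, pt, TS_ZBAR] = zsum / n[pt]
            s0x = 0.0
            s0y = 0.0
            s1x = 0.0
            s1y = 0.0
            for i in range(n[pt]):
                px = 0.5 * (x1[pt, i] + x2[pt, i])
                py = 0.5 * (y1[pt, i] + y2[pt, i])
                if S[pt, i] == 0:
                    s0x += px
                    s0y += py
                else:
                    s1x += px
                    s1y += py
            if n0 > 0:
                ts[yr, pt, TS_STIG0] = s0x / n0
                ts[yr, pt, TS_ANTH0] = s0y / n0
            else:
                ts[yr, pt, TS_STIG0] = np.nan
                ts[yr, pt, TS_ANTH0] = np.nan
            if n1 > 0:
                ts[yr, pt, TS_STIG1] = s1y / n1
                ts[yr, pt, TS_ANTH1] = s1x / n1
            else:
                ts[yr, pt, TS_STIG1] = np.nan
                ts[yr, pt, TS_ANTH1] = np.nan
            ts[yr, pt, TS_FERT_RES] = fert_res[pt]
            ts[yr, pt, TS_FERT_MIG] = fert_mig[pt]
            ts[yr, pt, TS_MEAN_O] = osum / n[pt]
            ts[yr, pt, TS_DIM] = idx
            if idx > dim_threshold and tdim[pt] == 0:
                tdim[pt] = year
        years_run = year
        if ip[I_EARLY] == 1 and tdim[0] > 0 and tdim[1] > 0:
            break

    xp = 0.5 * (x1 + x2)
    yp = 0.5 * (y1 + y2)
    zp = 0.5 * (z1 + z2)
    return (xp, yp, zp, S, o, p, s, n,
            ts[:years_run], tdim, extinct, years_run, nclip,
            fert_res, fert_mig, removed, selfed, received,
            smidx, sres, nseeds)
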