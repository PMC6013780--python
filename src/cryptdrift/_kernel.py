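"""Numba kernels for crypt ensemble simulation.

Two engines share the same niche update rule (synchronous weekly division,
asymmetric vs symmetric fate outcome on a ring of N stem cells):

* the multiscale engine tracks the full per-cell mtDNA population (mutation,
  relaxed replication, hypergeometric segregation, threshold deficiency);
* the induction engine replaces the mtDNA layer with an irreversible
  stochastic labelling event at a prescribed time-dependent rate — the exact
  stochastic counterpart of the analytic birth--death clone model.

Both kernels use numba's global RNG, seeded once per call, so a given seed
reproduces a run bit-exactly.  Per-cell mutant lineages are stored in a fixed
number of slots; the slot budget (24) is far above the number of lineages
that can realistically segregate in one cell at copy number 200.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LMAX = 24  # lineage slots per cell
_POOLMAX = LMAX + 8


@njit(cache=True)
def _shuffle_inplace(order):
    n = order.shape[0]
    for i in range(n):
        order[i] = i
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp


@njit(cache=True)
def _hypergeom(ngood, nbad, nsample):
    """Exact hypergeometric draw by a sequential inclusion chain.

    Sampling ``nsample`` of ``ngood + nbad`` items without replacement, each
    successive marked item is included with probability
    (slots left)/(items left).  Symmetries (marked <-> unmarked, sample <->
    complement) keep the loop over the smallest of the four groups, which
    for mtDNA pools is usually a handful of molecules.
    """
    tot = ngood + nbad
    if nsample <= 0:
        return 0
    if nsample >= tot:
        return ngood
    flip_sample = False
    if nsample > tot - nsample:
        nsample = tot - nsample
        flip_sample = True
    flip_good = False
    g = ngood
    if ngood > nbad:
        g = nbad
        flip_good = True
    y = 0
    k = nsample
    t = tot
    for _ in range(g):
        if k <= 0:
            break
        if np.random.random() * t < k:
            y += 1
            k -= 1
        t -= 1
    if flip_good:
        x = nsample - y  # y counted the (smaller) unmarked group
    else:
        x = y
    if flip_sample:
        x = ngood - x
    return x


@njit(cache=True)
def _draw_partition(poolc, npool, rem_total, m, dA):
    """Fill ``dA`` with daughter-A per-lineage counts from a sequential
    multivariate hypergeometric split of the doubled pool; returns the
    leftover draw assigned to the wild-type remainder."""
    rem = rem_total
    need = m
    for s in range(npool):
        cs = poolc[s]
        if need <= 0 or cs <= 0:
            x = 0
        elif need >= rem:
            x = cs
        else:
            x = _hypergeom(cs, rem - cs, need)
        dA[s] = x
        need -= x
        rem -= cs
    return need  # daughter-A wild-type draw


@njit(cache=True)
def _write_daughter(counts, ids, nslots, i, poolid, dcounts, npool):
    # slots at index >= nslots[i] are never read, so no need to zero them
    k = 0
    for s in range(npool):
        if dcounts[s] > 0 and k < LMAX:
            counts[i, k] = dcounts[s]
            ids[i, k] = poolid[s]
            k += 1
    nslots[i] = k


@njit(cache=True)
def _clonality(counts, ids, nslots, n_sc, theta_count):
    """Distinct dominant lineages among deficient cells (0 if none)."""
    doms = np.zeros(n_sc, np.int64)
    nd = 0
    for i in range(n_sc):
        tot = 0
        best = 0
        bestc = 0
        for s in range(nslots[i]):
            tot += counts[i, s]
            if counts[i, s] > bestc or (
                counts[i, s] == bestc and bestc > 0 and ids[i, s] < best
            ):
                bestc = counts[i, s]
                best = ids[i, s]
        if tot >= theta_count:
            doms[nd] = best
            nd += 1
    distinct = 0
    for a in range(nd):
        seen = False
        for b in range(a):
            if doms[b] == doms[a]:
                seen = True
                break
        if not seen:
            distinct += 1
    return distinct


@njit(cache=True)
def run_mtdna_ensemble(
    n_crypts,
    n_sc,
    copy_number,
    n_gens,
    years_per_gen,
    mu_start,
    mu_end,
    mu_t_end,
    p_asym,
    theta_count,
    record_gens,
    mu_scale,
    init_mut_count,
    replace_any,
    resample_scheme,
    seed,
):
    """Simulate ``n_crypts`` independent crypts under the multiscale model.

    Returns (k_deficient, clonality, n_replacements) where the first two are
    (n_crypts, len(record_gens)) arrays sampled after the stated number of
    completed generations, and n_replacements counts symmetric
    loss/replacement events over the whole run.
    """
    np.random.seed(seed)
    m = copy_number
    n_rec = record_gens.shape[0]
    k_def = np.zeros((n_crypts, n_rec), np.int64)
    clon = np.zeros((n_crypts, n_rec), np.int64)
    n_repl = 0
    next_id = 1

    counts = np.zeros((n_sc, LMAX), np.int64)
    ids = np.zeros((n_sc, LMAX), np.int64)
    nslots = np.zeros(n_sc, np.int64)
    poolc = np.zeros(_POOLMAX, np.int64)
    poolid = np.zeros(_POOLMAX, np.int64)
    dA = np.zeros(_POOLMAX, np.int64)
    dB = np.zeros(_POOLMAX, np.int64)
    replaced = np.zeros(n_sc, np.uint8)
    order = np.zeros(n_sc, np.int64)

    log_ratio = np.log(mu_end / mu_start)

    for c in range(n_crypts):
        counts[:, :] = 0
        ids[:, :] = 0
        nslots[:] = 0
        if init_mut_count > 0:
            counts[0, 0] = init_mut_count
            ids[0, 0] = next_id
            nslots[0] = 1
        if init_mut_count > 0:
            next_id += 1

        rec = 0
        while rec < n_rec and record_gens[rec] == 0:
            kd = 0
            for i in range(n_sc):
                tot = 0
                for s in range(nslots[i]):
                    tot += counts[i, s]
                if tot >= theta_count:
                    kd += 1
            k_def[c, rec] = kd
            clon[c, rec] = _clonality(counts, ids, nslots, n_sc, theta_count)
            rec += 1

        for g in range(1, n_gens + 1):
            t = g * years_per_gen
            mu = mu_start * np.exp(log_ratio * t / mu_t_end) * mu_scale[c]
            if mu > 0.999:
                mu = 0.999
            _shuffle_inplace(order)
            replaced[:] = 0
            for oi in range(n_sc):
                i = order[oi]
                if replaced[i]:
                    continue  # expunged before its turn: division pre-empted
                ns = nslots[i]
                wt = m
                npool = 0
                if resample_scheme:
                    # 2M molecules drawn with replacement from the parent
                    # composition; sequential binomial thinning.
                    tot_par = m
                    rem_draw = 2 * m
                    for s in range(ns):
                        cpar = counts[i, s]
                        wt -= cpar
                        if rem_draw > 0 and cpar > 0:
                            x = np.random.binomial(rem_draw, cpar / tot_par)
                        else:
                            x = 0
                        if x > 0:
                            poolc[npool] = x
                            poolid[npool] = ids[i, s]
                            npool += 1
                        rem_draw -= x
                        tot_par -= cpar
                    wt_pool = rem_draw
                else:
                    for s in range(ns):
                        if counts[i, s] > 0:
                            poolc[npool] = 2 * counts[i, s]
                            poolid[npool] = ids[i, s]
                            npool += 1
                            wt -= counts[i, s]
                    wt_pool = 2 * wt
                if mu > 0.0 and wt_pool > 0:
                    if resample_scheme:
                        n_new = np.random.binomial(wt_pool, mu)
                    else:
                        n_new = np.random.binomial(wt, mu)
                else:
                    n_new = 0

                if npool == 0 and n_new == 0:
                    # all-wild-type division: daughters equal the parent
                    u = np.random.random()
                    if u >= p_asym:
                        n_repl += 1
                        if replace_any:
                            j = i
                            while j == i:
                                j = np.random.randint(0, n_sc)
                        else:
                            if np.random.random() < 0.5:
                                j = (i + 1) % n_sc
                            else:
                                j = (i - 1) % n_sc
                        nslots[j] = 0
                        replaced[j] = 1
                    continue

                for _ in range(n_new):
                    if npool < _POOLMAX:
                        poolc[npool] = 1
                        poolid[npool] = next_id
                        npool += 1
                        wt_pool -= 1
                    next_id += 1

                _draw_partition(poolc, npool, 2 * m, m, dA)
                for s in range(npool):
                    dB[s] = poolc[s] - dA[s]
                # wild-type counts enter implicitly: daughters hold M total

                u = np.random.random()
                if u < p_asym:
                    if np.random.random() < 0.5:
                        _write_daughter(counts, ids, nslots, i, poolid, dA, npool)
                    else:
                        _write_daughter(counts, ids, nslots, i, poolid, dB, npool)
                else:
                    n_repl += 1
                    if replace_any:
                        j = i
                        while j == i:
                            j = np.random.randint(0, n_sc)
                    else:
                        if np.random.random() < 0.5:
                            j = (i + 1) % n_sc
                        else:
                            j = (i - 1) % n_sc
                    if np.random.random() < 0.5:
                        _write_daughter(counts, ids, nslots, i, poolid, dA, npool)
                        _write_daughter(counts, ids, nslots, j, poolid, dB, npool)
                    else:
                        _write_daughter(counts, ids, nslots, i, poolid, dB, npool)
                        _write_daughter(counts, ids, nslots, j, poolid, dA, npool)
                    replaced[j] = 1

            while rec < n_rec and record_gens[rec] == g:
                kd = 0
                for i in range(n_sc):
                    tot = 0
                    for s in range(nslots[i]):
                        tot += counts[i, s]
                    if tot >= theta_count:
                        kd += 1
                k_def[c, rec] = kd
                clon[c, rec] = _clonality(counts, ids, nslots, n_sc, theta_count)
                rec += 1
            if rec >= n_rec and g < n_gens:
                break  # nothing left to record

    return k_def, clon, n_repl


@njit(cache=True)
def run_induction_ensemble(
    n_crypts,
    n_sc,
    n_gens,
    years_per_gen,
    r0_abs,
    eta,
    p_asym,
    record_gens,
    rate_scale,
    init_labelled,
    replace_any,
    seed,
):
    """Niche dynamics with irreversible stochastic labelling (induction).

    ``r0_abs`` is the absolute induction rate per crypt per year at t=0,
    growing as exp(eta * t); per cell and generation the labelling
    probability is r(t) * years_per_gen / n_sc.  ``init_labelled`` starts
    each crypt with one labelled cell (for pure drift experiments).
    Returns (k_labelled, clonality, n_replacements).
    """
    np.random.seed(seed)
    n_rec = record_gens.shape[0]
    k_lab = np.zeros((n_crypts, n_rec), np.int64)
    clon = np.zeros((n_crypts, n_rec), np.int64)
    n_repl = 0
    next_id = 1
    labels = np.zeros(n_sc, np.int64)
    replaced = np.zeros(n_sc, np.uint8)
    order = np.zeros(n_sc, np.int64)

    for c in range(n_crypts):
        labels[:] = 0
        if init_labelled:
            labels[0] = next_id
        if init_labelled:
            next_id += 1

        rec = 0
        while rec < n_rec and record_gens[rec] == 0:
            kd = 0
            for i in range(n_sc):
                if labels[i] > 0:
                    kd += 1
            k_lab[c, rec] = kd
            clon[c, rec] = _label_clonality(labels, n_sc)
            rec += 1

        for g in range(1, n_gens + 1):
            t = g * years_per_gen
            p_ind = r0_abs * np.exp(eta * t) * years_per_gen / n_sc * rate_scale[c]
            if p_ind > 1.0:
                p_ind = 1.0
            _shuffle_inplace(order)
            replaced[:] = 0
            for oi in range(n_sc):
                i = order[oi]
                if replaced[i]:
                    continue
                if labels[i] == 0 and p_ind > 0.0:
                    if np.random.random() < p_ind:
                        labels[i] = next_id
                        next_id += 1
                u = np.random.random()
                if u < p_asym:
                    pass  # clonal configuration unchanged
                else:
                    n_repl += 1
                    if replace_any:
                        j = i
                        while j == i:
                            j = np.random.randint(0, n_sc)
                    else:
                        if np.random.random() < 0.5:
                            j = (i + 1) % n_sc
                        else:
                            j = (i - 1) % n_sc
                    labels[j] = labels[i]
                    replaced[j] = 1

            while rec < n_rec and record_gens[rec] == g:
                kd = 0
                for i in range(n_sc):
                    if labels[i] > 0:
                        kd += 1
                k_lab[c, rec] = kd
                clon[c, rec] = _label_clonality(labels, n_sc)
                rec += 1
            if rec >= n_rec and g < n_gens:
                break

    return k_lab, clon, n_repl


@njit(cache=True)
def _label_clonality(labels, n_sc):
    distinct = 0
    for a in range(n_sc):
        if labels[a] == 0:
            continue
        seen = False
        for b in range(a):
            if labels[b] == labels[a]:
                seen = True
                break
        if not seen:
            distinct += 1
    return distinct
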