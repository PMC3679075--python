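"""Plain-Python reference implementation of the Monte Carlo engine.

Deliberately written without the package's compiled kernels, in the most
literal style possible, and drawing from the RNG in the same documented
order (selection sweep in member order; per death: parent pair, gamete 1,
gamete 2; per gamete: mutation count+positions per copy, crossover
count+sites, product choice, hotspot toggle).  Used by the tests to check
that the fast engine is bit-for-bit the same algorithm.
"""

from __future__ import annotations

import numpy as np


def draw_count(rng, mean):
    if mean <= 0:
        return 0
    u = rng.random() * 2 * mean
    n = int(u)
    if rng.random() < u - n:
        n += 1
    return n


def ref_gamete(g0, g1, h0, h1, M, C, hotspot_mutation, gene_reversions,
               single_recomb, bootstrap, rng):
    g0, g1, h0, h1 = g0.copy(), g1.copy(), h0.copy(), h1.copy()
    L = len(g0)
    S = L - 1
    for g in (g0, g1):
        for _ in range(draw_count(rng, M)):
            pos = int(rng.integers(0, L))
            if g[pos] == 0:
                g[pos] = 1
            elif gene_reversions:
                g[pos] = 0
    k = draw_count(rng, C)
    if k:
        if single_recomb:
            allowed = [s for s in range(S) if h0[s] | h1[s]]
        else:
            allowed = [s for s in range(S) if h0[s] & h1[s]]
        total = len(allowed)
        for _ in range(k):
            if not allowed:
                if total == 0 and bootstrap:
                    site = int(rng.integers(0, S))
                    h0[site] = h1[site] = 1
                    _swap_tails(g0, g1, h0, h1, site)
                break
            r = int(rng.integers(0, len(allowed)))
            site = allowed.pop(r)
            _swap_tails(g0, g1, h0, h1, site)
    which = int(rng.integers(0, 2))
    gs, hs = (g0, h0) if which == 0 else (g1, h1)
    if hotspot_mutation:
        pos = int(rng.integers(0, S))
        hs[pos] ^= 1
    return gs, hs


def _swap_tails(g0, g1, h0, h1, site):
    g0[site + 1:], g1[site + 1:] = g1[site + 1:].copy(), g0[site + 1:].copy()
    h0[site + 1:], h1[site + 1:] = h1[site + 1:].copy(), h0[site + 1:].copy()


def ref_step(genes, hots, params, rng):
    """One MC step in place; returns the death count."""
    N, _, L = genes.shape
    d = (genes[:, 0] & genes[:, 1]).sum(axis=1)
    surv, dead = [], []
    for i in range(N):
        p = params.x if params.neutral_mode else params.x ** (int(d[i]) + 1)
        (surv if rng.random() < p else dead).append(i)
    if len(surv) < 2:
        raise RuntimeError("extinct")
    for slot in dead:
        while True:
            i1 = surv[int(rng.integers(0, len(surv)))]
            i2 = i1
            while i2 == i1:
                i2 = surv[int(rng.integers(0, len(surv)))]
            gA, hA = ref_gamete(genes[i1, 0], genes[i1, 1], hots[i1, 0],
                                hots[i1, 1], params.M, params.C,
                                params.hotspot_mutation, params.gene_reversions,
                                params.single_hotspot_recomb,
                                params.bootstrap_hotspots, rng)
            gB, hB = ref_gamete(genes[i2, 0], genes[i2, 1], hots[i2, 0],
                                hots[i2, 1], params.M, params.C,
                                params.hotspot_mutation, params.gene_reversions,
                                params.single_hotspot_recomb,
                                params.bootstrap_hotspots, rng)
            genes[slot, 0], genes[slot, 1] = gA, gB
            hots[slot, 0], hots[slot, 1] = hA, hB
            dd = int((gA & gB).sum())
            if not params.viable_births:
                break
            pv = params.x if params.neutral_mode else params.x ** (dd + 1)
            if rng.random() < pv:
                break
    return len(dead)
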