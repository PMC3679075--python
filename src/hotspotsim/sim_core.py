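"""Forward-time Monte Carlo engine for diploid bitstring chromosomes.

Each individual carries two homologous chromosomes represented as
bit-vectors of ``L`` genes (0 = wild allele, 1 = defective, recessive) plus
a bit-vector over the ``L - 1`` intergenic sites marking recombination
hotspots.  A Monte Carlo step applies viability selection — an individual
with ``d`` homozygous defective loci survives with probability
``x**(d + 1)`` — and replaces every death with a newborn produced by two
uniformly drawn surviving parents.  Gametes are formed by copying the
parental chromosomes, mutating genes, crossing over only at "allowed"
sites (where both copies carry a hotspot), and toggling one uniformly
chosen hotspot bit on the transmitted chromosome.  Hotspot locations are
therefore inherited, reshuffled by recombination, and churned by the
toggle process; any large-scale structure in their distribution is
self-organized by the selection acting on genes alone.

The hot loop is compiled with numba and mutates flat ``uint8`` arrays in
place; the dataclass layer (:class:`Haplotype`, :class:`Individual`,
:class:`Population`) gives a convenient object view over the same memory.
All randomness is drawn from a single :class:`numpy.random.Generator`,
shared between the compiled kernels and the Python-level operations, so a
seed fixes the entire trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .params import ConfigError, RunOptions, SimParams

__all__ = [
    "Haplotype",
    "Individual",
    "Population",
    "RunResult",
    "ExtinctionError",
    "init_population",
    "homozygous_defect_count",
    "survival_probability",
    "selection",
    "draw_event_count",
    "mutate_genes",
    "allowed_positions",
    "crossover",
    "make_gamete",
    "toggle_hotspot",
    "make_offspring",
    "mc_step",
    "run",
]


class ExtinctionError(RuntimeError):
    """Fewer than two survivors remain; the population cannot reproduce."""

    def __init__(self, step: int, trajectory: pd.DataFrame | None = None):
        super().__init__(f"population extinct at MC step {step}")
        self.step = step
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# object layer

@dataclass
class Haplotype:
    """One chromosome: gene bits (length L) + hotspot bits (length L-1)."""

    genes: np.ndarray
    hotspots: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.uint8)
        self.hotspots = np.asarray(self.hotspots, dtype=np.uint8)
        if self.genes.ndim != 1 or self.hotspots.ndim != 1:
            raise ValueError("gene and hotspot vectors must be 1-D")
        if self.hotspots.shape[0] != self.genes.shape[0] - 1:
            raise ValueError(
                f"hotspot vector must have length L-1 "
                f"({self.genes.shape[0] - 1}), got {self.hotspots.shape[0]}"
            )

    @property
    def L(self) -> int:
        return self.genes.shape[0]

    def copy(self) -> "Haplotype":
        return Haplotype(self.genes.copy(), self.hotspots.copy())


@dataclass
class Individual:
    """A diploid genome: two homologous haplotypes of equal length."""

    hap1: Haplotype
    hap2: Haplotype

    def __post_init__(self) -> None:
        if self.hap1.L != self.hap2.L:
            raise ValueError("haplotypes must share L")

    @property
    def L(self) -> int:
        return self.hap1.L

    def copy(self) -> "Individual":
        return Individual(self.hap1.copy(), self.hap2.copy())


class Population:
    """Fixed-size collection of diploid individuals, stored as flat arrays.

    ``genes`` has shape ``(N, 2, L)`` and ``hotspots`` ``(N, 2, L-1)``,
    both ``uint8``.  Indexing returns an :class:`Individual` whose arrays
    are *views* into the population storage.
    """

    def __init__(self, genes: np.ndarray, hotspots: np.ndarray, step: int = 0):
        genes = np.ascontiguousarray(genes, dtype=np.uint8)
        hotspots = np.ascontiguousarray(hotspots, dtype=np.uint8)
        if genes.ndim != 3 or genes.shape[1] != 2:
            raise ValueError("genes must have shape (N, 2, L)")
        if hotspots.shape != (genes.shape[0], 2, genes.shape[2] - 1):
            raise ValueError("hotspots must have shape (N, 2, L-1)")
        self.genes = genes
        self.hotspots = hotspots
        self.step = step

    @classmethod
    def empty(cls, N: int, L: int) -> "Population":
        return cls(np.zeros((N, 2, L), np.uint8), np.zeros((N, 2, L - 1), np.uint8))

    @property
    def N(self) -> int:
        return self.genes.shape[0]

    @property
    def L(self) -> int:
        return self.genes.shape[2]

    def __len__(self) -> int:
        return self.N

    def __getitem__(self, i: int) -> Individual:
        return Individual(
            Haplotype(self.genes[i, 0], self.hotspots[i, 0]),
            Haplotype(self.genes[i, 1], self.hotspots[i, 1]),
        )

    @property
    def members(self) -> list[Individual]:
        return [self[i] for i in range(self.N)]

    def copy(self) -> "Population":
        return Population(self.genes.copy(), self.hotspots.copy(), self.step)

    def homozygous_defects(self) -> np.ndarray:
        """Per-individual count of homozygous defective loci (``d``)."""
        return (self.genes[:, 0, :] & self.genes[:, 1, :]).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# compiled kernels (single RNG stream shared with the Python layer)

@njit(cache=True)
def _draw_event_count(rng, mean):
    if mean <= 0.0:
        return 0
    u = rng.random() * 2.0 * mean
    n = int(u)
    if rng.random() < u - n:
        n += 1
    return n


@njit(cache=True)
def _apply_mutations(genes, n_mut, reversions, rng):
    L = genes.shape[0]
    for _ in range(n_mut):
        pos = rng.integers(0, L)
        if genes[pos] == 0:
            genes[pos] = 1
        elif reversions:
            genes[pos] = 0


@njit(cache=True)
def _crossover_inplace(g, h, site):
    # reciprocal exchange of everything to the right of intergenic `site`;
    # the site's own hotspot bits stay with the left segment
    # (explicit element loops: LLVM vectorizes them, slice ops do not)
    g0, g1 = g[0], g[1]
    for j in range(site + 1, g0.shape[0]):
        t = g0[j]
        g0[j] = g1[j]
        g1[j] = t
    h0, h1 = h[0], h[1]
    for j in range(site + 1, h0.shape[0]):
        t = h0[j]
        h0[j] = h1[j]
        h1[j] = t


@njit(cache=True)
def _gamete_from_copies(g, h, M, C, hotspot_mutation, gene_reversions,
                        single_recomb, bootstrap, mask, rng):
    """Mutate/recombine the two chromosome copies in ``g``/``h`` (in place)
    and return which copy (0 or 1) becomes the gamete.  ``mask`` is scratch
    of length L-1 for sampling crossover sites without replacement."""
    S = h.shape[1]
    _apply_mutations(g[0], _draw_event_count(rng, M), gene_reversions, rng)
    _apply_mutations(g[1], _draw_event_count(rng, M), gene_reversions, rng)
    k = _draw_event_count(rng, C)
    if k > 0:
        h0, h1 = h[0], h[1]
        cnt = 0
        if single_recomb:
            for s in range(S):
                m = h0[s] | h1[s]
                mask[s] = m
                cnt += m
        else:
            for s in range(S):
                m = h0[s] & h1[s]
                mask[s] = m
                cnt += m
        total_allowed = cnt
        for _ in range(k):
            if cnt == 0:
                if total_allowed == 0 and bootstrap:
                    site = rng.integers(0, S)
                    h[0, site] = 1
                    h[1, site] = 1
                    _crossover_inplace(g, h, site)
                    total_allowed = 1
                break
            # uniform over the not-yet-used allowed sites: pick the r-th
            # remaining set bit of the mask
            r = rng.integers(0, cnt)
            site = -1
            for s in range(S):
                if mask[s] != 0:
                    if r == 0:
                        site = s
                        break
                    r -= 1
            _crossover_inplace(g, h, site)
            mask[site] = 0
            cnt -= 1
    which = rng.integers(0, 2)
    if hotspot_mutation:
        pos = rng.integers(0, S)
        h[which, pos] ^= np.uint8(1)
    return which


@njit(cache=True)
def _load_parent(genes, hots, i, sg, sh):
    L = genes.shape[2]
    for j in range(L):
        sg[0, j] = genes[i, 0, j]
        sg[1, j] = genes[i, 1, j]
    for j in range(L - 1):
        sh[0, j] = hots[i, 0, j]
        sh[1, j] = hots[i, 1, j]


@njit(cache=True)
def _store_gamete(genes, hots, slot, hap, sg, sh, w):
    L = genes.shape[2]
    for j in range(L):
        genes[slot, hap, j] = sg[w, j]
    for j in range(L - 1):
        hots[slot, hap, j] = sh[w, j]


#: bound on re-drawn parent pairs per replacement under viable_births;
#: at the organized steady state a handful of tries suffice
MAX_BIRTH_RETRIES = 1000


# ---------------------------------------------------------------------------
# bit-packed (uint64) engine: same algorithm, same RNG draw sequence as the
# byte kernels, ~5x faster; used by the run() loop

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_ONE = np.uint64(1)


@njit(cache=True, inline="always")
def _popcount(v):
    v = v - ((v >> _ONE) & _M1)
    v = (v & _M2) + ((v >> np.uint64(2)) & _M2)
    v = (v + (v >> np.uint64(4))) & _M4
    return int((v * _H01) >> np.uint64(56))


@njit(cache=True)
def _pack_bits(bits, words):
    """bits: (..., n) uint8 -> words: (..., ceil(n/64)) uint64, LSB first."""
    flat_b = bits.reshape(-1, bits.shape[-1])
    flat_w = words.reshape(-1, words.shape[-1])
    n = bits.shape[-1]
    for r in range(flat_b.shape[0]):
        for w in range(flat_w.shape[1]):
            flat_w[r, w] = 0
        for j in range(n):
            if flat_b[r, j]:
                flat_w[r, j >> 6] |= _ONE << np.uint64(j & 63)


@njit(cache=True)
def _unpack_bits(words, bits):
    flat_b = bits.reshape(-1, bits.shape[-1])
    flat_w = words.reshape(-1, words.shape[-1])
    n = bits.shape[-1]
    for r in range(flat_b.shape[0]):
        for j in range(n):
            flat_b[r, j] = (flat_w[r, j >> 6] >> np.uint64(j & 63)) & _ONE


@njit(cache=True)
def _flip_bit(row, pos):
    row[pos >> 6] ^= _ONE << np.uint64(pos & 63)


@njit(cache=True)
def _get_bit(row, pos):
    return int((row[pos >> 6] >> np.uint64(pos & 63)) & _ONE)


@njit(cache=True)
def _swap_tail(a, b, first):
    """Swap bits at positions >= first between rows a and b (same length)."""
    wb = first >> 6
    if wb >= a.shape[0]:
        return
    keep = np.uint64((1 << (first & 63)) - 1)
    t = (a[wb] ^ b[wb]) & ~keep
    a[wb] ^= t
    b[wb] ^= t
    for w in range(wb + 1, a.shape[0]):
        t = a[w] ^ b[w]
        a[w] ^= t
        b[w] ^= t


@njit(cache=True)
def _gamete_packed(gw, hw, L, S, M, C, hotspot_mutation, gene_reversions,
                   single_recomb, bootstrap, allow, rng):
    """Packed counterpart of :func:`_gamete_from_copies`: identical logic
    and identical RNG draw order on (2, Wg)/(2, Wh) uint64 copies.
    ``allow`` is scratch of Wh words for the not-yet-used allowed mask."""
    # mutations on each copy
    for c in range(2):
        n_mut = _draw_event_count(rng, M)
        for _ in range(n_mut):
            pos = rng.integers(0, L)
            if _get_bit(gw[c], pos) == 0:
                _flip_bit(gw[c], pos)
            elif gene_reversions:
                _flip_bit(gw[c], pos)
    k = _draw_event_count(rng, C)
    if k > 0:
        cnt = 0
        for w in range(allow.shape[0]):
            if single_recomb:
                allow[w] = hw[0, w] | hw[1, w]
            else:
                allow[w] = hw[0, w] & hw[1, w]
            cnt += _popcount(allow[w])
        total_allowed = cnt
        for _ in range(k):
            if cnt == 0:
                if total_allowed == 0 and bootstrap:
                    site = rng.integers(0, S)
                    if _get_bit(hw[0], site) == 0:
                        _flip_bit(hw[0], site)
                    if _get_bit(hw[1], site) == 0:
                        _flip_bit(hw[1], site)
                    _swap_tail(gw[0], gw[1], site + 1)
                    _swap_tail(hw[0], hw[1], site + 1)
                    total_allowed = 1
                break
            r = rng.integers(0, cnt)
            # locate the r-th set bit of the allowed mask
            site = -1
            for w in range(allow.shape[0]):
                pc = _popcount(allow[w])
                if r < pc:
                    v = allow[w]
                    for b in range(64):
                        if (v >> np.uint64(b)) & _ONE:
                            if r == 0:
                                site = (w << 6) + b
                                break
                            r -= 1
                    break
                r -= pc
            _swap_tail(gw[0], gw[1], site + 1)
            _swap_tail(hw[0], hw[1], site + 1)
            allow[site >> 6] &= ~(_ONE << np.uint64(site & 63))
            cnt -= 1
    which = rng.integers(0, 2)
    if hotspot_mutation:
        pos = rng.integers(0, S)
        _flip_bit(hw[which], pos)
    return which


@njit(cache=True)
def _mc_step_packed(genes, hots, d, L, S, x, M, C, hotspot_mutation,
                    gene_reversions, single_recomb, bootstrap, neutral,
                    viable, rng, sg, sh, allow, survivors, dead):
    """Packed counterpart of :func:`_mc_step_kernel` on
    (N, 2, Wg)/(N, 2, Wh) uint64 arrays; same RNG draw sequence."""
    N = genes.shape[0]
    Wg = genes.shape[2]
    Wh = hots.shape[2]
    ns = 0
    nd = 0
    for i in range(N):
        if neutral:
            p = x
        else:
            p = x ** (d[i] + 1)
        if rng.random() < p:
            survivors[ns] = i
            ns += 1
        else:
            dead[nd] = i
            nd += 1
    if ns < 2:
        return -1
    for j in range(nd):
        slot = dead[j]
        for _attempt in range(MAX_BIRTH_RETRIES):
            i1 = survivors[rng.integers(0, ns)]
            i2 = i1
            while i2 == i1:
                i2 = survivors[rng.integers(0, ns)]
            for w in range(Wg):
                sg[0, w] = genes[i1, 0, w]
                sg[1, w] = genes[i1, 1, w]
            for w in range(Wh):
                sh[0, w] = hots[i1, 0, w]
                sh[1, w] = hots[i1, 1, w]
            wch = _gamete_packed(sg, sh, L, S, M, C, hotspot_mutation,
                                 gene_reversions, single_recomb, bootstrap,
                                 allow, rng)
            for w in range(Wg):
                genes[slot, 0, w] = sg[wch, w]
            for w in range(Wh):
                hots[slot, 0, w] = sh[wch, w]
            for w in range(Wg):
                sg[0, w] = genes[i2, 0, w]
                sg[1, w] = genes[i2, 1, w]
            for w in range(Wh):
                sh[0, w] = hots[i2, 0, w]
                sh[1, w] = hots[i2, 1, w]
            wch = _gamete_packed(sg, sh, L, S, M, C, hotspot_mutation,
                                 gene_reversions, single_recomb, bootstrap,
                                 allow, rng)
            for w in range(Wg):
                genes[slot, 1, w] = sg[wch, w]
            for w in range(Wh):
                hots[slot, 1, w] = sh[wch, w]
            dd = 0
            for w in range(Wg):
                dd += _popcount(genes[slot, 0, w] & genes[slot, 1, w])
            d[slot] = dd
            if not viable:
                break
            pv = x if neutral else x ** (dd + 1)
            if rng.random() < pv:
                break
    return nd


@njit(cache=True)
def _packed_summary(genes, hots, Wh_bits):
    """(sum_gene_bits, sum_hom, sum_double, sum_single) over the population,
    computed directly from the packed words."""
    N = genes.shape[0]
    tot = 0
    hom = 0
    dbl = 0
    sng = 0
    for i in range(N):
        for w in range(genes.shape[2]):
            tot += _popcount(genes[i, 0, w]) + _popcount(genes[i, 1, w])
            hom += _popcount(genes[i, 0, w] & genes[i, 1, w])
        for w in range(hots.shape[2]):
            dbl += _popcount(hots[i, 0, w] & hots[i, 1, w])
            sng += _popcount(hots[i, 0, w] ^ hots[i, 1, w])
    return tot, hom, dbl, sng


@njit(cache=True)
def _mc_step_kernel(genes, hots, d, x, M, C, hotspot_mutation, gene_reversions,
                    single_recomb, bootstrap, neutral, viable, rng,
                    sg, sh, used, survivors, dead):
    """One synchronized MC step: selection sweep in member order, then each
    death replaced (in death order) by a newborn from two distinct uniform
    survivors.  With ``viable``, the newborn is tossed against the survival
    rule at birth and the whole replacement is re-drawn until it passes.
    Returns the number of deaths, or -1 on extinction."""
    N = genes.shape[0]
    L = genes.shape[2]
    ns = 0
    nd = 0
    for i in range(N):
        if neutral:
            p = x
        else:
            p = x ** (d[i] + 1)
        if rng.random() < p:
            survivors[ns] = i
            ns += 1
        else:
            dead[nd] = i
            nd += 1
    if ns < 2:
        return -1
    for j in range(nd):
        slot = dead[j]
        for _attempt in range(MAX_BIRTH_RETRIES):
            i1 = survivors[rng.integers(0, ns)]
            i2 = i1
            while i2 == i1:
                i2 = survivors[rng.integers(0, ns)]
            # gamete of parent 1 -> haplotype 0 of the newborn
            _load_parent(genes, hots, i1, sg, sh)
            w = _gamete_from_copies(sg, sh, M, C, hotspot_mutation,
                                    gene_reversions, single_recomb, bootstrap,
                                    used, rng)
            _store_gamete(genes, hots, slot, 0, sg, sh, w)
            # gamete of parent 2 -> haplotype 1
            _load_parent(genes, hots, i2, sg, sh)
            w = _gamete_from_copies(sg, sh, M, C, hotspot_mutation,
                                    gene_reversions, single_recomb, bootstrap,
                                    used, rng)
            _store_gamete(genes, hots, slot, 1, sg, sh, w)
            dd = 0
            for j in range(L):
                dd += genes[slot, 0, j] & genes[slot, 1, j]
            d[slot] = dd
            if not viable:
                break
            pv = x if neutral else x ** (dd + 1)
            if rng.random() < pv:
                break
    return nd


# ---------------------------------------------------------------------------
# public operations

def init_population(params: SimParams, rng: np.random.Generator) -> Population:
    """Founder population: all genes wild; each founder carries exactly one
    hotspot at a uniformly chosen intergenic site, on both haplotypes, so
    initial recombination positions are spread evenly across the population.
    """
    if not isinstance(params, SimParams):
        raise ConfigError("params must be a SimParams instance")
    pop = Population.empty(params.N, params.L)
    sites = rng.integers(0, params.L - 1, size=params.N)
    for i, s in enumerate(sites):
        pop.hotspots[i, :, s] = 1
    return pop


def homozygous_defect_count(ind: Individual) -> int:
    """Number of loci defective on both haplotypes (the ``d`` in x**(d+1))."""
    return int(np.count_nonzero(ind.hap1.genes & ind.hap2.genes))


def survival_probability(d: int, params: SimParams) -> float:
    """Per-step survival probability ``x**(d+1)``.

    In neutral mode survival is a flat ``x`` regardless of genotype, so the
    population keeps turning over without selection on defects.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if params.neutral_mode:
        return params.x
    return params.x ** (d + 1)


def selection(pop: Population, params: SimParams,
              rng: np.random.Generator) -> tuple[list[Individual], int]:
    """Independent viability selection over the whole population.

    Sweeps members in index order; each draws one uniform number and
    survives iff it falls below its survival probability.  Returns the
    surviving individuals and the death count.
    """
    d = pop.homozygous_defects()
    survivors = []
    for i in range(pop.N):
        p = params.x if params.neutral_mode else params.x ** (d[i] + 1)
        if rng.random() < p:
            survivors.append(pop[i])
    n_deaths = pop.N - len(survivors)
    if not survivors:
        raise ExtinctionError(pop.step)
    return survivors, n_deaths


def draw_event_count(mean: float, rng: np.random.Generator) -> int:
    """Number of events for one gamete: toss u ~ U(0, 2*mean); perform
    floor(u) events plus one more with probability frac(u).  The expected
    count equals ``mean`` and the support is {0, ..., ceil(2*mean)}."""
    if mean < 0:
        raise ValueError("mean must be >= 0")
    return int(_draw_event_count(rng, float(mean)))


def mutate_genes(hap: Haplotype, n_mut: int, params: SimParams,
                 rng: np.random.Generator) -> Haplotype:
    """Flip ``n_mut`` uniformly drawn gene bits (draws independent, so a
    site may be hit twice).  With ``gene_reversions`` off, a draw landing
    on a defective allele is suppressed (only 0 -> 1 applied)."""
    if n_mut < 0:
        raise ValueError("n_mut must be >= 0")
    out = hap.copy()
    _apply_mutations(out.genes, int(n_mut), params.gene_reversions, rng)
    return out


def allowed_positions(hapA: Haplotype, hapB: Haplotype,
                      params: SimParams) -> np.ndarray:
    """0-based intergenic sites where crossover may occur: both copies
    carry a hotspot (double hotspot), or either copy when
    ``single_hotspot_recomb`` is enabled."""
    if hapA.L != hapB.L:
        raise ValueError("haplotypes must share L")
    if params.single_hotspot_recomb:
        mask = hapA.hotspots | hapB.hotspots
    else:
        mask = hapA.hotspots & hapB.hotspots
    return np.nonzero(mask)[0]


def crossover(hapA: Haplotype, hapB: Haplotype,
              site: int) -> tuple[Haplotype, Haplotype]:
    """Reciprocal exchange at 0-based intergenic ``site`` (between loci
    ``site`` and ``site+1``).  Gene bits up to and including locus ``site``
    and hotspot bits up to and including ``site`` stay; the suffixes are
    swapped.  The per-locus multiset of bits is conserved across the pair.
    """
    L = hapA.L
    if hapA.L != hapB.L:
        raise ValueError("haplotypes must share L")
    if not (0 <= site <= L - 2):
        raise ValueError(f"crossover site must be in [0, {L - 2}], got {site}")
    gA = np.concatenate([hapA.genes[: site + 1], hapB.genes[site + 1:]])
    gB = np.concatenate([hapB.genes[: site + 1], hapA.genes[site + 1:]])
    hA = np.concatenate([hapA.hotspots[: site + 1], hapB.hotspots[site + 1:]])
    hB = np.concatenate([hapB.hotspots[: site + 1], hapA.hotspots[site + 1:]])
    return Haplotype(gA, hA), Haplotype(gB, hB)


def toggle_hotspot(hap: Haplotype, params: SimParams,
                   rng: np.random.Generator) -> Haplotype:
    """Invert the hotspot bit at one uniformly chosen intergenic site
    (creates a hotspot where there was none, removes an existing one).
    No-op when ``hotspot_mutation`` is off."""
    out = hap.copy()
    if params.hotspot_mutation:
        pos = int(rng.integers(0, hap.L - 1))
        out.hotspots[pos] ^= 1
    return out


def make_gamete(parent: Individual, params: SimParams,
                rng: np.random.Generator) -> Haplotype:
    """Form one gamete: copy both chromosomes, mutate each copy, apply the
    drawn number of crossovers at allowed sites (sampled without
    replacement within this gamete; a bootstrap hotspot is created when a
    crossover is demanded but no allowed site exists), return one product
    uniformly, with one hotspot toggle applied to it."""
    L = parent.L
    sg = np.empty((2, L), np.uint8)
    sh = np.empty((2, L - 1), np.uint8)
    sg[0] = parent.hap1.genes
    sg[1] = parent.hap2.genes
    sh[0] = parent.hap1.hotspots
    sh[1] = parent.hap2.hotspots
    used = np.zeros(L - 1, np.uint8)
    w = _gamete_from_copies(sg, sh, float(params.M), float(params.C),
                            params.hotspot_mutation, params.gene_reversions,
                            params.single_hotspot_recomb,
                            params.bootstrap_hotspots, used, rng)
    return Haplotype(sg[w].copy(), sh[w].copy())


def make_offspring(p1: Individual, p2: Individual, params: SimParams,
                   rng: np.random.Generator) -> Individual:
    """Fuse one gamete from each parent (hermaphroditic mating)."""
    return Individual(make_gamete(p1, params, rng), make_gamete(p2, params, rng))


def mc_step(pop: Population, params: SimParams,
            rng: np.random.Generator) -> tuple[Population, int]:
    """One Monte Carlo step in place: selection over all members, then each
    death replaced by a newborn from two distinct uniform survivors.
    Newborns first face selection at the next step.  Returns the (mutated)
    population and the number of deaths."""
    d = pop.homozygous_defects()
    N, L = pop.N, pop.L
    sg = np.empty((2, L), np.uint8)
    sh = np.empty((2, L - 1), np.uint8)
    used = np.zeros(L - 1, np.uint8)
    survivors = np.empty(N, np.int64)
    dead = np.empty(N, np.int64)
    nd = _mc_step_kernel(pop.genes, pop.hotspots, d, float(params.x),
                         float(params.M), float(params.C),
                         params.hotspot_mutation, params.gene_reversions,
                         params.single_hotspot_recomb, params.bootstrap_hotspots,
                         params.neutral_mode, params.viable_births,
                         rng, sg, sh, used, survivors, dead)
    if nd < 0:
        raise ExtinctionError(pop.step)
    pop.step += 1
    return pop, int(nd)


# ---------------------------------------------------------------------------
# trajectory loop

_TRAJ_COLUMNS = ("step", "n_deaths", "frac_defective_alleles",
                 "frac_homozygous_defective", "mean_hotspots_per_genome",
                 "mean_double", "mean_single", "mean_none")


def _summary_row(pop: Population, n_deaths: int) -> tuple:
    g0 = pop.genes[:, 0, :]
    g1 = pop.genes[:, 1, :]
    h0 = pop.hotspots[:, 0, :]
    h1 = pop.hotspots[:, 1, :]
    frac_def = float(pop.genes.mean())
    frac_hom = float((g0 & g1).mean())
    double = float((h0 & h1).sum(axis=1).mean())
    single = float((h0 ^ h1).sum(axis=1).mean())
    none = (pop.L - 1) - double - single
    return (pop.step, n_deaths, frac_def, frac_hom,
            2.0 * double + single, double, single, none)


@dataclass
class RunResult:
    """Outcome of :func:`run`: final population, thinned per-step summary
    trajectory, full-population snapshots, and a status flag
    (``"ok"`` or ``"extinct"``)."""

    population: Population
    trajectory: pd.DataFrame
    snapshots: dict[int, Population] = field(default_factory=dict)
    status: str = "ok"
    params: SimParams | None = None


def run(params: SimParams, options: RunOptions | None = None,
        init_pop: Population | None = None,
        rng: np.random.Generator | None = None) -> RunResult:
    """Run ``params.n_steps`` Monte Carlo steps.

    The trajectory records a summary row at step 0, every ``thinning``
    steps, and at the final step.  Full population snapshots are taken at
    each step listed in ``options.snapshot_steps``.  If
    ``options.variant_switch_step`` is set, the flags in
    ``options.switch_flags`` replace the corresponding :class:`SimParams`
    flags once the step counter reaches it (two-phase protocols).  Passing
    ``init_pop`` resumes from an existing population (its step counter is
    kept), which together with a fresh seed implements descendant branches.
    On extinction the partial trajectory is returned with
    ``status="extinct"``.
    """
    options = options or RunOptions()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if init_pop is None:
        pop = init_population(params, rng)
    else:
        pop = init_pop.copy()
    start_step = pop.step
    end_step = start_step + params.n_steps

    rows = [_summary_row(pop, 0)]
    snapshots: dict[int, Population] = {}
    want_snapshot = set(options.snapshot_steps)
    if start_step in want_snapshot:
        snapshots[start_step] = pop.copy()
    status = "ok"
    active = params
    switched = options.variant_switch_step is None

    # the long loop runs on the bit-packed engine: same algorithm and RNG
    # draw sequence as the byte kernels, ~5x faster; the per-individual
    # homozygous-defect cache d is kept current by the kernel
    N, L = pop.N, pop.L
    S = L - 1
    d = pop.homozygous_defects()
    Wg = (L + 63) // 64
    Wh = (S + 63) // 64
    gw = np.zeros((N, 2, Wg), np.uint64)
    hw = np.zeros((N, 2, Wh), np.uint64)
    _pack_bits(pop.genes, gw)
    _pack_bits(pop.hotspots, hw)
    sg = np.empty((2, Wg), np.uint64)
    sh = np.empty((2, Wh), np.uint64)
    allow = np.empty(Wh, np.uint64)
    surv_buf = np.empty(N, np.int64)
    dead_buf = np.empty(N, np.int64)

    def _unpack_population(step):
        genes = np.empty((N, 2, L), np.uint8)
        hots = np.empty((N, 2, S), np.uint8)
        _unpack_bits(gw, genes)
        _unpack_bits(hw, hots)
        return Population(genes, hots, step)

    def _row_packed(step, nd):
        tot, hom, dbl, sng = _packed_summary(gw, hw, S)
        frac_def = tot / (2.0 * N * L)
        return (step, nd, frac_def, hom / (N * L), (2.0 * dbl + sng) / N,
                dbl / N, sng / N, S - (dbl + sng) / N)

    step = pop.step
    while step < end_step:
        if not switched and step >= options.variant_switch_step:
            active = active.replace(**dict(options.switch_flags))
            switched = True
        nd = _mc_step_packed(gw, hw, d, L, S, float(active.x),
                             float(active.M), float(active.C),
                             active.hotspot_mutation, active.gene_reversions,
                             active.single_hotspot_recomb,
                             active.bootstrap_hotspots, active.neutral_mode,
                             active.viable_births,
                             rng, sg, sh, allow, surv_buf, dead_buf)
        if nd < 0:
            status = "extinct"
            break
        step += 1
        if (step - start_step) % options.thinning == 0 or step == end_step:
            rows.append(_row_packed(step, nd))
        if step in want_snapshot:
            snapshots[step] = _unpack_population(step)

    _unpack_bits(gw, pop.genes)
    _unpack_bits(hw, pop.hotspots)
    pop.step = step
    traj = pd.DataFrame(rows, columns=_TRAJ_COLUMNS)
    traj = traj.drop_duplicates(subset="step", keep="last").reset_index(drop=True)
    return RunResult(pop, traj, snapshots, status, params)
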