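import numpy as np
import pytest

from hotspotsim import Haplotype, Individual, Population, SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(20230611)


@pytest.fixture
def small_params():
    return SimParams(N=50, L=32, x=0.9, M=1.0, C=1.0, seed=7, n_steps=10)


def make_hap(genes: str, hotspots: str) -> Haplotype:
    return Haplotype(
        np.array([int(c) for c in genes], np.uint8),
        np.array([int(c) for c in hotspots], np.uint8),
    )


def make_ind(g1: str, h1: str, g2: str, h2: str) -> Individual:
    return Individual(make_hap(g1, h1), make_hap(g2, h2))


def pop_from_individuals(inds) -> Population:
    N = len(inds)
    L = inds[0].L
    genes = np.zeros((N, 2, L), np.uint8)
    hots = np.zeros((N, 2, L - 1), np.uint8)
    for i, ind in enumerate(inds):
        genes[i, 0] = ind.hap1.genes
        genes[i, 1] = ind.hap2.genes
        hots[i, 0] = ind.hap1.hotspots
        hots[i, 1] = ind.hap2.hotspots
    return Population(genes, hots)
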