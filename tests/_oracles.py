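"""Brute-force oracles, independent of the library's closed forms."""

import itertools

import numpy as np


def hwe_genotype_distribution(p):
    """Unordered genotype -> probability under Hardy-Weinberg."""
    dist = {}
    k = len(p)
    for i in range(k):
        for j in range(i, k):
            prob = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            dist[(i, j)] = prob
    return dist

def pi_enumeration(p):
    """P(two random HWE individuals share a genotype), by enumeration."""
    dist = hwe_genotype_distribution(p)
    return sum(prob**2 for prob in dist.values())


def pisibs_enumeration(p):
    """P(two full sibs share a genotype): enumerate parental genotype pairs
    and the Mendelian offspring distribution for each."""
    dist = hwe_genotype_distribution(p)
    total = 0.0
    for (g1, p1), (g2, p2) in itertools.product(dist.items(), repeat=2):
        child = {}
        for a in g1:
            for b in g2:
                g = tuple(sorted((a, b)))
                child[g] = child.get(g, 0.0) + 0.25
        total += p1 * p2 * sum(q**2 for q in child.values())
    return total


def random_frequency_vector(rng, max_alleles=6):
    k = rng.integers(1, max_alleles + 1)
    v = rng.dirichlet(np.ones(k))
    return v / v.sum()
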