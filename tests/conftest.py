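"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's computational kernels:
descent labels are traced by recursion over ancestry paths, likelihoods are
summed over all founder-allele assignments, and HMM quantities come from
explicit enumeration over complete inheritance-vector sequences.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pedimpute.descent import haldane
from pedimpute.pedio import (
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Marker,
    Pedigree,
)


# ---------------------------------------------------------------------------
# pedigree fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("F1", sex="male"),
            Individual("M1", sex="female"),
            Individual("C1", "F1", "M1"),
        ]
    )


@pytest.fixture
def quartet() -> Pedigree:
    return Pedigree(
        [
            Individual("F1", sex="male"),
            Individual("M1", sex="female"),
            Individual("C1", "F1", "M1"),
            Individual("C2", "F1", "M1"),
        ]
    )


def small_pedigree_battery() -> list[Pedigree]:
    """Pedigrees with m <= 6 meioses for exhaustive-oracle comparisons."""
    trio = [
        Individual("F1"),
        Individual("M1"),
        Individual("C1", "F1", "M1"),
    ]
    quartet = trio + [Individual("C2", "F1", "M1")]
    quintet = quartet + [Individual("C3", "F1", "M1")]
    three_gen = [
        Individual("F1"),
        Individual("M1"),
        Individual("M2"),
        Individual("C1", "F1", "M1"),
        Individual("G1", "C1", "M2"),
    ]
    half_sibs = [
        Individual("F1"),
        Individual("M1"),
        Individual("M2"),
        Individual("C1", "F1", "M1"),
        Individual("C2", "F1", "M2"),
        Individual("C3", "F1", "M2"),
    ]
    return [Pedigree(p) for p in (trio, quartet, quintet, three_gen, half_sibs)]


def random_genotypes(
    ped: Pedigree,
    markers: list[Marker],
    rng: np.random.Generator,
    missing_rate: float = 0.2,
) -> GenotypeMatrix:
    """Mendelian-consistent genotypes via a gene drop, then random masking."""
    from pedimpute.simdata import simulate_truth

    gmap = GeneticMap.constant_rate()
    truth = simulate_truth(ped, markers, gmap, seed=int(rng.integers(2**31 - 1)))
    g = truth.genotypes()
    mask = rng.random(g.geno.shape) < missing_rate
    g.geno[mask] = -1
    return g


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_labels(ped: Pedigree, iv: np.ndarray) -> np.ndarray:
    """Slot -> founder-gene labels by explicit recursion over ancestry."""
    founder_rank = {f: j for j, f in enumerate(ped.founders)}

    def trace(ind_id: str, slot: int) -> int:
        ind = ped.individuals[ped.index[ind_id]]
        if ind.is_founder:
            return 2 * founder_rank[ind_id] + slot
        parent = ind.sire if slot == 0 else ind.dam
        bit = int(iv[ped.meiosis_map[(ind_id, slot)]])
        return trace(parent, bit)

    out = np.empty(2 * ped.n, dtype=int)
    for i, ind in enumerate(ped.individuals):
        out[2 * i] = trace(ind.id, 0)
        out[2 * i + 1] = trace(ind.id, 1)
    return out


def oracle_locus_likelihood(
    ped: Pedigree, labels: np.ndarray, gt: dict[str, int], p: float
) -> float:
    """Sum over all 2^G founder-allele assignments of prior x consistency."""
    observed = {
        ped.index[i]: d for i, d in gt.items() if d is not None and d >= 0
    }
    touched = sorted(
        {int(labels[2 * i + s]) for i in observed for s in (0, 1)}
    )
    total = 0.0
    for vals in itertools.product((0, 1), repeat=len(touched)):
        assign = dict(zip(touched, vals))
        prior = 1.0
        for v in vals:
            prior *= p if v else 1.0 - p
        if all(
            assign[labels[2 * i]] + assign[labels[2 * i + 1]] == d
            for i, d in observed.items()
        ):
            total += prior
    return total


def oracle_iv_marginals(
    ped: Pedigree, geno: np.ndarray, markers: list[Marker], gmap: GeneticMap
) -> np.ndarray:
    """Per-locus IV marginals by enumeration over all IV sequences.

    ``geno`` is (n individuals, L markers) with -1 missing, in pedigree
    order.  Returns (L, 2^m) with state bit j = (state >> j) & 1.
    """
    m = ped.n_meioses
    S = 2**m
    L = len(markers)
    pos = np.array([gmap.bp_to_cm(mk.chrom, mk.pos_bp) for mk in markers])
    thetas = np.atleast_1d(haldane(np.diff(pos)))
    emis = np.empty((L, S))
    for s in range(S):
        iv = np.array([(s >> j) & 1 for j in range(m)], dtype=np.uint8)
        labels = oracle_labels(ped, iv)
        for t in range(L):
            gt = {pid: int(geno[i, t]) for i, pid in enumerate(ped.ids)}
            emis[t, s] = oracle_locus_likelihood(
                ped, labels, gt, markers[t].alt_freq
            )
    ham = np.array([[bin(a ^ b).count("1") for b in range(S)] for a in range(S)])

    def shaped(arr: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
        shape = [1] * L
        for ax, size in zip(axes, arr.shape):
            shape[ax] = size
        return arr.reshape(
            tuple(arr.shape[axes.index(a)] if a in axes else 1 for a in range(L))
        )

    full = shaped(emis[0] / S, (0,))
    for t in range(1, L):
        th = thetas[t - 1]
        T = th**ham * (1 - th) ** (m - ham)
        idx = [1] * L
        idx[t - 1] = S
        idx[t] = S
        full = full * T.reshape(tuple(idx)) * shaped(emis[t], (t,))
    Z = full.sum()
    marg = np.empty((L, S))
    for t in range(L):
        axes = tuple(a for a in range(L) if a != t)
        marg[t] = full.sum(axis=axes) / Z
    return marg
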