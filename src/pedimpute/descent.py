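"""Inheritance-vector inference over framework markers.

An inheritance vector (IV) carries one bit per meiosis at a locus: 0 when the
parent transmitted its paternally inherited allele, 1 for the maternal one.
Conditional on an IV, every allele slot in the pedigree maps to a founder
gene (the descent partition), which makes the single-locus likelihood a sum
over founder-allele assignments.  Along a chromosome the IVs form a hidden
Markov chain whose transitions factor per meiosis with Haldane recombination
fractions.  Small pedigrees are handled exactly by forward-backward over the
2^m state space; larger ones by a meiosis-wise Gibbs ("L") sampler in which
each meiosis' entire bit path is resampled from its conditional 2-state HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .pedio import GeneticMap, GenotypeMatrix, Pedigree

__all__ = [
    "haldane",
    "build_descent",
    "DescentPartition",
    "locus_likelihood",
    "transition_prob",
    "exact_iv_posterior",
    "sample_iv_mcmc",
    "IVSampleSet",
    "MendelianInconsistencyError",
]


class MendelianInconsistencyError(ValueError):
    """Observed framework genotypes are impossible under the pedigree."""


def haldane(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a genetic distance in centimorgans.

    theta = (1 - exp(-2 d)) / 2 with d in Morgans; no crossover interference.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(d_cm) else theta


@dataclass
class DescentPartition:
    """Slot -> founder-gene labels implied by a pedigree and one IV."""

    pedigree: Pedigree
    labels: np.ndarray  # (2n,) founder-gene index per slot

    def founder_gene(self, ind_id: str, slot: int) -> tuple[str, int]:
        """(founder id, copy) carried by ``slot`` (0 paternal / 1 maternal)."""
        g = int(self.labels[2 * self.pedigree.index[ind_id] + slot])
        return self.pedigree.founders[g // 2], g % 2


def build_descent(ped: Pedigree, iv: np.ndarray) -> DescentPartition:
    iv = np.asarray(iv, dtype=np.uint8)
    if iv.shape != (ped.n_meioses,):
        raise ValueError(
            f"IV length {iv.shape} does not match {ped.n_meioses} meioses"
        )
    labels = np.empty(2 * ped.n, np.int32)
    _kernels.labels_for_bits(
        iv, ped.parent_of_slot, ped.meiosis_of_slot, ped.gene_of_slot, labels
    )
    return DescentPartition(ped, labels)


def locus_likelihood(
    part: DescentPartition, obs: dict[str, int], p: float
) -> float:
    """P(observed dosages at one marker | descent partition, alt freq p).

    Sums over all founder-allele assignments consistent with the non-missing
    observations; genes untouched by any observation contribute factor 1.
    """
    ped = part.pedigree
    gt = np.full(ped.n, -1, np.int8)
    for ind_id, dose in obs.items():
        if dose is not None and dose >= 0:
            gt[ped.index[ind_id]] = dose
    ng = ped.n_genes
    uf = np.empty(ng, np.int32)
    par = np.empty(ng, np.uint8)
    w0 = np.empty(ng, np.float64)
    w1 = np.empty(ng, np.float64)
    return float(_kernels.solve_site(part.labels, gt, float(p), uf, par, w0, w1))


def transition_prob(iv_a: np.ndarray, iv_b: np.ndarray, theta: float) -> float:
    """theta^k (1-theta)^(m-k) for k differing meiosis bits."""
    a = np.asarray(iv_a)
    b = np.asarray(iv_b)
    if a.shape != b.shape:
        raise ValueError("IV length mismatch")
    k = int(np.sum(a != b))
    m = a.shape[0]
    return float(theta**k * (1.0 - theta) ** (m - k))


@dataclass
class IVSampleSet:
    """Realizations of the IV process across framework markers.

    ``bits`` has shape (n_samples, n_meioses, n_markers).  For the exact
    sampler, per-locus marginals over all 2^m states are attached.
    """

    bits: np.ndarray
    method: str  # "exact" | "mcmc"
    seed: int
    chrom: str
    positions_cm: np.ndarray
    marginals: np.ndarray | None = None  # (n_markers, 2^m)
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.bits.shape[0]

    @property
    def n_meioses(self) -> int:
        return self.bits.shape[1]

    @property
    def n_markers(self) -> int:
        return self.bits.shape[2]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# method=%s seed=%d chrom=%s\n" % (self.method, self.seed, self.chrom))
            fh.write("sample\tmarker\tbits\n")
            for s in range(self.n_samples):
                for t in range(self.n_markers):
                    bstr = "".join(str(int(b)) for b in self.bits[s, :, t])
                    fh.write(f"{s}\t{t}\t{bstr}\n")


def _framework_arrays(
    ped: Pedigree, framework: GenotypeMatrix, gmap: GeneticMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray, str, np.ndarray]:
    chroms = {m.chrom for m in framework.markers}
    if len(chroms) != 1:
        raise ValueError(
            "IV inference runs per chromosome; split the framework matrix "
            f"(got chromosomes {sorted(chroms)})"
        )
    chrom = chroms.pop()
    order = [framework.ids.index(i) for i in ped.ids]
    obs_t = np.ascontiguousarray(framework.geno[order].T)  # (L, n)
    p = np.array([m.alt_freq for m in framework.markers])
    pos_cm = np.asarray(
        gmap.bp_to_cm(chrom, np.array([m.pos_bp for m in framework.markers]))
    , dtype=float)
    theta = haldane(np.diff(pos_cm))
    return obs_t, p, np.atleast_1d(theta), chrom, pos_cm


def _bits_table(m: int) -> np.ndarray:
    s = np.arange(2**m, dtype=np.int64)
    return ((s[:, None] >> np.arange(m)) & 1).astype(np.uint8)


def _apply_transition(v: np.ndarray, theta: float, m: int) -> np.ndarray:
    """Multiply by the m-fold Kronecker transition matrix in O(m 2^m)."""
    w = v.reshape((2,) * m)
    for ax in range(m):
        a = np.take(w, 0, axis=ax)
        b = np.take(w, 1, axis=ax)
        w = np.stack(
            ((1 - theta) * a + theta * b, theta * a + (1 - theta) * b), axis=ax
        )
    return w.reshape(-1)


def exact_iv_posterior(
    ped: Pedigree,
    framework: GenotypeMatrix,
    gmap: GeneticMap,
    seed: int = 0,
    n_samples: int = 1000,
    m_max: int = 16,
) -> IVSampleSet:
    """Exact forward-backward over all 2^m IVs; i.i.d. joint samples.

    Raises :class:`MendelianInconsistencyError` if any locus has zero
    likelihood under every IV, and ``ValueError`` when m exceeds ``m_max``.
    """
    m = ped.n_meioses
    if m > m_max:
        raise ValueError(f"m={m} exceeds m_max={m_max}; use sample_iv_mcmc")
    obs_t, p, theta, chrom, pos_cm = _framework_arrays(ped, framework, gmap)
    L = obs_t.shape[0]
    if L < 1:
        raise ValueError("need at least one framework marker")
    S = 2**m
    table = _bits_table(m)
    E = _kernels.emissions_for_states(
        table, obs_t, p, ped.parent_of_slot, ped.meiosis_of_slot,
        ped.gene_of_slot, ped.n_genes,
    )
    if np.any(E.sum(axis=1) == 0):
        bad = int(np.flatnonzero(E.sum(axis=1) == 0)[0])
        raise MendelianInconsistencyError(
            f"framework marker {bad} is impossible under every IV"
        )

    fwd = np.empty((L, S))
    v = E[0] / S
    fwd[0] = v / v.sum()
    for t in range(1, L):
        v = E[t] * _apply_transition(fwd[t - 1], theta[t - 1], m)
        fwd[t] = v / v.sum()
    bwd = np.empty((L, S))
    v = np.ones(S)
    bwd[L - 1] = v
    for t in range(L - 2, -1, -1):
        v = _apply_transition(E[t + 1] * bwd[t + 1], theta[t], m)
        bwd[t] = v / v.sum()
    marg = fwd * bwd
    marg /= marg.sum(axis=1, keepdims=True)

    # joint samples by backward sampling
    rng = np.random.default_rng(seed)
    popcnt = np.array([bin(x).count("1") for x in range(S)])
    states = np.empty((n_samples, L), np.int64)
    states[:, L - 1] = rng.choice(S, size=n_samples, p=fwd[L - 1])
    for t in range(L - 2, -1, -1):
        th = theta[t]
        for i in range(n_samples):
            nxt = states[i, t + 1]
            h = popcnt[np.arange(S) ^ nxt]
            w = fwd[t] * th**h * (1 - th) ** (m - h)
            states[i, t] = rng.choice(S, p=w / w.sum())
    bits = np.ascontiguousarray(
        np.transpose(table[states], (0, 2, 1))
    )  # (n_samples, m, L)
    return IVSampleSet(
        bits=bits.astype(np.uint8),
        method="exact",
        seed=seed,
        chrom=chrom,
        positions_cm=pos_cm,
        marginals=marg,
        meta={"n_samples": n_samples},
    )


# ---------------------------------------------------------------------------
# MCMC (meiosis-wise Gibbs / L-sampler)
# ---------------------------------------------------------------------------

def _consistency_deficit(
    labels: np.ndarray, gt: np.ndarray, p: float, ng: int
) -> int:
    """Number of observed individuals that must be dropped for consistency.

    Greedy scorer used only to construct a starting configuration: processes
    individuals in order, skipping (and counting) any whose constraint
    contradicts those already absorbed.
    """
    uf = np.empty(ng, np.int32)
    par = np.empty(ng, np.uint8)
    w0 = np.empty(ng, np.float64)
    w1 = np.empty(ng, np.float64)
    tmp = np.full(gt.shape[0], -1, np.int8)
    deficit = 0
    for i in range(gt.shape[0]):
        if gt[i] < 0:
            continue
        tmp[i] = gt[i]
        # re-solve the growing prefix; drop the newcomer on contradiction
        if _kernels.solve_site(labels, tmp, p, uf, par, w0, w1) == 0.0:
            tmp[i] = -1
            deficit += 1
    return deficit


def _initial_bits(
    ped: Pedigree,
    obs_t: np.ndarray,
    p: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
    max_repair: int = 4_000,
) -> np.ndarray:
    """Locus-wise search for a Mendelian-consistent starting configuration.

    Random IVs are rejection-sampled per locus; if none is consistent within
    the attempt budget, a greedy bit-flip repair minimises the number of
    irreconcilable observations before giving up.
    """
    m = ped.n_meioses
    L = obs_t.shape[0]
    ng = ped.n_genes
    bits = np.zeros((m, L), np.uint8)
    labels = np.empty(2 * ped.n, np.int32)
    uf = np.empty(ng, np.int32)
    par = np.empty(ng, np.uint8)
    w0 = np.empty(ng, np.float64)
    w1 = np.empty(ng, np.float64)

    def consistent(iv, t):
        _kernels.labels_for_bits(iv, ped.parent_of_slot, ped.meiosis_of_slot,
                                 ped.gene_of_slot, labels)
        return _kernels.solve_site(labels, obs_t[t], p[t], uf, par, w0, w1) > 0

    for t in range(L):
        iv = bits[:, t - 1].copy() if t > 0 else rng.integers(0, 2, m).astype(np.uint8)
        if consistent(iv, t):
            bits[:, t] = iv
            continue
        found = False
        for _ in range(max_attempts):
            iv = rng.integers(0, 2, m).astype(np.uint8)
            if consistent(iv, t):
                found = True
                break
        if not found:
            # greedy repair from the best random candidate
            _kernels.labels_for_bits(iv, ped.parent_of_slot,
                                     ped.meiosis_of_slot, ped.gene_of_slot,
                                     labels)
            score = _consistency_deficit(labels, obs_t[t], p[t], ng)
            for _ in range(max_repair):
                j = rng.integers(m)
                iv[j] ^= 1
                _kernels.labels_for_bits(iv, ped.parent_of_slot,
                                         ped.meiosis_of_slot,
                                         ped.gene_of_slot, labels)
                new = _consistency_deficit(labels, obs_t[t], p[t], ng)
                if new <= score:
                    score = new
                    if score == 0 and consistent(iv, t):
                        found = True
                        break
                else:
                    iv[j] ^= 1
            if not found:
                raise MendelianInconsistencyError(
                    f"no Mendelian-consistent IV found for framework marker {t}"
                )
        bits[:, t] = iv
    return bits


def sample_iv_mcmc(
    ped: Pedigree,
    framework: GenotypeMatrix,
    gmap: GeneticMap,
    n_samples: int = 1000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    m_locus_gibbs: int = 8,
) -> IVSampleSet:
    """Gibbs sampling of IV paths over framework markers.

    Each sweep combines a meiosis-wise pass (each meiosis' whole bit path
    resampled from its conditional 2-state HMM) with random meiosis-pair
    path updates, which cross the reducibility barriers single-meiosis moves
    cannot (e.g. opposite-homozygote siblings).  For pedigrees with at most
    ``m_locus_gibbs`` meioses an exact locus-wise joint update over all 2^m
    states is interleaved as well, making the sampler irreducible outright.
    """
    obs_t, p, theta, chrom, pos_cm = _framework_arrays(ped, framework, gmap)
    rng = np.random.default_rng(seed)
    bits = _initial_bits(ped, obs_t, p, rng)
    _kernels.seed_rng(int(rng.integers(2**31 - 1)))
    m = ped.n_meioses
    use_locus = m <= m_locus_gibbs
    bits_table = _bits_table(m if use_locus else 1)
    popcnt = np.array(
        [bin(x).count("1") for x in range(bits_table.shape[0])], np.int64
    )
    n_pairs = max(1, m // 2)
    # meioses transmitting from each founder, for phase-flip moves
    groups = []
    for fid in ped.founders:
        fidx = ped.index[fid]
        rows = [
            me for (cid, origin), me in ped.meiosis_map.items()
            if ped.index[
                ped.individuals[ped.index[cid]].sire if origin == 0
                else ped.individuals[ped.index[cid]].dam
            ] == fidx
        ]
        if rows:
            groups.append(np.array(sorted(rows), np.int64))
    flip_offsets = np.cumsum([0] + [len(g) for g in groups]).astype(np.int64)
    flip_flat = (
        np.concatenate(groups).astype(np.int64) if groups
        else np.zeros(0, np.int64)
    )
    args = (
        obs_t, p, theta, ped.parent_of_slot, ped.meiosis_of_slot,
        ped.gene_of_slot, ped.n_genes,
    )
    _kernels.run_sweeps(bits, *args, burn_in, bits_table, popcnt,
                        use_locus, n_pairs, flip_flat, flip_offsets)
    out = np.empty((n_samples, ped.n_meioses, obs_t.shape[0]), np.uint8)
    _kernels.collect_samples(bits, *args, n_samples, thin, bits_table, popcnt,
                             use_locus, n_pairs, flip_flat, flip_offsets, out)
    return IVSampleSet(
        bits=out,
        method="mcmc",
        seed=seed,
        chrom=chrom,
        positions_cm=pos_cm,
        meta={"burn_in": burn_in, "thin": thin, "n_samples": n_samples},
    )
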