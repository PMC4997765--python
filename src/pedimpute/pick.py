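"""Selection of pedigree members for whole-genome sequencing.

The coverage metric is the expected fraction of allele copies in the
pedigree that are identical by descent with an allele copy carried by the
selected set, at a single unlinked locus ("genome-wide" mode: only the
pedigree structure enters).  A slot counts as covered when its founder-gene
label appears among the selected individuals' slots; this descent-based
criterion approximates the full coverage statistic, which additionally
integrates over genotype configurations.  Greedy maximization of the metric
reproduces the iterative ranking strategy; two common heuristics (founders
only, most recent generation) are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedio import Pedigree


@dataclass(frozen=True)
class CoverageEstimate:
    selected: tuple[str, ...]
    coverage: float
    se: float
    n_draws: int
    exact: bool


@dataclass(frozen=True)
class SelectionRanking:
    """Greedy ranking with marginal coverage gains (order is deterministic)."""

    ids: tuple[str, ...]
    gains: tuple[float, ...]
    cumulative: tuple[float, ...]


def _drop_labels(ped: Pedigree, bits: np.ndarray) -> np.ndarray:
    """Founder-gene labels (draws x 2n slots) for a batch of IV draws."""
    D = bits.shape[0]
    labels = np.empty((D, 2 * ped.n), np.int32)
    for s in range(2 * ped.n):
        g = ped.gene_of_slot[s]
        if g >= 0:
            labels[:, s] = g
        else:
            pa = ped.parent_of_slot[s]
            b = bits[:, ped.meiosis_of_slot[s]]
            labels[:, s] = np.where(b == 0, labels[:, 2 * pa], labels[:, 2 * pa + 1])
    return labels


def _coverage_draws(ped: Pedigree, n_draws: int, seed: int,
                    m_max_exact: int = 16) -> tuple[np.ndarray, bool]:
    m = ped.n_meioses
    if m <= m_max_exact and 2**m <= n_draws * 4:
        S = 2**m
        bits = ((np.arange(S)[:, None] >> np.arange(m)) & 1).astype(np.uint8)
        return _drop_labels(ped, bits), True
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n_draws, m), dtype=np.uint8)
    return _drop_labels(ped, bits), False


def _called_fraction_genotype(
    ped: Pedigree,
    labels: np.ndarray,
    alleles: np.ndarray,
    selected: list[str],
) -> np.ndarray:
    """Per-draw fraction of allele copies *determined* by donor genotypes.

    Refines the descent criterion by integrating over genotype
    configurations: a founder gene only counts as called when the selected
    individuals' unordered genotypes pin its allele down exactly —
    homozygous donors force both their genes, and a heterozygous donor
    resolves one gene only once the other is forced.  Deep, unphasable
    donor sets therefore score lower than under pure descent coverage.
    """
    D = labels.shape[0]
    forced = np.zeros_like(alleles, dtype=bool)  # (D, n_genes)
    sel_idx = [ped.index[i] for i in selected]
    rows = np.arange(D)
    geno = {}
    for i in sel_idx:
        a = labels[:, 2 * i]
        b = labels[:, 2 * i + 1]
        geno[i] = (alleles[rows, a] + alleles[rows, b], a, b)
    for _ in range(max(1, 2 * len(sel_idx))):
        changed = False
        for i in sel_idx:
            g, a, b = geno[i]
            hom = g != 1
            before = forced[rows, a].sum() + forced[rows, b].sum()
            forced[rows[hom], a[hom]] = True
            forced[rows[hom], b[hom]] = True
            het = ~hom
            fa = forced[rows, a]
            fb = forced[rows, b]
            forced[rows[het & fa], b[het & fa]] = True
            forced[rows[het & fb], a[het & fb]] = True
            after = forced[rows, a].sum() + forced[rows, b].sum()
            changed = changed or (after != before)
        if not changed:
            break
    covered = forced[rows[:, None], labels]
    return covered.mean(axis=1)


def _coverage_from_labels(
    ped: Pedigree,
    labels: np.ndarray,
    selected: list[str],
    include_selected: bool = True,
) -> tuple[float, float]:
    D = labels.shape[0]
    sel_slots = np.concatenate(
        [[2 * ped.index[i], 2 * ped.index[i] + 1] for i in selected]
    ).astype(int) if selected else np.array([], int)
    present = np.zeros((D, ped.n_genes), bool)
    if len(sel_slots):
        rows = np.repeat(np.arange(D), len(sel_slots))
        present[rows, labels[:, sel_slots].ravel()] = True
    if include_selected:
        eval_slots = np.arange(2 * ped.n)
    else:
        keep = np.setdiff1d(np.arange(2 * ped.n), sel_slots)
        eval_slots = keep
    if len(eval_slots) == 0:
        return 1.0, 0.0
    covered = present[np.arange(D)[:, None], labels[:, eval_slots]]
    per_draw = covered.mean(axis=1)
    return float(per_draw.mean()), float(per_draw.std(ddof=1) / np.sqrt(D)) if D > 1 else 0.0


def _allele_draws(
    n_draws: int, n_genes: int, seed: int
) -> np.ndarray:
    """Founder-gene alleles for a random locus, frequency integrated out.

    Each draw takes an alt frequency uniform on (0.05, 0.95) and samples the
    founder genes independently at that frequency.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=(n_draws, 1))
    return (rng.random((n_draws, n_genes)) < p).astype(np.int8)


def expected_coverage(
    ped: Pedigree,
    selected: list[str],
    n_draws: int = 100_000,
    seed: int = 0,
    include_selected: bool = True,
    m_max_exact: int = 16,
    metric: str = "descent",
) -> CoverageEstimate:
    """Expected fraction of allele copies covered by the selected set.

    The default ``descent`` metric counts a slot as covered when its founder
    gene is carried by a selected individual (conditional on the inheritance
    vector, that allele copy is shared identically by descent with a donor).
    ``metric="genotype"`` additionally requires the allele to be determined
    by the donors' unordered genotypes (see
    :func:`_called_fraction_genotype`).  Exact enumeration over all 2^m
    inheritance vectors is used when the pedigree is small enough; otherwise
    Monte-Carlo gene drops.
    """
    if ped.n == 0:
        raise ValueError("empty pedigree")
    unknown = set(selected) - set(ped.ids)
    if unknown:
        raise KeyError(f"selected ids not in pedigree: {sorted(unknown)}")
    if metric == "descent":
        labels, exact = _coverage_draws(ped, n_draws, seed, m_max_exact)
        cov, se = _coverage_from_labels(ped, labels, list(selected), include_selected)
        return CoverageEstimate(
            tuple(selected), cov, 0.0 if exact else se, labels.shape[0], exact
        )
    if metric != "genotype":
        raise ValueError(f"unknown coverage metric {metric!r}")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n_draws, ped.n_meioses), dtype=np.uint8)
    labels = _drop_labels(ped, bits)
    alleles = _allele_draws(n_draws, ped.n_genes, seed + 1)
    per_draw = _called_fraction_genotype(ped, labels, alleles, list(selected))
    return CoverageEstimate(
        tuple(selected),
        float(per_draw.mean()),
        float(per_draw.std(ddof=1) / np.sqrt(n_draws)),
        n_draws,
        False,
    )


def gigi_pick_rank(
    ped: Pedigree,
    k: int,
    n_draws: int = 50_000,
    seed: int = 0,
    candidates: list[str] | None = None,
    m_max_exact: int = 16,
    metric: str = "genotype",
) -> SelectionRanking:
    """Greedy coverage-maximizing ranking of individuals for sequencing.

    At each step the candidate whose addition maximizes expected coverage of
    the augmented set joins the ranking; ties break by id.  Ranking uses the
    genotype-aware coverage metric by default — it is what the called
    fraction downstream actually tracks — with ``metric="descent"``
    available for the pure identity-by-descent criterion.  All evaluations
    share one set of gene-drop draws (common random numbers), so the greedy
    order is deterministic given the seed and monotone in the selected set.
    """
    pool = list(candidates) if candidates is not None else list(ped.ids)
    if not (1 <= k <= len(pool)):
        raise ValueError(f"k={k} out of range for {len(pool)} candidates")
    if metric == "genotype":
        rng = np.random.default_rng(seed)
        bits = rng.integers(0, 2, size=(n_draws, ped.n_meioses), dtype=np.uint8)
        labels = _drop_labels(ped, bits)
        alleles = _allele_draws(n_draws, ped.n_genes, seed + 1)

        def coverage(sel: list[str]) -> float:
            return float(_called_fraction_genotype(ped, labels, alleles, sel).mean())

    elif metric == "descent":
        labels, _ = _coverage_draws(ped, n_draws, seed, m_max_exact)

        def coverage(sel: list[str]) -> float:
            return _coverage_from_labels(ped, labels, sel)[0]

    else:
        raise ValueError(f"unknown coverage metric {metric!r}")
    chosen: list[str] = []
    gains: list[float] = []
    cums: list[float] = []
    current = 0.0
    for _ in range(k):
        best_id, best_cov = None, -1.0
        for cand in sorted(set(pool) - set(chosen)):
            cov = coverage(chosen + [cand])
            if cov > best_cov + 1e-12:
                best_id, best_cov = cand, cov
        chosen.append(best_id)
        gains.append(best_cov - current)
        cums.append(best_cov)
        current = best_cov
    return SelectionRanking(tuple(chosen), tuple(gains), tuple(cums))


def heuristic_bottom(
    ped: Pedigree, k: int, candidates: list[str] | None = None
) -> list[str]:
    """The k most-recent-generation (childless) members.

    Ranked by number of in-pedigree ancestors (descending; deeper placement
    means more of the pedigree is phased through them), ties by id.  When a
    candidate subset is given (e.g. the animals for which sequencing is on
    the table), only those are considered.
    """
    pool = candidates if candidates is not None else ped.ids
    childless = [i for i in pool if not ped.children_of(i)]
    if len(childless) < k:
        raise ValueError(f"only {len(childless)} childless individuals; k={k}")

    def n_ancestors(ind_id: str) -> int:
        seen: set[str] = set()
        stack = [ind_id]
        while stack:
            ind = ped.individuals[ped.index[stack.pop()]]
            for par in (ind.sire, ind.dam):
                if par is not None and par not in seen:
                    seen.add(par)
                    stack.append(par)
        return len(seen)

    ranked = sorted(childless, key=lambda i: (-n_ancestors(i), i))
    return ranked[:k]


def heuristic_founders(
    ped: Pedigree, k: int, candidates: list[str] | None = None
) -> list[str]:
    """The k founders with the most descendants (ties by id).

    A candidate subset restricts the founders considered.
    """
    pool = candidates if candidates is not None else ped.ids
    founders = [i for i in ped.founders if i in set(pool)]
    if len(founders) < k:
        raise ValueError(f"only {len(founders)} eligible founders; k={k}")
    ranked = sorted(founders, key=lambda i: (-len(ped.descendants_of(i)), i))
    return ranked[:k]
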