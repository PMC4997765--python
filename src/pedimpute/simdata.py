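"""Synthetic data generation: pedigrees, gene dropping, sequencing noise, GBS.

The generator emulates the study design the package targets: a small,
two-generation breeding-colony pedigree genotyped everywhere by sparse GBS,
with a few members whole-genome sequenced.  Founder haplotypes are drawn
from stated allele frequencies in linkage equilibrium, transmission follows
a Markov crossover process over adjacent markers with Haldane recombination
fractions (no interference, matching the inference model), read depth is
Poisson with a per-read miscall rate, and genotypes are called by a flat-
prior binomial classifier with the standard DP >= 10 / GQ >= 20 hard filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .descent import haldane
from .digest import Enzyme, revcomp_motif, _motif_regex
from .pedio import GeneticMap, GenotypeMatrix, Individual, Marker, Pedigree


# ---------------------------------------------------------------------------
# Pedigree templates
# ---------------------------------------------------------------------------

#: (id, sire, dam, sex) rows of the 16-member two-generation colony pedigree.
#: One consistent instantiation of a breeding-colony family: 6 founders
#: (A, B, C, D, E plus dam O), harem-style matings (no full siblings), and
#: all of the colony's common relationship classes: parent/offspring,
#: half-sibling, half-avuncular, half-cousin and grandparent/grandchild.
#: K is a child of D; M, P and K have no offspring; founder E is related
#: only to G and N, neither of which carries whole-genome data in the
#: scenarios shipped with the package.
_FIG1_ROWS = [
    ("A", None, None, "female"),
    ("B", None, None, "male"),
    ("C", None, None, "female"),
    ("D", None, None, "male"),
    ("E", None, None, "male"),
    ("O", None, None, "female"),
    ("F", "B", "A", "male"),
    ("G", "E", "A", "female"),
    ("H", "B", "C", "male"),
    ("I", "H", "O", "female"),
    ("J", "B", "O", "male"),
    ("K", "D", "A", "male"),
    ("L", "H", "G", "female"),
    ("M", "F", "O", "male"),
    ("N", "J", "G", "female"),
    ("P", "J", "A", "male"),
]

#: The nine members carrying whole-genome sequence in the shipped scenarios.
WGS_IDS = ["B", "H", "J", "F", "M", "K", "P", "C", "D"]


def fig1_like_pedigree() -> Pedigree:
    """The fixed 16-member (ids A..P) two-generation colony pedigree."""
    return Pedigree(
        Individual(i, s, d, sex) for i, s, d, sex in _FIG1_ROWS
    )


def trio_pedigree() -> Pedigree:
    return Pedigree(
        [
            Individual("F1", sex="male"),
            Individual("M1", sex="female"),
            Individual("C1", "F1", "M1"),
        ]
    )


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def make_markers(
    n: int,
    spacing_bp: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
    start_bp: int = 50_000,
    maf_min: float = 0.25,
    freq: str = "uniform_maf",
    jitter_bp: int = 0,
) -> list[Marker]:
    """Evenly spaced biallelic markers with sampled alt frequencies.

    ``freq`` chooses the frequency model: ``uniform_maf`` draws alt
    frequencies uniformly on [maf_min, 1 - maf_min] (framework-marker-like);
    ``sfs`` draws a neutral-spectrum-like minor-allele frequency
    (density ~ 1/x on [0.02, 0.5]) with a random minor allele, emulating
    variant sites discovered by whole-genome sequencing.
    """
    pos = start_bp + spacing_bp * np.arange(n)
    if jitter_bp:
        pos = pos + rng.integers(-jitter_bp, jitter_bp + 1, size=n)
        pos = np.sort(pos)
    if freq == "uniform_maf":
        af = rng.uniform(maf_min, 1.0 - maf_min, size=n)
    elif freq == "sfs":
        lo = 1.0 / 30.0  # singleton frequency in a 30-chromosome reference
        minor = lo * (0.5 / lo) ** rng.uniform(0.0, 1.0, size=n)
        flip = rng.random(n) < 0.5
        af = np.where(flip, minor, 1.0 - minor)
    else:
        raise ValueError(f"unknown frequency model {freq!r}")
    bases = np.array(list("ACGT"))
    out = []
    for k in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        out.append(
            Marker(chrom, int(pos[k]), bases[ref], bases[alt], float(af[k]))
        )
    return out


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

@dataclass
class TruthPanel:
    """Phased ground truth from a gene-dropping simulation.

    ``slot_alleles``/``slot_labels`` have shape (2n, L): per-slot alt dosage
    (0/1) and founder-gene label; ``iv_bits`` (m, L) are the true meiosis
    indicators.  The unphased dosage matrix derives as the slot sum.
    """

    pedigree: Pedigree
    markers: list[Marker]
    slot_alleles: np.ndarray
    slot_labels: np.ndarray
    iv_bits: np.ndarray

    def genotypes(self) -> GenotypeMatrix:
        geno = (
            self.slot_alleles[0::2, :] + self.slot_alleles[1::2, :]
        ).astype(np.int8)
        return GenotypeMatrix(self.pedigree.ids, self.markers, geno)


def simulate_truth(
    ped: Pedigree,
    markers: list[Marker],
    gmap: GeneticMap,
    seed: int = 0,
) -> TruthPanel:
    """Drop founder genes down the pedigree with map-based recombination."""
    rng = np.random.default_rng(seed)
    L = len(markers)
    chroms = {m.chrom for m in markers}
    if len(chroms) != 1:
        raise ValueError("simulate_truth operates on one chromosome at a time")
    chrom = chroms.pop()
    pos_cm = np.asarray(
        gmap.bp_to_cm(chrom, np.array([m.pos_bp for m in markers])), dtype=float
    )
    theta = np.atleast_1d(haldane(np.diff(pos_cm)))
    p = np.array([m.alt_freq for m in markers])

    m_meio = ped.n_meioses
    bits = np.empty((m_meio, L), np.uint8)
    bits[:, 0] = rng.integers(0, 2, m_meio)
    flips = rng.random((m_meio, L - 1)) < theta[None, :]
    bits[:, 1:] = (bits[:, :1] + np.cumsum(flips, axis=1)) % 2

    gene_alleles = (
        rng.random((ped.n_genes, L)) < p[None, :]
    ).astype(np.int8)

    n2 = 2 * ped.n
    labels = np.empty((n2, L), np.int32)
    for s in range(n2):
        g = ped.gene_of_slot[s]
        if g >= 0:
            labels[s] = g
        else:
            pa = ped.parent_of_slot[s]
            b = bits[ped.meiosis_of_slot[s]]
            labels[s] = np.where(b == 0, labels[2 * pa], labels[2 * pa + 1])
    alleles = gene_alleles[labels, np.arange(L)[None, :]]
    return TruthPanel(ped, list(markers), alleles.astype(np.int8), labels, bits)


# ---------------------------------------------------------------------------
# Sequencing observation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageModel:
    """Poisson depth + per-read miscall observation model with hard filters."""

    mean_depth: float = 30.0
    error_rate: float = 0.01
    min_dp: int = 10
    min_gq: int = 20

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")


MAX_GQ = 99


def simulate_observation(
    truth: TruthPanel, model: CoverageModel, seed: int = 0
) -> GenotypeMatrix:
    """Observe the truth through Poisson depth and a flat-prior caller.

    Per cell: depth ~ Poisson(mean_depth); alt reads ~ Binomial(depth, mu)
    with mu = error_rate, 0.5, 1 - error_rate for 0/1/2 true alt copies; the
    call is the flat-prior argmax of the three binomial likelihoods and
    GQ = round(-10 log10(1 - posterior)); cells failing DP/GQ are missing.
    """
    rng = np.random.default_rng(seed)
    g_true = truth.genotypes().geno
    n, L = g_true.shape
    depth = rng.poisson(model.mean_depth, size=(n, L))
    mu = np.array([model.error_rate, 0.5, 1.0 - model.error_rate])
    alt_reads = rng.binomial(depth, mu[g_true])

    logp = np.stack(
        [stats.binom.logpmf(alt_reads, depth, m) for m in mu], axis=-1
    )
    call = np.argmax(logp, axis=-1).astype(np.int8)
    lse = np.logaddexp.reduce(logp, axis=-1)
    post = np.exp(np.max(logp, axis=-1) - lse)
    gq = np.minimum(
        np.round(-10.0 * np.log10(np.maximum(1.0 - post, 10.0 ** (-0.1 * MAX_GQ - 1)))),
        MAX_GQ,
    ).astype(np.int32)

    geno = call.copy()
    geno[(depth < model.min_dp) | (gq < model.min_gq)] = -1
    return GenotypeMatrix(
        truth.pedigree.ids, truth.markers, geno, depth.astype(np.int32), gq
    )


def error_free_observation(truth: TruthPanel) -> GenotypeMatrix:
    """The truth seen without sequencing noise (complete, exact genotypes)."""
    return truth.genotypes()


# ---------------------------------------------------------------------------
# GBS sparsification
# ---------------------------------------------------------------------------

@dataclass
class GBSDesign:
    """Which markers a GBS assay observes and how completely.

    ``call_rate`` is the per-cell probability that a genotype inside the
    design's marker set survives; the default emulates the study condition
    that about 69 % of individual genotypes were callable per site.
    """

    marker_indices: np.ndarray | None = None  # None = all markers
    call_rate: float = 0.69

    def __post_init__(self) -> None:
        if not (0.0 < self.call_rate <= 1.0):
            raise ValueError("call_rate must lie in (0, 1]")


def apply_gbs_design(
    g: GenotypeMatrix, design: GBSDesign, seed: int = 0
) -> GenotypeMatrix:
    """Mask markers outside the design and thin cells to the call rate."""
    rng = np.random.default_rng(seed)
    out = g.copy()
    if design.marker_indices is not None:
        keep = np.zeros(g.n_markers, bool)
        keep[np.asarray(design.marker_indices)] = True
        out.geno[:, ~keep] = -1
    if design.call_rate < 1.0:
        drop = rng.random(out.geno.shape) >= design.call_rate
        out.geno[drop] = -1
    return out


# ---------------------------------------------------------------------------
# Synthetic genomes for digest testing
# ---------------------------------------------------------------------------

@dataclass
class SynthGenome:
    seq: str
    planted_sites: list[int]  # motif start positions
    repeat_blocks: list[tuple[int, int]]  # 0-based half-open lowercase spans

    def write_fasta(self, path, name: str = "synth1") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for k in range(0, len(self.seq), 80):
                fh.write(self.seq[k : k + 80] + "\n")


def synth_genome(
    length: int,
    enzyme: Enzyme,
    n_sites: int,
    repeat_blocks: list[tuple[int, int]] | None = None,
    seed: int = 0,
    max_attempts: int = 50,
) -> SynthGenome:
    """Random genome with exactly ``n_sites`` planted motifs, else motif-free.

    The background is rejection-sampled until it contains no spurious motif
    occurrence (either strand), motifs are planted at well-separated
    positions, and the stated repeat blocks are lowercased afterwards
    (matching is case-insensitive, so masking never hides a site).
    """
    motif = enzyme.motif.upper()
    mlen = len(motif)
    if n_sites * mlen >= length:
        raise ValueError("n_sites * motif length must be below genome length")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pats = [_motif_regex(motif)]
    if not enzyme.is_palindromic:
        pats.append(_motif_regex(revcomp_motif(motif)))

    def occurrences(s: str) -> list[int]:
        hits: set[int] = set()
        for pat in pats:
            hits |= {m.start() for m in pat.finditer(s)}
        return sorted(hits)

    iupac_fill = {"W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT",
                  "M": "AC", "N": "ACGT", "B": "CGT", "D": "AGT",
                  "H": "ACT", "V": "ACG"}

    for _ in range(max_attempts):
        seq = rng.choice(bases, size=length)
        # knock out spurious background occurrences
        for _ in range(20):
            hits = occurrences("".join(seq))
            if not hits:
                break
            for h in hits:
                seq[h : h + mlen] = rng.choice(bases, size=mlen)
        else:
            continue
        # plant motifs at separated positions
        gap = 2 * mlen + 2
        if n_sites > 0:
            avail = length - mlen - n_sites * gap
            if avail <= 0:
                raise ValueError("cannot place that many sites in the genome")
            offsets = np.sort(rng.choice(avail, size=n_sites, replace=False))
            starts = offsets + gap * np.arange(n_sites)
        else:
            starts = np.array([], dtype=int)
        concrete = "".join(
            c if c in "ACGT" else rng.choice(list(iupac_fill[c])) for c in motif
        )
        for st in starts:
            seq[st : st + mlen] = list(concrete)
        s = "".join(seq)
        if occurrences(s) == list(map(int, starts)):
            blocks = repeat_blocks or []
            if blocks:
                arr = list(s)
                for a, b in blocks:
                    arr[a:b] = [c.lower() for c in arr[a:b]]
                s = "".join(arr)
            return SynthGenome(s, list(map(int, starts)), list(blocks))
    raise RuntimeError("could not satisfy synth_genome constraints")
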