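"""Domain types and I/O for pedigrees, markers, genotype matrices and genetic maps.

Conventions
-----------
* Pedigree individuals are stored in topological order (parents precede
  offspring).  A pedigree with ``f`` founders and ``n - f`` non-founders has
  ``m = 2 (n - f)`` meioses; the meiosis for (child, paternal) transmission of
  the *k*-th non-founder is ``2 k`` and the maternal one ``2 k + 1``.
* Each individual carries two allele "slots": slot ``2 i`` is the paternally
  inherited copy of individual *i*, slot ``2 i + 1`` the maternal copy.
  Founder slots are identified with *founder genes*, numbered ``2 j`` and
  ``2 j + 1`` for the *j*-th founder.
* VCF positions are 1-based; all internal interval arithmetic is 0-based
  half-open.  Conversion happens only at I/O boundaries.
* Genotypes are alt-allele dosages ``{0, 1, 2}`` with ``-1`` for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MISSING = -1

PATERNAL = 0
MATERNAL = 1


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``sire``/``dam`` are ``None`` for founders."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"  # {male, female, unknown}; carried but unused

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be non-empty")
        if (self.sire is None) != (self.dam is None):
            raise PedigreeError(
                f"individual {self.id!r} has exactly one parent specified; "
                "both parents must be present or both absent"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire is None


class Pedigree:
    """A non-inbred pedigree with fast index lookups for descent machinery.

    Parameters
    ----------
    individuals:
        Members in any order; they are re-sorted topologically.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        by_id: dict[str, Individual] = {}
        for ind in members:
            if ind.id in by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            by_id[ind.id] = ind
        for ind in members:
            for par in (ind.sire, ind.dam):
                if par is not None and par not in by_id:
                    raise PedigreeError(
                        f"parent {par!r} of {ind.id!r} is not in the pedigree"
                    )
        ts = TopologicalSorter(
            {
                ind.id: [p for p in (ind.sire, ind.dam) if p is not None]
                for ind in members
            }
        )
        try:
            order = list(ts.static_order())
        except CycleError as exc:
            raise PedigreeError(f"pedigree contains a cycle: {exc}") from exc

        self.individuals: list[Individual] = [by_id[i] for i in order]
        self.index: dict[str, int] = {i: k for k, i in enumerate(order)}
        self.ids: list[str] = order
        self.n = len(order)
        self.founders: list[str] = [i.id for i in self.individuals if i.is_founder]
        self.n_founders = len(self.founders)
        self.n_meioses = 2 * (self.n - self.n_founders)
        self.n_genes = 2 * self.n_founders

        # meiosis_map: (non-founder id, parent-of-origin) -> meiosis index
        self.meiosis_map: dict[tuple[str, int], int] = {}
        k = 0
        for ind in self.individuals:
            if not ind.is_founder:
                self.meiosis_map[(ind.id, PATERNAL)] = 2 * k
                self.meiosis_map[(ind.id, MATERNAL)] = 2 * k + 1
                k += 1

        self._build_slot_arrays()
        self._check_not_inbred()

    def _build_slot_arrays(self) -> None:
        """Per-slot arrays used by the descent kernels (see module docstring)."""
        n2 = 2 * self.n
        self.parent_of_slot = np.full(n2, -1, dtype=np.int32)
        self.meiosis_of_slot = np.full(n2, -1, dtype=np.int32)
        self.gene_of_slot = np.full(n2, -1, dtype=np.int32)
        founder_rank = {fid: j for j, fid in enumerate(self.founders)}
        for i, ind in enumerate(self.individuals):
            if ind.is_founder:
                j = founder_rank[ind.id]
                self.gene_of_slot[2 * i] = 2 * j
                self.gene_of_slot[2 * i + 1] = 2 * j + 1
            else:
                self.parent_of_slot[2 * i] = self.index[ind.sire]
                self.parent_of_slot[2 * i + 1] = self.index[ind.dam]
                self.meiosis_of_slot[2 * i] = self.meiosis_map[(ind.id, PATERNAL)]
                self.meiosis_of_slot[2 * i + 1] = self.meiosis_map[(ind.id, MATERNAL)]

    def kinship(self) -> np.ndarray:
        """Pairwise kinship coefficients (topological recursion)."""
        n = self.n
        phi = np.zeros((n, n))
        for i, ind in enumerate(self.individuals):
            if ind.is_founder:
                phi[i, i] = 0.5
            else:
                s, d = self.index[ind.sire], self.index[ind.dam]
                phi[i, i] = 0.5 + 0.5 * phi[s, d]
                for j in range(i):
                    phi[i, j] = phi[j, i] = 0.5 * (phi[s, j] + phi[d, j])
        return phi

    def _check_not_inbred(self) -> None:
        phi = self.kinship()
        for ind in self.individuals:
            if not ind.is_founder:
                s, d = self.index[ind.sire], self.index[ind.dam]
                if phi[s, d] > 0:
                    raise PedigreeError(
                        f"individual {ind.id!r} is inbred (parents {ind.sire!r} "
                        f"and {ind.dam!r} are related); inbred pedigrees are not "
                        "supported"
                    )

    def children_of(self, ind_id: str) -> list[str]:
        return [i.id for i in self.individuals if ind_id in (i.sire, i.dam)]

    def descendants_of(self, ind_id: str) -> set[str]:
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            cur = stack.pop()
            for ch in self.children_of(cur):
                if ch not in out:
                    out.add(ch)
                    stack.append(ch)
        return out

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return (
            f"Pedigree(n={self.n}, founders={self.n_founders}, "
            f"meioses={self.n_meioses})"
        )


@dataclass(frozen=True, order=True)
class Marker:
    """A biallelic SNV with a population alt-allele frequency."""

    chrom: str
    pos_bp: int  # 1-based
    ref: str = "A"
    alt: str = "C"
    alt_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"marker {self.chrom}:{self.pos_bp} has ref == alt")
        if not (0.0 < self.alt_freq < 1.0):
            raise ValueError(
                f"marker {self.chrom}:{self.pos_bp} alt_freq {self.alt_freq} "
                "must lie strictly inside (0, 1)"
            )

    @property
    def maf(self) -> float:
        return min(self.alt_freq, 1.0 - self.alt_freq)


class GenotypeMatrix:
    """Individuals x markers alt-dosage matrix with depth and quality.

    ``geno`` holds dosages in {0,1,2} with -1 for missing; ``depth`` and ``gq``
    may be recorded even where the genotype itself is missing.
    """

    def __init__(
        self,
        ids: Sequence[str],
        markers: Sequence[Marker],
        geno: np.ndarray,
        depth: np.ndarray | None = None,
        gq: np.ndarray | None = None,
    ):
        self.ids = list(ids)
        self.markers = list(markers)
        if sorted(self.markers, key=lambda m: (m.chrom, m.pos_bp)) != self.markers:
            raise ValueError("markers must be sorted by (chrom, pos_bp)")
        shape = (len(self.ids), len(self.markers))
        self.geno = np.asarray(geno, dtype=np.int8)
        if self.geno.shape != shape:
            raise ValueError(f"geno shape {self.geno.shape} != {shape}")
        self.depth = (
            np.zeros(shape, dtype=np.int32)
            if depth is None
            else np.asarray(depth, dtype=np.int32)
        )
        self.gq = (
            np.zeros(shape, dtype=np.int32)
            if gq is None
            else np.asarray(gq, dtype=np.int32)
        )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.ids, self.markers, self.geno.copy(), self.depth.copy(), self.gq.copy()
        )

    def subset_markers(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            self.ids,
            [self.markers[k] for k in keep],
            self.geno[:, keep],
            self.depth[:, keep],
            self.gq[:, keep],
        )

    def marker_positions(self) -> dict[tuple[str, int], int]:
        return {(m.chrom, m.pos_bp): k for k, m in enumerate(self.markers)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.markers == other.markers
            and np.array_equal(self.geno, other.geno)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.gq, other.gq)
        )


class GeneticMap:
    """Piecewise-linear bp -> cM map with per-chromosome anchors.

    A constant-rate map (``GeneticMap.constant_rate``) applies one cM/Mb rate
    to every chromosome; the default rate of 1 cM/Mb is the conventional
    mammalian average and is used whenever no empirical map is supplied.
    """

    def __init__(self, anchors: dict[str, list[tuple[int, float]]] | None = None,
                 default_rate_cm_per_mb: float | None = None):
        self.anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.default_rate = default_rate_cm_per_mb
        for chrom, pairs in (anchors or {}).items():
            bp = np.array([p for p, _ in pairs], dtype=float)
            cm = np.array([c for _, c in pairs], dtype=float)
            if len(bp) == 0:
                raise ValueError(f"chromosome {chrom!r} has no anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"anchor bp not strictly increasing on {chrom!r}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"anchor cM decreasing on {chrom!r}")
            self.anchors[chrom] = (bp, cm)

    @classmethod
    def constant_rate(cls, cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls(default_rate_cm_per_mb=cm_per_mb)

    def bp_to_cm(self, chrom: str, pos_bp: int | np.ndarray) -> float | np.ndarray:
        pos = np.asarray(pos_bp, dtype=float)
        if chrom not in self.anchors:
            if self.default_rate is None:
                raise KeyError(f"chromosome {chrom!r} not in genetic map")
            out = pos * self.default_rate / 1e6
            return float(out) if np.isscalar(pos_bp) else out
        bp, cm = self.anchors[chrom]
        if len(bp) == 1:
            rate = (self.default_rate or 1.0) / 1e6
            out = cm[0] + (pos - bp[0]) * rate
        else:
            out = np.interp(pos, bp, cm)
            # constant-rate extrapolation beyond the anchored span
            lo_rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
            hi_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            out = np.where(pos < bp[0], cm[0] + (pos - bp[0]) * lo_rate, out)
            out = np.where(pos > bp[-1], cm[-1] + (pos - bp[-1]) * hi_rate, out)
        return float(out) if np.isscalar(pos_bp) else out


def bp_to_cm(gmap: GeneticMap, chrom: str, pos_bp: int) -> float:
    """Functional alias for :meth:`GeneticMap.bp_to_cm`."""
    return gmap.bp_to_cm(chrom, pos_bp)


# ---------------------------------------------------------------------------
# PED / MAP readers
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female"}


def read_pedigree(path) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file ("0" = absent parent)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        dtype=str,
        comment="#",
        names=["fam", "id", "sire", "dam", "sex", "pheno"],
    )
    inds = []
    for row in df.itertuples(index=False):
        sire = None if row.sire in ("0", None) else row.sire
        dam = None if row.dam in ("0", None) else row.dam
        inds.append(
            Individual(
                id=row.id,
                sire=sire,
                dam=dam,
                sex=_SEX_CODE.get(str(row.sex), "unknown"),
            )
        )
    return Pedigree(inds)


def write_pedigree(ped: Pedigree, path, fam: str = "FAM1") -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                f"{fam}\t{ind.id}\t{ind.sire or '0'}\t{ind.dam or '0'}"
                f"\t{sex_code[ind.sex]}\t-9\n"
            )


def read_genetic_map(path, default_rate_cm_per_mb: float = 1.0) -> GeneticMap:
    """Read a PLINK-style .map file (chrom, marker-id, cM, bp)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "bp"],
        dtype={"chrom": str},
    )
    anchors: dict[str, list[tuple[int, float]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("bp")
        anchors[chrom] = list(zip(sub.bp.astype(int), sub.cm.astype(float)))
    return GeneticMap(anchors, default_rate_cm_per_mb=default_rate_cm_per_mb)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def _trio_possible() -> np.ndarray:
    """possible[father, mother, child] for dosages 0..2 of a biallelic marker."""
    tbl = np.zeros((3, 3, 3), dtype=bool)
    for f in range(3):
        for m in range(3):
            fa = {0: [0], 1: [0, 1], 2: [1]}[f]
            ma = {0: [0], 1: [0, 1], 2: [1]}[m]
            for a in fa:
                for b in ma:
                    tbl[f, m, a + b] = True
    return tbl


_TRIO_OK = _trio_possible()
# duo[parent, child]: child must receive one allele from the parent
_DUO_OK = np.array(
    [[True, True, False], [True, True, True], [False, True, True]]
)


def mendelian_errors(
    ped: Pedigree, g: GenotypeMatrix
) -> list[tuple[int, str, tuple[str, str]]]:
    """List (marker index, individual id, (sire, dam)) Mendelian violations.

    Trio combinations are checked where both parents have non-missing
    genotypes; otherwise each available parent is checked as a duo.  Missing
    genotypes never trigger violations.
    """
    idx = {i: k for k, i in enumerate(g.ids)}
    for ind in ped.individuals:
        if ind.id not in idx:
            raise KeyError(f"pedigree individual {ind.id!r} absent from matrix")
    out: list[tuple[int, str, tuple[str, str]]] = []
    for ind in ped.individuals:
        if ind.is_founder:
            continue
        ci, si, di = idx[ind.id], idx[ind.sire], idx[ind.dam]
        c, s, d = g.geno[ci], g.geno[si], g.geno[di]
        valid_c = c >= 0
        trio = valid_c & (s >= 0) & (d >= 0)
        bad = np.zeros(g.n_markers, dtype=bool)
        bad[trio] = ~_TRIO_OK[s[trio], d[trio], c[trio]]
        duo_s = valid_c & (s >= 0) & (d < 0)
        bad[duo_s] = ~_DUO_OK[s[duo_s], c[duo_s]]
        duo_d = valid_c & (s < 0) & (d >= 0)
        bad[duo_d] = ~_DUO_OK[d[duo_d], c[duo_d]]
        for k in np.flatnonzero(bad):
            out.append((int(k), ind.id, (ind.sire, ind.dam)))
    return out


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)
# ---------------------------------------------------------------------------

def _vcf_header(matrix: GenotypeMatrix) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chrom_max: dict[str, int] = {}
    for m in matrix.markers:
        chrom_max[m.chrom] = max(chrom_max.get(m.chrom, 0), m.pos_bp)
    for chrom, mx in chrom_max.items():
        header.contigs.add(chrom, length=mx + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    header.info.add("AF", "A", "Float", "Alt allele frequency")
    for s in matrix.ids:
        header.add_sample(s)
    return header


def write_genotypes_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a biallelic-SNV VCF with GT/DP/GQ (uncompressed text)."""
    header = _vcf_header(matrix)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for k, m in enumerate(matrix.markers):
            rec = vcf.new_record(
                contig=m.chrom,
                start=m.pos_bp - 1,
                stop=m.pos_bp,
                alleles=(m.ref, m.alt),
            )
            rec.info["AF"] = round(m.alt_freq, 6)
            for i, s in enumerate(matrix.ids):
                dose = int(matrix.geno[i, k])
                if dose < 0:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[dose]
                rec.samples[s]["DP"] = int(matrix.depth[i, k])
                rec.samples[s]["GQ"] = int(matrix.gq[i, k])
            vcf.write(rec)


def read_genotypes_vcf(path, pedigree: Pedigree | None = None) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF; other records are skipped and counted.

    Half-calls and missing genotypes map to dosage -1.  If ``pedigree`` is
    given, sample names must match its individual ids.
    """
    skipped = 0
    markers: list[Marker] = []
    rows_g: list[list[int]] = []
    rows_d: list[list[int]] = []
    rows_q: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if pedigree is not None:
            unknown = set(samples) - set(pedigree.ids)
            if unknown:
                raise ValueError(f"VCF samples not in pedigree: {sorted(unknown)}")
        for rec in vcf:
            if (
                len(rec.alts or ()) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
                or rec.ref not in "ACGT"
                or rec.alts[0] not in "ACGT"
            ):
                skipped += 1
                continue
            try:
                af = rec.info.get("AF")
            except (KeyError, ValueError):
                af = None
            af = float(af[0]) if isinstance(af, tuple) else float(af or 0.5)
            # VCF floats are single precision; re-round to the written digits
            af = round(min(max(af, 1e-6), 1 - 1e-6), 6)
            markers.append(
                Marker(rec.chrom, rec.pos, rec.ref, rec.alts[0], alt_freq=af)
            )
            g_row, d_row, q_row = [], [], []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    g_row.append(MISSING)
                else:
                    g_row.append(int(sum(gt)))
                d_row.append(int(call.get("DP") or 0))
                q_row.append(int(call.get("GQ") or 0))
            rows_g.append(g_row)
            rows_d.append(d_row)
            rows_q.append(q_row)
    if skipped:
        log.info("read_genotypes_vcf: skipped %d non-biallelic-SNV records", skipped)
    geno = np.array(rows_g, dtype=np.int8).T if rows_g else np.zeros((len(samples), 0), np.int8)
    depth = np.array(rows_d, dtype=np.int32).T if rows_d else None
    gq = np.array(rows_q, dtype=np.int32).T if rows_q else None
    mat = GenotypeMatrix(samples, markers, geno, depth, gq)
    mat.n_skipped_records = skipped
    return mat
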