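"""In silico restriction digest for GBS panel design.

Predicts the reduced-representation fraction of a genome captured by a
restriction enzyme: cut-site scanning (IUPAC-aware, case-insensitive),
fragmentation of each contig, size selection to the sequencer-friendly
window, repeat filtering via soft-masked (lowercase) bases, and ranking of
candidate enzymes against a target fragment count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_motif(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme recognition motif with its top-strand cut offset."""

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        bad = [c for c in self.motif.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in motif {self.motif!r}")
        if not (0 <= self.cut_offset <= len(self.motif)):
            raise ValueError("cut_offset must lie within the motif")

    @property
    def is_palindromic(self) -> bool:
        return self.motif.upper() == revcomp_motif(self.motif.upper())


BUILTIN_ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in [
        Enzyme("PstI", "CTGCAG", 5),
        Enzyme("BglII", "AGATCT", 1),
        Enzyme("ApeKI", "GCWGC", 1),
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("HindIII", "AAGCTT", 1),
    ]
}


@dataclass(frozen=True)
class Fragment:
    """A digest fragment in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DigestSummary:
    enzyme: str
    n_fragments_total: int
    n_in_size_range: int
    bp_in_range: int
    genome_fraction: float


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported; character
    # classes over ACGT only, so sequence 'N' never matches
    body = "".join(f"[{IUPAC[c]}]" for c in motif.upper())
    return re.compile(f"(?=({body}))", re.IGNORECASE)


def scan_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Sorted 0-based cut positions (motif start + cut_offset) in ``seq``.

    Palindromic motifs are scanned on the forward strand only; for
    non-palindromic motifs, reverse-complement occurrences are merged in
    (cut taken at the same offset from the occurrence start on the top
    strand, keeping fragment bookkeeping consistent across enzymes).
    """
    cuts = {m.start() + enzyme.cut_offset for m in _motif_regex(enzyme.motif).finditer(seq)}
    if not enzyme.is_palindromic:
        rc = revcomp_motif(enzyme.motif.upper())
        cuts |= {
            m.start() + enzyme.cut_offset
            for m in _motif_regex(rc).finditer(seq)
        }
    return sorted(c for c in cuts if 0 <= c <= len(seq))


def _masked_fraction(seq: str, start: int, end: int, lower_cum: np.ndarray) -> float:
    return float(lower_cum[end] - lower_cum[start]) / (end - start)


def fragments_from_cuts(contig: str, seq: str, cuts: Sequence[int]) -> list[Fragment]:
    """k cuts -> k+1 fragments tiling [0, len(seq)); terminal fragments kept."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_lower = (arr >= 97).astype(np.int64)  # lowercase ASCII letters
    lower_cum = np.concatenate([[0], np.cumsum(is_lower)])
    bounds = [0, *[c for c in cuts if 0 < c < len(seq)], len(seq)]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            out.append(Fragment(contig, a, b, _masked_fraction(seq, a, b, lower_cum)))
    return out


def digest_genome(fasta_path, enzyme: Enzyme) -> list[Fragment]:
    """Digest every contig of a (possibly soft-masked) FASTA file."""
    fa = Fasta(str(fasta_path), read_long_names=False)
    names = list(fa.keys())
    if not names:
        raise ValueError(f"empty FASTA: {fasta_path}")
    out: list[Fragment] = []
    for name in names:
        seq = str(fa[name][:])
        out.extend(fragments_from_cuts(name, seq, scan_sites(seq, enzyme)))
    return out


def size_select(
    fragments: Iterable[Fragment], min_bp: int = 200, max_bp: int = 500
) -> list[Fragment]:
    """Keep fragments with min_bp <= length <= max_bp (bounds inclusive)."""
    if min_bp > max_bp:
        raise ValueError(f"min_bp {min_bp} > max_bp {max_bp}")
    return [f for f in fragments if min_bp <= f.length <= max_bp]


def mask_filter(
    fragments: Iterable[Fragment], max_masked_fraction: float = 0.5
) -> list[Fragment]:
    """Drop fragments whose soft-masked fraction exceeds the threshold."""
    if not (0.0 <= max_masked_fraction <= 1.0):
        raise ValueError("max_masked_fraction must lie in [0, 1]")
    return [f for f in fragments if f.masked_fraction <= max_masked_fraction]


def summarize_digest(
    enzyme: Enzyme,
    fragments: Sequence[Fragment],
    genome_length: int,
    min_bp: int = 200,
    max_bp: int = 500,
    max_masked_fraction: float = 0.5,
) -> DigestSummary:
    kept = mask_filter(size_select(fragments, min_bp, max_bp), max_masked_fraction)
    bp = sum(f.length for f in kept)
    return DigestSummary(
        enzyme=enzyme.name,
        n_fragments_total=len(fragments),
        n_in_size_range=len(kept),
        bp_in_range=bp,
        genome_fraction=bp / genome_length if genome_length else 0.0,
    )


def rank_enzymes(
    summaries: Sequence[DigestSummary],
    target_min: int = 60_000,
    target_max: int = 100_000,
) -> list[DigestSummary]:
    """Rank enzymes toward the target count of usable fragments.

    Enzymes inside [target_min, target_max] on ``n_in_size_range`` come
    first, larger ``bp_in_range`` preferred among them; enzymes outside the
    window are ordered by distance to the nearest bound.  Ties break on name.
    """
    if not summaries:
        raise ValueError("need at least one digest summary")

    def key(s: DigestSummary):
        inside = target_min <= s.n_in_size_range <= target_max
        if inside:
            return (0, -s.bp_in_range, s.enzyme)
        dist = (
            target_min - s.n_in_size_range
            if s.n_in_size_range < target_min
            else s.n_in_size_range - target_max
        )
        return (1, dist, s.enzyme)

    return sorted(summaries, key=key)


def fragments_to_bed(fragments: Iterable[Fragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t.\t{f.masked_fraction:.4f}\n")
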