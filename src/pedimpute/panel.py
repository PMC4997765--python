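"""Framework / dense marker panel construction and allele-frequency estimation.

Framework markers anchor inheritance-vector inference, so they must be
common (high MAF), reliably callable across the cohort's GBS libraries, and
roughly evenly spaced; dense markers are the remaining variant sites to be
imputed.  Panel construction is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedio import GeneticMap, GenotypeMatrix, Marker


@dataclass(frozen=True)
class PanelSpec:
    """Filters a framework-marker candidate must pass."""

    min_site_depth: int = 20
    min_call_rate: float = 0.5
    min_maf: float = 0.25
    require_concordance: bool = True
    max_discordance_rate: float = 0.0  # 0 = any single discordant call rejects

    def __post_init__(self) -> None:
        if not (0.0 < self.min_call_rate <= 1.0):
            raise ValueError("min_call_rate must lie in (0, 1]")


@dataclass
class MarkerPanel:
    framework: list[Marker]
    dense: list[Marker]

    def __post_init__(self) -> None:
        fw = {(m.chrom, m.pos_bp) for m in self.framework}
        dn = {(m.chrom, m.pos_bp) for m in self.dense}
        if fw & dn:
            raise ValueError("framework and dense panels overlap")


def candidate_framework_sites(
    gbs: GenotypeMatrix,
    wgs: GenotypeMatrix,
    spec: PanelSpec = PanelSpec(),
) -> list[Marker]:
    """Markers reliably genotyped by GBS, common, and concordant with WGS.

    Keeps markers where (a) at least ``min_call_rate`` of individuals have a
    non-missing GBS call with depth >= ``min_site_depth``, (b) the sample MAF
    from GBS exceeds ``min_maf``, and (c) if required, GBS and WGS calls
    agree for (almost) every individual carrying both.
    """
    gbs_pos = gbs.marker_positions()
    wgs_pos = wgs.marker_positions()
    shared = [key for key in gbs_pos if key in wgs_pos]
    if not shared:
        raise ValueError("GBS and WGS matrices share no markers")
    common_ids = [i for i in wgs.ids if i in gbs.ids]
    g_rows = np.array([gbs.ids.index(i) for i in common_ids])
    w_rows = np.array([wgs.ids.index(i) for i in common_ids])

    out: list[Marker] = []
    for key in shared:
        kg = gbs_pos[key]
        geno = gbs.geno[:, kg]
        good = (geno >= 0) & (gbs.depth[:, kg] >= spec.min_site_depth)
        if good.mean() < spec.min_call_rate:
            continue
        called = geno[geno >= 0]
        if len(called) == 0:
            continue
        af = called.sum() / (2 * len(called))
        if min(af, 1 - af) <= spec.min_maf:
            continue
        if spec.require_concordance:
            kw = wgs_pos[key]
            gg = gbs.geno[g_rows, kg]
            ww = wgs.geno[w_rows, kw]
            both = (gg >= 0) & (ww >= 0)
            if both.any():
                rate = float((gg[both] != ww[both]).mean())
                if rate > spec.max_discordance_rate:
                    continue
        out.append(gbs.markers[kg])
    return sorted(out, key=lambda m: (m.chrom, m.pos_bp))


def select_spaced_markers(
    candidates: list[Marker],
    target_spacing: float,
    gmap: GeneticMap | None = None,
    use_cm: bool = False,
) -> list[Marker]:
    """Greedy left-to-right spacing selection per chromosome.

    Keeps the first candidate on each chromosome, then every next candidate
    at least ``target_spacing`` (bp, or cM when ``use_cm``) from the last
    kept one.
    """
    if use_cm and gmap is None:
        raise ValueError("use_cm requires a genetic map")
    out: list[Marker] = []
    last: dict[str, float] = {}
    for m in candidates:
        pos = gmap.bp_to_cm(m.chrom, m.pos_bp) if use_cm else float(m.pos_bp)
        if m.chrom not in last or pos - last[m.chrom] >= target_spacing:
            out.append(m)
            last[m.chrom] = pos
    return out


def select_dense_markers(
    wgs_sites: list[Marker],
    spacing: float = 10_000,
    framework: list[Marker] | None = None,
    gmap: GeneticMap | None = None,
    use_cm: bool = False,
) -> list[Marker]:
    """Spacing selection over the WGS site pool, excluding framework sites."""
    fw = {(m.chrom, m.pos_bp) for m in framework or []}
    pool = [m for m in wgs_sites if (m.chrom, m.pos_bp) not in fw]
    return select_spaced_markers(pool, spacing, gmap=gmap, use_cm=use_cm)


def estimate_allele_freqs(
    reference: GenotypeMatrix,
    exclude: set[str] | None = None,
    pseudo_clamp: bool = False,
) -> np.ndarray:
    """Alt-allele frequencies from a reference cohort, per marker.

    Frequencies are allele counts over non-missing calls among non-excluded
    individuals; markers with zero calls yield NaN.  With ``pseudo_clamp``
    the estimates are clamped to [1/(2N+2), 1 - 1/(2N+2)] so monomorphic
    markers still give proper imputation priors.
    """
    keep = [k for k, i in enumerate(reference.ids) if i not in (exclude or set())]
    if not keep:
        raise ValueError("no reference individuals left after exclusions")
    geno = reference.geno[keep]
    called = geno >= 0
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    if pseudo_clamp:
        n_ind = len(keep)
        lo = 1.0 / (2 * n_ind + 2)
        af = np.clip(af, lo, 1.0 - lo)
    return af
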