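"""Dense-genotype imputation given inheritance vectors.

At each dense position, per-meiosis IV bits are interpolated from the
flanking framework markers (Haldane transitions), founder-gene alleles are
conditioned on the observed dense genotypes of the sequenced donors, and the
resulting posterior genotype distribution for every unsequenced individual
is averaged across IV realizations, each weighted by the likelihood of the
donor observations under that realization.  Genotypes are then called either
as the most likely genotype (always 2 alleles) or only above confidence
thresholds, where a single confident allele may be emitted as a half-call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .descent import IVSampleSet, haldane
from .pedio import GeneticMap, GenotypeMatrix, Marker, Pedigree

log = logging.getLogger(__name__)

RR, RA, AA = 0, 1, 2


@dataclass(frozen=True)
class CallThresholds:
    """Posterior confidence required to call a genotype or a single allele."""

    t_both: float = 0.99
    t_single: float = 0.98

    def __post_init__(self) -> None:
        for v in (self.t_both, self.t_single):
            if not (0.5 < v <= 1.0):
                raise ValueError("thresholds must lie in (0.5, 1]")


STRICT = CallThresholds(t_both=0.99, t_single=0.98)
RELAXED = CallThresholds(t_both=0.95, t_single=0.98)


@dataclass(frozen=True)
class ImputedCall:
    """Outcome of calling one imputed genotype.

    ``alleles`` holds 0 (ref) / 1 (alt) values; length equals
    ``n_alleles_called`` (2 for a full genotype, 1 for a half-call, 0 for
    no-call).
    """

    n_alleles_called: int
    alleles: tuple[int, ...]
    method: str  # "most_likely" | "threshold"


def interp_iv_bit(
    b_left: int | None,
    b_right: int | None,
    theta_left: float,
    theta_right: float,
) -> float:
    """P(dense-position bit = 0) given flanking framework bits.

    With both flanks the two transition probabilities are combined and
    normalized; with a single flank (dense position outside the framework
    span) the one-interval transition applies; with none, 0.5.
    """
    return float(
        _kernels._interp_p0(
            0 if b_left is None else int(b_left),
            0 if b_right is None else int(b_right),
            b_left is not None,
            b_right is not None,
            float(theta_left),
            float(theta_right),
        )
    )


def call_most_likely(gp, alt_freq: float = 0.5) -> ImputedCall:
    """Argmax genotype; ties prefer the genotype carrying the major allele."""
    gp = np.asarray(gp, dtype=float)
    pref = _genotype_preference(alt_freq)
    g = pref[int(np.argmax(gp[pref]))]
    alleles = {RR: (0, 0), RA: (0, 1), AA: (1, 1)}[int(g)]
    return ImputedCall(2, alleles, "most_likely")


def _genotype_preference(alt_freq: float) -> np.ndarray:
    # order in which equal-probability genotypes win: major-allele-bearing
    # first, then lexicographic RR < RA < AA
    return np.array([2, 1, 0]) if alt_freq > 0.5 else np.array([0, 1, 2])


def call_threshold(gp, ap, t: CallThresholds, alt_freq: float = 0.5) -> ImputedCall:
    """Call both alleles above ``t_both``; else one confident allele; else none.

    The single-allele rule works on the unordered genotype: allele ``a`` is
    callable when the posterior probability that the genotype *contains* at
    least one copy of ``a`` reaches ``t_single``.  (A rule on the two phased
    slots would not be invariant under the unidentifiable phase labeling of
    founder haplotypes; the containment probability is.)  If both alleles
    pass, the more probable one is called, ties toward the major allele.
    """
    gp = np.asarray(gp, dtype=float)
    if gp.max() >= t.t_both:
        return ImputedCall(2, call_most_likely(gp, alt_freq).alleles, "threshold")
    contains = np.array([gp[0] + gp[1], gp[1] + gp[2]])  # ref, alt
    if contains.max() >= t.t_single:
        if abs(contains[0] - contains[1]) < 1e-12:
            allele = 1 if alt_freq > 0.5 else 0
        else:
            allele = int(np.argmax(contains))
        return ImputedCall(1, (allele,), "threshold")
    return ImputedCall(0, (), "threshold")


@dataclass
class ImputationResult:
    """Posteriors and calls for every (dense marker, target individual).

    Arrays are indexed (marker, target).  ``thr_n`` counts alleles called by
    the threshold method; for ``thr_n == 2`` the dosage sits in ``thr_dose``,
    for ``thr_n == 1`` the single allele in ``thr_allele``.
    """

    markers: list[Marker]
    target_ids: list[str]
    donor_ids: list[str]
    gt_post: np.ndarray  # (Ld, nt, 3)
    slot_post: np.ndarray  # (Ld, nt, 2)
    ml_dose: np.ndarray  # (Ld, nt) in {0,1,2}
    thr_n: np.ndarray  # (Ld, nt) in {0,1,2}
    thr_dose: np.ndarray  # (Ld, nt), -1 unless thr_n == 2
    thr_allele: np.ndarray  # (Ld, nt), -1 unless thr_n == 1
    site_ok: np.ndarray  # (Ld,) bool; False where every IV contradicted donors
    thresholds: CallThresholds

    @property
    def n_skipped_sites(self) -> int:
        return int((~self.site_ok).sum())


def _flank_arrays(
    dense_markers: list[Marker],
    ivs: IVSampleSet,
    gmap: GeneticMap,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    fw_cm = ivs.positions_cm
    pos_cm = np.asarray(
        gmap.bp_to_cm(ivs.chrom, np.array([m.pos_bp for m in dense_markers])),
        dtype=float,
    )
    right = np.searchsorted(fw_cm, pos_cm, side="left")
    left = right - 1
    has_right = right < len(fw_cm)
    has_left = left >= 0
    theta_l = np.where(
        has_left, haldane(np.abs(pos_cm - fw_cm[np.clip(left, 0, None)])), 0.0
    )
    theta_r = np.where(
        has_right,
        haldane(np.abs(fw_cm[np.clip(right, None, len(fw_cm) - 1)] - pos_cm)),
        0.0,
    )
    left_idx = np.where(has_left, left, -1).astype(np.int64)
    right_idx = np.where(has_right, right, -1).astype(np.int64)
    return left_idx, right_idx, theta_l.astype(float), theta_r.astype(float)


def impute_markers(
    ped: Pedigree,
    dense_markers: list[Marker],
    dense_obs: GenotypeMatrix,
    donors: list[str],
    ivs: IVSampleSet,
    gmap: GeneticMap,
    thresholds: CallThresholds = STRICT,
    k_dense: int = 1,
    seed: int = 0,
) -> ImputationResult:
    """Impute every dense marker into all non-donor pedigree members.

    ``dense_obs`` holds the donors' observed genotypes over exactly
    ``dense_markers`` (non-donor cells are ignored).  Donor genotypes are
    treated as error-free; sites where every sampled IV contradicts them are
    flagged and skipped.
    """
    if [m for m in dense_obs.markers] != list(dense_markers):
        raise ValueError("dense_obs markers must equal dense_markers")
    targets = [i for i in ped.ids if i not in set(donors)]
    target_idx = np.array([ped.index[i] for i in targets], np.int64)

    order = [dense_obs.ids.index(i) for i in ped.ids]
    obs = dense_obs.geno[order]  # (n, Ld) in pedigree order
    donor_rows = np.array([ped.index[i] for i in donors])
    masked = np.full_like(obs, -1)
    masked[donor_rows] = obs[donor_rows]
    obs_t = np.ascontiguousarray(masked.T)

    p_dense = np.array([m.alt_freq for m in dense_markers])
    left_idx, right_idx, theta_l, theta_r = _flank_arrays(dense_markers, ivs, gmap)

    _kernels.seed_rng(int(np.random.default_rng(seed).integers(2**31 - 1)))
    gt_post, slot_post, zsum = _kernels.impute_sites(
        ivs.bits, left_idx, right_idx, theta_l, theta_r, obs_t, p_dense,
        target_idx, ped.parent_of_slot, ped.meiosis_of_slot, ped.gene_of_slot,
        ped.n_genes, int(k_dense),
    )
    site_ok = zsum > 0
    if not site_ok.all():
        log.warning(
            "impute_markers: %d site(s) contradicted donor genotypes under "
            "every sampled IV; skipped", int((~site_ok).sum()),
        )
    denom = np.where(site_ok, zsum, 1.0)[:, None, None]
    gt_post = gt_post / denom
    slot_post = slot_post / denom

    ml_dose, thr_n, thr_dose, thr_allele = _vector_calls(
        gt_post, slot_post, p_dense, thresholds, site_ok
    )
    return ImputationResult(
        markers=list(dense_markers),
        target_ids=targets,
        donor_ids=list(donors),
        gt_post=gt_post,
        slot_post=slot_post,
        ml_dose=ml_dose,
        thr_n=thr_n,
        thr_dose=thr_dose,
        thr_allele=thr_allele,
        site_ok=site_ok,
        thresholds=thresholds,
    )


def _vector_calls(
    gt_post: np.ndarray,
    slot_post: np.ndarray,
    p_dense: np.ndarray,
    t: CallThresholds,
    site_ok: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    Ld, nt, _ = gt_post.shape
    # most-likely: argmax in major-allele-first preference order so exact
    # ties resolve toward the major allele, then lexicographically
    ml_dose = np.empty((Ld, nt), np.int8)
    alt_major = p_dense > 0.5
    for sel, pref in ((~alt_major, np.array([0, 1, 2])), (alt_major, np.array([2, 1, 0]))):
        if sel.any():
            sub = gt_post[sel][:, :, pref]
            ml_dose[sel] = pref[np.argmax(sub, axis=2)].astype(np.int8)

    gmax = gt_post.max(axis=2)
    both = (gmax >= t.t_both) & site_ok[:, None]
    # single-allele rule on the unordered genotype (phase-invariant):
    # P(genotype contains ref) and P(genotype contains alt)
    contains_ref = gt_post[:, :, 0] + gt_post[:, :, 1]
    contains_alt = gt_post[:, :, 1] + gt_post[:, :, 2]
    best = np.maximum(contains_ref, contains_alt)
    one = (~both) & (best >= t.t_single) & site_ok[:, None]

    thr_n = np.zeros((Ld, nt), np.int8)
    thr_n[both] = 2
    thr_n[one] = 1
    thr_dose = np.where(both, ml_dose, -1).astype(np.int8)
    tie = np.abs(contains_ref - contains_alt) < 1e-12
    single_alt = np.where(
        tie, (p_dense > 0.5)[:, None], contains_alt > contains_ref
    )
    thr_allele = np.where(one, single_alt.astype(np.int8), -1).astype(np.int8)
    return ml_dose, thr_n, thr_dose, thr_allele


def dense_posterior(
    ivs: IVSampleSet,
    ped: Pedigree,
    dense_obs: dict[str, int],
    p: float,
    pos_cm: float,
    k_dense: int = 1,
    seed: int = 0,
    exact: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (genotype, per-slot alt) probabilities at one dense position.

    Returns ``(gt_post, slot_post)`` with shapes (n_targets, 3) and
    (n_targets, 2) over the individuals absent from ``dense_obs`` (pedigree
    order).  ``exact=True`` enumerates all dense IVs against the exact
    framework-state weights (single framework marker only) instead of
    Monte-Carlo draws.
    """
    targets = [i for i in ped.ids if i not in dense_obs]
    target_idx = np.array([ped.index[i] for i in targets], np.int64)
    gt = np.full(ped.n, -1, np.int8)
    for k, v in dense_obs.items():
        if v is not None and v >= 0:
            gt[ped.index[k]] = v

    if exact:
        if ivs.marginals is None or ivs.n_markers != 1:
            raise ValueError(
                "exact mode needs an exact IV posterior over one framework marker"
            )
        return _dense_posterior_exact(
            ivs, ped, gt, target_idx, float(p), float(pos_cm)
        )

    m = ped.n_meioses
    fw_cm = ivs.positions_cm
    right = int(np.searchsorted(fw_cm, pos_cm, side="left"))
    left = right - 1
    left_idx = np.array([left if left >= 0 else -1], np.int64)
    right_idx = np.array([right if right < len(fw_cm) else -1], np.int64)
    tl = haldane(abs(pos_cm - fw_cm[left])) if left >= 0 else 0.0
    tr = haldane(abs(fw_cm[right] - pos_cm)) if right < len(fw_cm) else 0.0
    _kernels.seed_rng(int(np.random.default_rng(seed).integers(2**31 - 1)))
    gt_post, slot_post, zsum = _kernels.impute_sites(
        ivs.bits, left_idx, right_idx, np.array([tl]), np.array([tr]),
        np.ascontiguousarray(gt[None, :]), np.array([float(p)]), target_idx,
        ped.parent_of_slot, ped.meiosis_of_slot, ped.gene_of_slot,
        ped.n_genes, int(k_dense),
    )
    if zsum[0] == 0:
        raise ValueError("dense observations contradicted every sampled IV")
    return gt_post[0] / zsum[0], slot_post[0] / zsum[0]


def _dense_posterior_exact(
    ivs: IVSampleSet,
    ped: Pedigree,
    gt: np.ndarray,
    target_idx: np.ndarray,
    p: float,
    pos_cm: float,
) -> tuple[np.ndarray, np.ndarray]:
    m = ped.n_meioses
    theta = haldane(abs(pos_cm - float(ivs.positions_cm[0])))
    weights = ivs.marginals[0]
    S = weights.shape[0]
    table = ((np.arange(S)[:, None] >> np.arange(m)) & 1).astype(np.uint8)

    ng = ped.n_genes
    uf = np.empty(ng, np.int32)
    par = np.empty(ng, np.uint8)
    w0 = np.empty(ng, np.float64)
    w1 = np.empty(ng, np.float64)
    labels = np.empty(2 * ped.n, np.int32)
    nt = target_idx.shape[0]
    gt_acc = np.zeros((nt, 3))
    slot_acc = np.zeros((nt, 2))
    ztot = 0.0
    for s_fw in range(S):
        w_fw = weights[s_fw]
        if w_fw == 0:
            continue
        for s_d in range(S):
            diff = int(bin(s_fw ^ s_d).count("1"))
            trans = theta**diff * (1 - theta) ** (m - diff)
            if trans == 0:
                continue
            _kernels.labels_for_bits(
                table[s_d], ped.parent_of_slot, ped.meiosis_of_slot,
                ped.gene_of_slot, labels,
            )
            z = _kernels.solve_site(labels, gt, p, uf, par, w0, w1)
            if z > 0:
                wgt = w_fw * trans * z
                _kernels.accumulate_targets(
                    labels, target_idx, uf, par, w0, w1, gt_acc, slot_acc, wgt
                )
                ztot += wgt
    if ztot == 0:
        raise ValueError("dense observations contradicted every IV")
    return gt_acc / ztot, slot_acc / ztot
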