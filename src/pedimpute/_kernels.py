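"""Compiled kernels for descent-graph likelihoods, MCMC sweeps and imputation.

The single-locus likelihood exploits the structure of the founder-gene sum:
homozygous observations force the alleles of the genes they touch, while
heterozygous observations impose an exclusive-or constraint between the two
genes of that individual.  A union-find with parity over founder genes then
yields the exact sum over all founder-allele assignments in time linear in
the number of observations: each connected component either collapses to a
single consistent coloring (forced) or to exactly two colorings whose prior
weights are tracked incrementally (W0/W1 per component root).  The total
likelihood is the product over component roots of (W0 + W1); a contradiction
drives both weights to zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _find(g, uf, par):
    """Root and parity of gene ``g`` with path compression."""
    r = g
    pr = 0
    while uf[r] != r:
        pr ^= par[r]
        r = uf[r]
    cur = g
    pcur = pr
    while uf[cur] != cur:
        nxt = uf[cur]
        pnxt = pcur ^ par[cur]
        uf[cur] = r
        par[cur] = pcur
        cur = nxt
        pcur = pnxt
    return r, pr


@njit(cache=True)
def solve_site(labels, gt, p, uf, par, w0, w1):
    """Likelihood of one locus' observed dosages given slot -> gene labels.

    Leaves the union-find/weight state in place so that callers may follow up
    with :func:`accumulate_targets`.  Returns 0.0 on Mendelian contradiction.
    """
    n_genes = uf.shape[0]
    for g in range(n_genes):
        uf[g] = g
        par[g] = 0
        w0[g] = 1.0 - p
        w1[g] = p
    n = gt.shape[0]
    for i in range(n):
        d = gt[i]
        if d < 0:
            continue
        a = labels[2 * i]
        b = labels[2 * i + 1]
        if d == 1:
            if a == b:
                return 0.0
            ra, pa = _find(a, uf, par)
            rb, pb = _find(b, uf, par)
            if ra == rb:
                if pa ^ pb != 1:
                    return 0.0
            else:
                pi = pa ^ pb ^ 1
                uf[rb] = ra
                par[rb] = pi
                if pi == 0:
                    nw0 = w0[ra] * w0[rb]
                    nw1 = w1[ra] * w1[rb]
                else:
                    nw0 = w0[ra] * w1[rb]
                    nw1 = w1[ra] * w0[rb]
                w0[ra] = nw0
                w1[ra] = nw1
                if nw0 + nw1 == 0.0:
                    return 0.0
        else:
            v = 1 if d == 2 else 0
            for k in range(2):
                gene = a if k == 0 else b
                r, pg = _find(gene, uf, par)
                keep = v ^ pg  # surviving root branch
                if keep == 0:
                    w1[r] = 0.0
                else:
                    w0[r] = 0.0
                if w0[r] + w1[r] == 0.0:
                    return 0.0
    z = 1.0
    for g in range(n_genes):
        if uf[g] == g:
            z *= w0[g] + w1[g]
    return z


@njit(cache=True)
def accumulate_targets(labels, targets, uf, par, w0, w1, gt_acc, slot_acc, weight):
    """Add Z-weighted genotype/slot posteriors for target individuals.

    Must be called right after :func:`solve_site` returned a positive value;
    uses the component weights it left behind.
    """
    nt = targets.shape[0]
    for t in range(nt):
        i = targets[t]
        a = labels[2 * i]
        b = labels[2 * i + 1]
        ra, pa = _find(a, uf, par)
        rb, pb = _find(b, uf, par)
        if ra == rb:
            tot = w0[ra] + w1[ra]
            for rv in range(2):
                prob = (w1[ra] if rv == 1 else w0[ra]) / tot
                xa = pa ^ rv
                xb = pb ^ rv
                gt_acc[t, xa + xb] += weight * prob
                if xa == 1:
                    slot_acc[t, 0] += weight * prob
                if xb == 1:
                    slot_acc[t, 1] += weight * prob
        else:
            tota = w0[ra] + w1[ra]
            totb = w0[rb] + w1[rb]
            # P(x = 1) given x = parity ^ root
            pa1 = (w1[ra] if pa == 0 else w0[ra]) / tota
            pb1 = (w1[rb] if pb == 0 else w0[rb]) / totb
            gt_acc[t, 0] += weight * (1 - pa1) * (1 - pb1)
            gt_acc[t, 1] += weight * (pa1 * (1 - pb1) + (1 - pa1) * pb1)
            gt_acc[t, 2] += weight * pa1 * pb1
            slot_acc[t, 0] += weight * pa1
            slot_acc[t, 1] += weight * pb1


@njit(cache=True)
def labels_for_bits(bits_col, parent_of_slot, meiosis_of_slot, gene_of_slot, out):
    """Slot -> founder-gene labels for a single locus' inheritance vector."""
    n2 = out.shape[0]
    for s in range(n2):
        g = gene_of_slot[s]
        if g >= 0:
            out[s] = g
        else:
            pa = parent_of_slot[s]
            b = bits_col[meiosis_of_slot[s]]
            out[s] = out[2 * pa + b]


@njit(cache=True)
def emissions_for_states(bits_table, obs_t, p, parent_of_slot, meiosis_of_slot,
                         gene_of_slot, n_genes):
    """Emission matrix (loci x inheritance-vector states) for the exact HMM."""
    n_states = bits_table.shape[0]
    n_loci = obs_t.shape[0]
    n2 = parent_of_slot.shape[0]
    labels = np.empty(n2, np.int32)
    uf = np.empty(n_genes, np.int32)
    par = np.empty(n_genes, np.uint8)
    w0 = np.empty(n_genes, np.float64)
    w1 = np.empty(n_genes, np.float64)
    out = np.empty((n_loci, n_states), np.float64)
    for s in range(n_states):
        labels_for_bits(bits_table[s], parent_of_slot, meiosis_of_slot,
                        gene_of_slot, labels)
        for t in range(n_loci):
            out[t, s] = solve_site(labels, obs_t[t], p[t], uf, par, w0, w1)
    return out


@njit(cache=True)
def sweep_once(bits, obs_t, p, theta, parent_of_slot, meiosis_of_slot,
               gene_of_slot, n_genes):
    """One random-scan Gibbs sweep: resample each meiosis' whole bit path.

    For the chosen meiosis a 2-state forward-backward is run along the
    chromosome with emissions equal to the locus likelihood under bit 0/1
    (all other meioses held fixed), then the path is backward-sampled.
    ``bits`` (meioses x loci) is updated in place.
    """
    m, n_loci = bits.shape
    n2 = parent_of_slot.shape[0]
    labels0 = np.empty((n_loci, n2), np.int32)
    labels1 = np.empty((n_loci, n2), np.int32)
    e = np.empty((n_loci, 2), np.float64)
    alpha = np.empty((n_loci, 2), np.float64)
    uf = np.empty(n_genes, np.int32)
    par = np.empty(n_genes, np.uint8)
    w0 = np.empty(n_genes, np.float64)
    w1 = np.empty(n_genes, np.float64)

    order = np.empty(m, np.int64)
    for j in range(m):
        order[j] = j
    for j in range(m - 1, 0, -1):  # Fisher-Yates
        k = np.random.randint(0, j + 1)
        tmp = order[j]
        order[j] = order[k]
        order[k] = tmp

    for jj in range(m):
        j = order[jj]
        for t in range(n_loci):
            for s in range(n2):
                g = gene_of_slot[s]
                if g >= 0:
                    labels0[t, s] = g
                    labels1[t, s] = g
                else:
                    pa = parent_of_slot[s]
                    me = meiosis_of_slot[s]
                    if me == j:
                        labels0[t, s] = labels0[t, 2 * pa]
                        labels1[t, s] = labels1[t, 2 * pa + 1]
                    else:
                        b = bits[me, t]
                        labels0[t, s] = labels0[t, 2 * pa + b]
                        labels1[t, s] = labels1[t, 2 * pa + b]
            e[t, 0] = solve_site(labels0[t], obs_t[t], p[t], uf, par, w0, w1)
            e[t, 1] = solve_site(labels1[t], obs_t[t], p[t], uf, par, w0, w1)

        a0 = 0.5 * e[0, 0]
        a1 = 0.5 * e[0, 1]
        tot = a0 + a1
        alpha[0, 0] = a0 / tot
        alpha[0, 1] = a1 / tot
        for t in range(1, n_loci):
            th = theta[t - 1]
            a0 = e[t, 0] * (alpha[t - 1, 0] * (1 - th) + alpha[t - 1, 1] * th)
            a1 = e[t, 1] * (alpha[t - 1, 0] * th + alpha[t - 1, 1] * (1 - th))
            tot = a0 + a1
            alpha[t, 0] = a0 / tot
            alpha[t, 1] = a1 / tot

        b = 0 if np.random.random() < alpha[n_loci - 1, 0] else 1
        bits[j, n_loci - 1] = b
        for t in range(n_loci - 2, -1, -1):
            th = theta[t]
            p0 = alpha[t, 0] * ((1 - th) if b == 0 else th)
            p1 = alpha[t, 1] * (th if b == 0 else (1 - th))
            b = 0 if np.random.random() < p0 / (p0 + p1) else 1
            bits[j, t] = b


@njit(cache=True)
def pair_update(bits, j, k, obs_t, p, theta, parent_of_slot, meiosis_of_slot,
                gene_of_slot, n_genes):
    """Joint path resampling for a meiosis pair via a 4-state chain.

    Needed for irreducibility: constraints such as opposite homozygous
    siblings couple two meioses so that no single-meiosis move has positive
    probability, while the pairwise move crosses the barrier.
    """
    m, n_loci = bits.shape
    n2 = parent_of_slot.shape[0]
    labels = np.empty((4, n_loci, n2), np.int32)
    e = np.empty((n_loci, 4), np.float64)
    alpha = np.empty((n_loci, 4), np.float64)
    uf = np.empty(n_genes, np.int32)
    par = np.empty(n_genes, np.uint8)
    w0 = np.empty(n_genes, np.float64)
    w1 = np.empty(n_genes, np.float64)

    for c in range(4):
        bj = c & 1
        bk = c >> 1
        for t in range(n_loci):
            for s in range(n2):
                g = gene_of_slot[s]
                if g >= 0:
                    labels[c, t, s] = g
                else:
                    pa = parent_of_slot[s]
                    me = meiosis_of_slot[s]
                    if me == j:
                        b = bj
                    elif me == k:
                        b = bk
                    else:
                        b = bits[me, t]
                    labels[c, t, s] = labels[c, t, 2 * pa + b]
    for t in range(n_loci):
        for c in range(4):
            e[t, c] = solve_site(labels[c, t], obs_t[t], p[t], uf, par, w0, w1)

    tot = 0.0
    for c in range(4):
        alpha[0, c] = 0.25 * e[0, c]
        tot += alpha[0, c]
    for c in range(4):
        alpha[0, c] /= tot
    for t in range(1, n_loci):
        th = theta[t - 1]
        tot = 0.0
        for c in range(4):
            acc = 0.0
            for cp in range(4):
                fj = (1 - th) if (c & 1) == (cp & 1) else th
                fk = (1 - th) if (c >> 1) == (cp >> 1) else th
                acc += alpha[t - 1, cp] * fj * fk
            alpha[t, c] = e[t, c] * acc
            tot += alpha[t, c]
        for c in range(4):
            alpha[t, c] /= tot

    r = np.random.random()
    c = 3
    acc = 0.0
    for cc in range(4):
        acc += alpha[n_loci - 1, cc]
        if r < acc:
            c = cc
            break
    bits[j, n_loci - 1] = c & 1
    bits[k, n_loci - 1] = c >> 1
    for t in range(n_loci - 2, -1, -1):
        th = theta[t]
        tot = 0.0
        w = np.empty(4, np.float64)
        for cp in range(4):
            fj = (1 - th) if (c & 1) == (cp & 1) else th
            fk = (1 - th) if (c >> 1) == (cp >> 1) else th
            w[cp] = alpha[t, cp] * fj * fk
            tot += w[cp]
        r = np.random.random() * tot
        acc = 0.0
        cnew = 3
        for cp in range(4):
            acc += w[cp]
            if r < acc:
                cnew = cp
                break
        c = cnew
        bits[j, t] = c & 1
        bits[k, t] = c >> 1


@njit(cache=True)
def locus_gibbs_pass(bits, obs_t, p, theta, parent_of_slot, meiosis_of_slot,
                     gene_of_slot, n_genes, bits_table, popcnt):
    """Joint resampling of the whole IV at each locus over all 2^m states.

    Exact single-locus Gibbs; used for small pedigrees, where it makes the
    combined sampler irreducible regardless of genotype constraints.
    """
    m, n_loci = bits.shape
    S = bits_table.shape[0]
    n2 = parent_of_slot.shape[0]
    labels = np.empty(n2, np.int32)
    uf = np.empty(n_genes, np.int32)
    par = np.empty(n_genes, np.uint8)
    w0 = np.empty(n_genes, np.float64)
    w1 = np.empty(n_genes, np.float64)
    w = np.empty(S, np.float64)
    for t in range(n_loci):
        sl = 0
        sr = 0
        if t > 0:
            for j in range(m):
                sl |= int(bits[j, t - 1]) << j
        if t < n_loci - 1:
            for j in range(m):
                sr |= int(bits[j, t + 1]) << j
        tot = 0.0
        for s in range(S):
            labels_for_bits(bits_table[s], parent_of_slot, meiosis_of_slot,
                            gene_of_slot, labels)
            ws = solve_site(labels, obs_t[t], p[t], uf, par, w0, w1)
            if ws > 0.0:
                if t > 0:
                    th = theta[t - 1]
                    h = popcnt[s ^ sl]
                    ws *= th**h * (1 - th) ** (m - h)
                if t < n_loci - 1:
                    th = theta[t]
                    h = popcnt[s ^ sr]
                    ws *= th**h * (1 - th) ** (m - h)
            w[s] = ws
            tot += ws
        r = np.random.random() * tot
        acc = 0.0
        chosen = S - 1
        for s in range(S):
            acc += w[s]
            if r < acc:
                chosen = s
                break
        for j in range(m):
            bits[j, t] = (chosen >> j) & 1


@njit(cache=True)
def founder_phase_flips(bits, flip_flat, flip_offsets):
    """Randomly swap founders' gene labels (global meiosis-row flips).

    Swapping a founder's two (exchangeable) genes flips the bits of every
    meiosis transmitting from that founder, at all loci at once.  The
    likelihood and the chain prior are invariant, so the move is always
    accepted; it hops between the founder-phase symmetry modes that
    locus-local moves cross only through vanishing-probability paths.
    """
    n_groups = flip_offsets.shape[0] - 1
    n_loci = bits.shape[1]
    for f in range(n_groups):
        if np.random.random() < 0.5:
            for k in range(flip_offsets[f], flip_offsets[f + 1]):
                j = flip_flat[k]
                for t in range(n_loci):
                    bits[j, t] ^= 1


@njit(cache=True)
def run_sweeps(bits, obs_t, p, theta, parent_of_slot, meiosis_of_slot,
               gene_of_slot, n_genes, n_sweeps, bits_table, popcnt,
               use_locus_gibbs, n_pair_updates, flip_flat, flip_offsets):
    m = bits.shape[0]
    for _ in range(n_sweeps):
        sweep_once(bits, obs_t, p, theta, parent_of_slot, meiosis_of_slot,
                   gene_of_slot, n_genes)
        for _ in range(n_pair_updates):
            j = np.random.randint(0, m)
            k = np.random.randint(0, m)
            if j != k:
                pair_update(bits, j, k, obs_t, p, theta, parent_of_slot,
                            meiosis_of_slot, gene_of_slot, n_genes)
        if use_locus_gibbs:
            locus_gibbs_pass(bits, obs_t, p, theta, parent_of_slot,
                             meiosis_of_slot, gene_of_slot, n_genes,
                             bits_table, popcnt)
        founder_phase_flips(bits, flip_flat, flip_offsets)


@njit(cache=True)
def collect_samples(bits, obs_t, p, theta, parent_of_slot, meiosis_of_slot,
                    gene_of_slot, n_genes, n_keep, thin, bits_table, popcnt,
                    use_locus_gibbs, n_pair_updates, flip_flat, flip_offsets,
                    out):
    for k in range(n_keep):
        run_sweeps(bits, obs_t, p, theta, parent_of_slot, meiosis_of_slot,
                   gene_of_slot, n_genes, thin, bits_table, popcnt,
                   use_locus_gibbs, n_pair_updates, flip_flat, flip_offsets)
        out[k, :, :] = bits


@njit(cache=True, inline="always")
def _interp_p0(bl, br, has_l, has_r, tl, tr):
    """P(dense bit = 0) from flanking framework bits via Haldane transitions."""
    if has_l and has_r:
        wl0 = (1 - tl) if bl == 0 else tl
        wl1 = tl if bl == 0 else (1 - tl)
        wr0 = (1 - tr) if br == 0 else tr
        wr1 = tr if br == 0 else (1 - tr)
        v0 = wl0 * wr0
        v1 = wl1 * wr1
        return v0 / (v0 + v1)
    if has_l:
        return (1 - tl) if bl == 0 else tl
    if has_r:
        return (1 - tr) if br == 0 else tr
    return 0.5


@njit(cache=True)
def impute_sites(bits_samples, left_idx, right_idx, theta_left, theta_right,
                 obs_t, p_dense, targets, parent_of_slot, meiosis_of_slot,
                 gene_of_slot, n_genes, k_dense):
    """Monte-Carlo posterior genotype estimation at dense sites.

    For every retained framework inheritance-vector sample, ``k_dense`` dense
    IVs are drawn per meiosis from the flank-conditional distribution; each
    draw is weighted by the likelihood of the observed donor genotypes given
    the implied descent partition, and genotype/slot posteriors for the
    target individuals are accumulated under those weights.
    """
    n_samp, m, _ = bits_samples.shape
    n_dense = left_idx.shape[0]
    nt = targets.shape[0]
    n2 = parent_of_slot.shape[0]

    gt_post = np.zeros((n_dense, nt, 3), np.float64)
    slot_post = np.zeros((n_dense, nt, 2), np.float64)
    zsum = np.zeros(n_dense, np.float64)

    bcol = np.empty(m, np.uint8)
    labels = np.empty(n2, np.int32)
    uf = np.empty(n_genes, np.int32)
    par = np.empty(n_genes, np.uint8)
    w0 = np.empty(n_genes, np.float64)
    w1 = np.empty(n_genes, np.float64)

    for d in range(n_dense):
        li = left_idx[d]
        ri = right_idx[d]
        tl = theta_left[d]
        tr = theta_right[d]
        for s in range(n_samp):
            for _ in range(k_dense):
                for j in range(m):
                    bl = bits_samples[s, j, li] if li >= 0 else 0
                    br = bits_samples[s, j, ri] if ri >= 0 else 0
                    p0 = _interp_p0(bl, br, li >= 0, ri >= 0, tl, tr)
                    bcol[j] = 0 if np.random.random() < p0 else 1
                labels_for_bits(bcol, parent_of_slot, meiosis_of_slot,
                                gene_of_slot, labels)
                z = solve_site(labels, obs_t[d], p_dense[d], uf, par, w0, w1)
                if z > 0.0:
                    accumulate_targets(labels, targets, uf, par, w0, w1,
                                       gt_post[d], slot_post[d], z)
                    zsum[d] += z
    return gt_post, slot_post, zsum
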