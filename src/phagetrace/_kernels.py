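"""Numba inner loops: banded affine local alignment, ungapped diagonal
scoring, six-frame translation and PSSM placement scans.

Nucleotides are encoded A=0, C=1, G=2, T=3, ambiguous=4 (never matches).
Amino acids are encoded by :data:`phagetrace.markers.AA_ORDER`; 20 is an
unknown residue (scores 0 against every profile column), 21 is a stop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def best_ungapped_segment(read, ref, diag, match, mismatch):
    """Best-scoring contiguous ungapped segment on one diagonal (Kadane).

    ``diag`` is ref_pos - read_pos. Returns (score, read_start, read_end)
    with half-open read coordinates; score 0 means no positive segment.
    """
    n = read.shape[0]
    m = ref.shape[0]
    best = 0
    best_s = 0
    best_e = 0
    cur = 0
    cur_s = 0
    for i in range(n):
        j = i + diag
        if j < 0 or j >= m:
            cur = 0
            cur_s = i + 1
            continue
        a = read[i]
        b = ref[j]
        s = match if (a == b and a < 4) else mismatch
        if cur <= 0:
            cur = s
            cur_s = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_s = cur_s
            best_e = i + 1
    return best, best_s, best_e


@njit(cache=True)
def banded_gotoh(read, ref, d0, halfw, match, mismatch, gap_open, gap_ext):
    """Local affine-gap alignment restricted to a band around diagonal d0.

    Band covers ref positions j = i + d0 + (k - halfw) for k in [0, 2*halfw].
    Gap of length g costs gap_open + g*gap_ext. Returns
    (score, matches, columns, read_start, read_end, ref_start, ref_end),
    half-open coordinates; score 0 -> no alignment.
    """
    n = read.shape[0]
    m = ref.shape[0]
    w = 2 * halfw + 1

    H = np.full((n + 1, w), NEG, dtype=np.int64)
    E = np.full((n + 1, w), NEG, dtype=np.int64)
    F = np.full((n + 1, w), NEG, dtype=np.int64)
    # pointers: in H 0=stop,1=diag,2=from E,3=from F; in E/F 1 means extend
    PH = np.zeros((n + 1, w), dtype=np.int8)
    PE = np.zeros((n + 1, w), dtype=np.int8)
    PF = np.zeros((n + 1, w), dtype=np.int8)

    for k in range(w):
        j = 0 + d0 + (k - halfw)
        if 0 <= j <= m:
            H[0, k] = 0

    best = 0
    bi = 0
    bk = 0
    for i in range(1, n + 1):
        for k in range(w):
            j = i + d0 + (k - halfw)
            if j < 0 or j > m:
                continue
            # E: gap in read, consumes ref[j-1]; predecessor (i, j-1) = k-1
            e = NEG
            pe = 0
            if j >= 1 and k >= 1:
                ho = H[i, k - 1] - gap_open - gap_ext
                ee = E[i, k - 1] - gap_ext
                if ee > ho:
                    e = ee
                    pe = 1
                else:
                    e = ho
            E[i, k] = e
            PE[i, k] = pe
            # F: gap in ref, consumes read[i-1]; predecessor (i-1, j) = k+1
            f = NEG
            pf = 0
            if k + 1 < w:
                ho = H[i - 1, k + 1] - gap_open - gap_ext
                ff = F[i - 1, k + 1] - gap_ext
                if ff > ho:
                    f = ff
                    pf = 1
                else:
                    f = ho
            F[i, k] = f
            PF[i, k] = pf
            # H
            h = 0
            ph = 0
            if j >= 1 and H[i - 1, k] > NEG // 2:
                a = read[i - 1]
                b = ref[j - 1]
                s = match if (a == b and a < 4) else mismatch
                d = H[i - 1, k] + s
                if d > h:
                    h = d
                    ph = 1
            if e > h:
                h = e
                ph = 2
            if f > h:
                h = f
                ph = 3
            H[i, k] = h
            PH[i, k] = ph
            if h > best:
                best = h
                bi = i
                bk = k

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback
    i = bi
    k = bk
    state = 0  # 0=H, 1=E, 2=F
    matches = 0
    cols = 0
    read_e = bi
    ref_e = bi + d0 + (bk - halfw)
    while True:
        j = i + d0 + (k - halfw)
        if state == 0:
            p = PH[i, k]
            if p == 0:
                break
            elif p == 1:
                a = read[i - 1]
                b = ref[j - 1]
                if a == b and a < 4:
                    matches += 1
                cols += 1
                i -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            # consumed ref[j-1] against a gap
            cols += 1
            cont = PE[i, k]
            k -= 1
            if cont == 0:
                state = 0
        else:
            cols += 1
            cont = PF[i, k]
            i -= 1
            k += 1
            if cont == 0:
                state = 0
    read_s = i
    ref_s = i + d0 + (k - halfw)
    return best, matches, cols, read_s, read_e, ref_s, ref_e


@njit(cache=True)
def collect_seed_diagonals(codes, k, skmer, sref, spos):
    """Vote (ref, diagonal) pairs sharing exact k-mer seeds with a read.

    ``skmer`` is the sorted packed-k-mer array of the reference index with
    parallel ``sref``/``spos``. Returns (ref_idx, diag, votes) sorted by
    descending vote count (stable).
    """
    n = codes.shape[0]
    empty = np.empty(0, dtype=np.int64)
    if n < k:
        return empty, empty, empty
    mask = np.int64(1) << np.int64(2 * k)
    val = np.int64(0)
    bad = 0
    lo_list = np.empty(n - k + 1, dtype=np.int64)
    hi_list = np.empty(n - k + 1, dtype=np.int64)
    qp_list = np.empty(n - k + 1, dtype=np.int64)
    nq = 0
    total = 0
    for i in range(n):
        c = codes[i]
        if c > 3:
            bad = k
            val = (val * 4) % mask
        else:
            val = (val * 4 + c) % mask
            if bad > 0:
                bad -= 1
        if i >= k - 1 and bad == 0:
            lo = np.searchsorted(skmer, val, side="left")
            hi = np.searchsorted(skmer, val, side="right")
            if hi > lo:
                lo_list[nq] = lo
                hi_list[nq] = hi
                qp_list[nq] = i - (k - 1)
                nq += 1
                total += hi - lo
    if total == 0:
        return empty, empty, empty
    keys = np.empty(total, dtype=np.int64)
    t = 0
    for q in range(nq):
        qpos = qp_list[q]
        for idx in range(lo_list[q], hi_list[q]):
            diag = spos[idx] - qpos
            keys[t] = sref[idx] * (np.int64(1) << 33) + (diag + (np.int64(1) << 31))
            t += 1
    keys = np.sort(keys[:t])
    # run-length encode
    nunique = 1
    for i in range(1, t):
        if keys[i] != keys[i - 1]:
            nunique += 1
    ukey = np.empty(nunique, dtype=np.int64)
    votes = np.empty(nunique, dtype=np.int64)
    u = 0
    run = 1
    for i in range(1, t + 1):
        if i == t or keys[i] != keys[i - 1]:
            ukey[u] = keys[i - 1]
            votes[u] = run
            u += 1
            run = 1
        else:
            run += 1
    order = np.argsort(-votes, kind="mergesort")
    ukey = ukey[order]
    votes = votes[order]
    refs = ukey >> 33
    diags = (ukey & ((np.int64(1) << 33) - 1)) - (np.int64(1) << 31)
    return refs, diags, votes


@njit(cache=True)
def revcomp_codes(codes):
    n = codes.shape[0]
    out = np.empty(n, dtype=codes.dtype)
    for i in range(n):
        c = codes[n - 1 - i]
        out[i] = 3 - c if c < 4 else 4
    return out


@njit(cache=True)
def translate_frame(codes, frame, codon_aa):
    """Translate one forward frame of nucleotide codes to aa codes."""
    n = (codes.shape[0] - frame) // 3
    aa = np.empty(n, dtype=np.int8)
    for c in range(n):
        b0 = codes[frame + 3 * c]
        b1 = codes[frame + 3 * c + 1]
        b2 = codes[frame + 3 * c + 2]
        if b0 > 3 or b1 > 3 or b2 > 3:
            aa[c] = 20
        else:
            aa[c] = codon_aa[b0 * 16 + b1 * 4 + b2]
    return aa


@njit(cache=True)
def pssm_best_placement(pssm, seg, min_overlap):
    """Best local (contiguous) match of an aa segment against a PSSM.

    For each diagonal offset the best-scoring contiguous run of columns
    is found (Kadane), so unrelated residues flanking a marker fragment
    never penalise the match — the behaviour of local profile search.
    ``pssm`` has shape (W, 21); column 20 scores 0 (unknown residue).
    Returns (score, offset, match_start, match_len) where profile column
    offset + i aligns segment residue i; match_start/len are in segment
    coordinates.
    """
    W = pssm.shape[0]
    s = seg.shape[0]
    best = -1e30
    bp = 0
    bstart = 0
    blen = 0
    for p in range(-(s - min_overlap), W - min_overlap + 1):
        i0 = 0 if p >= 0 else -p
        i1 = s if p + s <= W else W - p
        cur = 0.0
        cur_s = i0
        for i in range(i0, i1):
            v = pssm[p + i, seg[i]]
            if cur <= 0.0:
                cur = v
                cur_s = i
            else:
                cur += v
            if cur > best:
                best = cur
                bp = p
                bstart = cur_s
                blen = i + 1 - cur_s
    return best, bp, bstart, blen


@njit(cache=True)
def search_frames_best(codes, pssm, codon_aa, min_seg):
    """Scan all six reading frames of a read against a PSSM.

    Segments are maximal stop-free stretches of >= min_seg residues,
    scored with local placement (see :func:`pssm_best_placement`).
    Returns (best_score, strand, frame, seg_start, seg_len, offset,
    match_start, match_len); strand 0 forward / 1 reverse, frame in
    [0,3), seg_start in aa coordinates of that frame, match_start/len in
    segment coordinates. best_score is -1e30 when nothing scorable.
    """
    best = -1e30
    b_strand = -1
    b_frame = -1
    b_start = 0
    b_len = 0
    b_place = 0
    b_ms = 0
    b_ml = 0
    for strand in range(2):
        sc = codes if strand == 0 else revcomp_codes(codes)
        for frame in range(3):
            aa = translate_frame(sc, frame, codon_aa)
            n = aa.shape[0]
            start = 0
            for c in range(n + 1):
                if c == n or aa[c] == 21:
                    seg_len = c - start
                    if seg_len >= min_seg:
                        score, place, ms, ml = pssm_best_placement(
                            pssm, aa[start:c], min_seg
                        )
                        if score > best:
                            best = score
                            b_strand = strand
                            b_frame = frame
                            b_start = start
                            b_len = seg_len
                            b_place = place
                            b_ms = ms
                            b_ml = ml
                    start = c + 1
    return best, b_strand, b_frame, b_start, b_len, b_place, b_ms, b_ml
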