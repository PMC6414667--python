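"""Exhaustive local alignment reference implementation.

A full-matrix Smith-Waterman with affine (Gotoh) gaps, vectorised row by
row with numpy and integer scores. It is deliberately independent of the
seed-and-extend production aligner in :mod:`phagetrace.recruitment` and is
used to validate it on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recruitment import encode_nt


@dataclass
class OracleAlignment:
    score: int
    matches: int
    columns: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def smith_waterman_affine(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_ext: int = 2,
) -> OracleAlignment | None:
    """Best local alignment by exhaustive dynamic programming.

    A gap of length g costs gap_open + g*gap_ext; gap columns count as
    non-matches in percent identity. Returns None when no cell scores > 0.
    """
    q = encode_nt(query).astype(np.int16)
    t = encode_nt(target).astype(np.int16)
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        return None
    NEG = np.int64(-(10**9))

    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)

    valid_t = t < 4
    for i in range(1, n + 1):
        sub = np.where((t == q[i - 1]) & valid_t & (q[i - 1] < 4), match, mismatch)
        F[i, 1:] = np.maximum(H[i - 1, 1:] - gap_open - gap_ext, F[i - 1, 1:] - gap_ext)
        htmp = np.maximum(H[i - 1, :-1] + sub, F[i, 1:])
        htmp = np.maximum(htmp, 0)
        # E[i,j] = max_{l<j} htmp[l] - gap_open - (j-l)*gap_ext, computed
        # by a prefix max (opening from a cell that itself ends in a
        # horizontal gap is always dominated).
        j_idx = np.arange(1, m + 1, dtype=np.int64)
        aug = np.concatenate(([NEG], htmp[:-1] + j_idx[:-1] * gap_ext))
        E[i, 1:] = np.maximum.accumulate(aug) - gap_open - j_idx * gap_ext
        H[i, 1:] = np.maximum(htmp, E[i, 1:])

    best = int(H.max())
    if best <= 0:
        return None
    bi, bj = np.unravel_index(int(H.argmax()), H.shape)

    # traceback by re-checking which move attains each stored value
    i, j = int(bi), int(bj)
    state = "H"
    matches = 0
    cols = 0
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4 and t[j - 1] < 4) else mismatch
            if i >= 1 and j >= 1 and h == H[i - 1, j - 1] + s:
                if s == match:
                    matches += 1
                cols += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("inconsistent traceback")
        elif state == "E":
            e = E[i, j]
            cols += 1
            if e == H[i, j - 1] - gap_open - gap_ext:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:
            f = F[i, j]
            cols += 1
            if f == H[i - 1, j] - gap_open - gap_ext:
                i -= 1
                state = "H"
            else:
                i -= 1
    return OracleAlignment(
        score=best,
        matches=matches,
        columns=cols,
        query_start=i,
        query_end=int(bi),
        target_start=j,
        target_end=int(bj),
    )
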