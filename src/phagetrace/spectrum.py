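"""Percent-identity recruitment spectra, population-structure calls and
conserved-island detection.

A recruitment histogram collects aligned bases into 1-point identity bins
over [70, 100]. Its shape separates population structures: near-clonal
populations recruit almost exclusively at 98-100% identity, a genomic
continuum spreads recruitment over a broad identity range, and discrete
clouds leave a gap in the high-identity region. Short conserved islands
recruit deeply at high identity while the rest of the replicon does not,
which biases plain mean coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .recruitment import AlignmentHit, CoverageProfile

logger = logging.getLogger(__name__)

BIN_LO = 70
BIN_HI = 100
N_BINS = BIN_HI - BIN_LO  # 1-point bins, top bin [99, 100] closed


@dataclass
class IdentityHistogram:
    ref_id: str
    sample_id: str
    weights: np.ndarray  # aligned bases per bin
    counts: np.ndarray  # hits per bin
    n_excluded: int = 0

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def bin_edges(self) -> np.ndarray:
        return np.arange(BIN_LO, BIN_HI + 1)


@dataclass
class SpectrumClass:
    label: str  # 'clonal' | 'continuum' | 'gapped' | 'sparse'
    frac_ge98: float
    frac_90_97: float
    occupied_span: int
    gap_intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SpectrumParams:
    """Quantitative rendering of the qualitative spectrum descriptions."""

    clonal_min_high: float = 0.50  # weight fraction in [98, 100]
    clonal_max_mid: float = 0.10  # weight fraction in [90, 97)
    occupancy: float = 0.01  # a bin is occupied at >= 1% of weight
    gap_min_bins: int = 3  # gap of >= 3 empty bins within [88, 98]
    gap_window: tuple[int, int] = (88, 98)
    continuum_min_span: int = 10  # >= 10 consecutive points within [80, 98]
    continuum_window: tuple[int, int] = (80, 98)
    continuum_max_gap: int = 1  # no internal gap of >= 2 bins


@dataclass
class ConservedIsland:
    ref_id: str
    start: int  # 0-based half-open
    end: int
    island_mean_depth: float
    background_depth: float
    enrichment: float
    median_identity: float


def identity_histogram(
    hits: list[AlignmentHit], ref_id: str, sample_id: str = ""
) -> IdentityHistogram:
    """Each hit adds its aligned length to the 1-point bin holding its
    percent identity (bin [b, b+1); top bin [99, 100] closed). Hits below
    70% are excluded and counted."""
    weights = np.zeros(N_BINS)
    counts = np.zeros(N_BINS, dtype=int)
    excluded = 0
    for h in hits:
        if h.ref_id != ref_id:
            continue
        if h.percent_identity < BIN_LO:
            excluded += 1
            continue
        b = min(int(np.floor(h.percent_identity)) - BIN_LO, N_BINS - 1)
        weights[b] += h.aligned_length
        counts[b] += 1
    if excluded:
        logger.info("identity_histogram(%s): excluded %d hits below %d%%", ref_id, excluded, BIN_LO)
    return IdentityHistogram(
        ref_id=ref_id, sample_id=sample_id, weights=weights, counts=counts, n_excluded=excluded
    )


def _occupied(hist: IdentityHistogram, params: SpectrumParams) -> np.ndarray:
    total = hist.total_weight
    return hist.weights >= params.occupancy * total


def classify_spectrum(
    hist: IdentityHistogram, params: SpectrumParams | None = None
) -> SpectrumClass:
    """Label a spectrum clonal, gapped, continuum or sparse.

    clonal: >= 50% of weight at [98, 100] and <= 10% in [90, 97).
    gapped: two occupied regions separated by >= 3 unoccupied bins
    falling within [88, 98]. continuum: occupied bins spanning >= 10
    consecutive points within [80, 98] with no internal gap of >= 2 bins.
    Precedence clonal > gapped > continuum; anything else is sparse.
    """
    params = params or SpectrumParams()
    total = hist.total_weight
    if total <= 0:
        return SpectrumClass("sparse", 0.0, 0.0, 0)

    frac_hi = float(hist.weights[98 - BIN_LO :].sum() / total)
    frac_mid = float(hist.weights[90 - BIN_LO : 97 - BIN_LO].sum() / total)
    occ = _occupied(hist, params)
    occ_idx = np.flatnonzero(occ)
    span = int(occ_idx[-1] - occ_idx[0] + 1) if len(occ_idx) else 0

    # maximal unoccupied runs flanked by occupied bins on both sides
    gaps: list[tuple[int, int]] = []
    if len(occ_idx) >= 2:
        for a, b in zip(occ_idx[:-1], occ_idx[1:]):
            if b - a > 1:
                gaps.append((int(a) + 1 + BIN_LO, int(b) + BIN_LO))  # [start, end) in % points

    if frac_hi >= params.clonal_min_high and frac_mid <= params.clonal_max_mid:
        return SpectrumClass("clonal", frac_hi, frac_mid, span, gaps)

    wlo, whi = params.gap_window
    for gs, ge in gaps:
        inside = min(ge, whi) - max(gs, wlo)
        if ge - gs >= params.gap_min_bins and inside >= params.gap_min_bins:
            return SpectrumClass("gapped", frac_hi, frac_mid, span, gaps)

    clo, chi = params.continuum_window
    w0, w1 = clo - BIN_LO, chi - BIN_LO
    best_run = 0
    run_start = None
    i = w0
    while i < w1:
        if occ[i]:
            if run_start is None:
                run_start = i
            i += 1
            continue
        # allow internal gaps of <= continuum_max_gap bins
        g = 0
        j = i
        while j < w1 and not occ[j]:
            g += 1
            j += 1
        if run_start is not None and g <= params.continuum_max_gap and j < w1:
            i = j
            continue
        if run_start is not None:
            best_run = max(best_run, i - run_start)
        run_start = None
        i = j
    if run_start is not None:
        best_run = max(best_run, w1 - run_start)
    if best_run >= params.continuum_min_span:
        return SpectrumClass("continuum", frac_hi, frac_mid, span, gaps)
    return SpectrumClass("sparse", frac_hi, frac_mid, span, gaps)


def detect_islands(
    profile: CoverageProfile,
    hits: list[AlignmentHit] | None = None,
    window: int = 500,
    enrichment: float = 5.0,
    max_island_frac: float = 0.10,
) -> list[ConservedIsland]:
    """Sliding-window scan (step window/2) for short high-coverage
    regions. Windows with mean depth >= enrichment x the median contig
    depth (median over all positions; mean of nonzero positions when the
    median is 0) merge into maximal intervals; intervals longer than
    max_island_frac x L are discarded. Each island is annotated with its
    enrichment ratio and the median identity of overlapping hits."""
    depth = np.asarray(profile.depth, dtype=float)
    L = len(depth)
    if L < window:
        raise ValueError("profile shorter than the window")
    background = float(np.median(depth))
    if background == 0:
        nz = depth[depth > 0]
        background = float(nz.mean()) if len(nz) else 0.0
    if background == 0:
        return []
    step = max(1, window // 2)
    starts = list(range(0, L - window + 1, step))
    if starts[-1] + window < L:
        starts.append(L - window)
    csum = np.concatenate([[0.0], np.cumsum(depth)])
    intervals = []
    for s in starts:
        mean = (csum[s + window] - csum[s]) / window
        if mean >= enrichment * background:
            intervals.append((s, s + window))
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if (e - s) > max_island_frac * L:
            continue
        island_mean = float(depth[s:e].mean())
        ids = [
            h.percent_identity
            for h in (hits or [])
            if h.ref_id == profile.ref_id and h.ref_start < e and h.ref_end > s
        ]
        out.append(
            ConservedIsland(
                ref_id=profile.ref_id,
                start=int(s),
                end=int(e),
                island_mean_depth=island_mean,
                background_depth=background,
                enrichment=island_mean / background,
                median_identity=float(np.median(ids)) if ids else float("nan"),
            )
        )
    return out
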