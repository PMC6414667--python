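"""Marker-gene read partitioning (psbA / PS-II D1, Gp23).

Reads are translated in all six frames and scanned against a
position-specific scoring matrix built from an aligned, group-labelled
marker-protein reference set. The acceptance threshold is calibrated
empirically on random-sequence null reads. Accepted reads are assigned
to the taxon group of their highest-identity reference at the matched
profile columns, giving per-sample expression partitions such as the
viral (T4-like + T7-like) share of total cyanobacterial + cyanophage
psbA, the T4-like : cyanobacteria expression ratio r, and the derived
infected-fraction estimate I = r / (r + alpha), where alpha is the
per-cell expression of the viral marker relative to the host one.

The profile is an ungapped PSSM (not a full profile HMM) and the
threshold an empirical quantile rather than an analytic E-value; both
are deliberate simplifications, calibrated and tested as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import search_frames_best
from .recruitment import encode_nt

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_CODE = np.full(256, 20, dtype=np.int8)
for _i, _a in enumerate(AA_ORDER):
    AA_CODE[ord(_a)] = _i
    AA_CODE[ord(_a.lower())] = _i
GAP_CODE = -1
STOP_CODE = 21

HOST_GROUPS = ("cyano_synechococcus", "cyano_prochlorococcus")
T4_GROUP = "T4like"
T7_GROUP = "T7like"


def _codon_table() -> np.ndarray:
    """64-entry codon -> aa-code table (standard code; stop = 21)."""
    from Bio.Data.CodonTable import standard_dna_table

    tab = np.full(64, 20, dtype=np.int8)
    code = {b: i for i, b in enumerate("ACGT")}
    for codon, aa in standard_dna_table.forward_table.items():
        tab[code[codon[0]] * 16 + code[codon[1]] * 4 + code[codon[2]]] = AA_CODE[ord(aa)]
    for codon in standard_dna_table.stop_codons:
        tab[code[codon[0]] * 16 + code[codon[1]] * 4 + code[codon[2]]] = STOP_CODE
    return tab


CODON_AA = _codon_table()


@dataclass
class MarkerReferenceSet:
    """Aligned marker proteins with per-sequence taxon-group labels."""

    ids: list[str]
    sequences: list[str]  # aligned; '-' for gaps
    labels: dict  # id -> group

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("reference sequences are not aligned (unequal lengths)")
        if len(set(self.labels.values())) < 2:
            raise ValueError("need at least two taxon groups")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.labels.values()))


@dataclass
class ProfileModel:
    """Per-column amino-acid log-odds profile plus the aligned references
    restricted to the kept columns (for nearest-reference assignment)."""

    pssm: np.ndarray  # (W, 21) float64; column 20 (unknown aa) scores 0
    kept_columns: np.ndarray
    ref_ids: list[str]
    ref_groups: list[str]
    ref_matrix: np.ndarray  # (n_refs, W) int8, -1 at gaps
    pseudocount: float
    threshold: float | None = None
    calibration_read_length: int | None = None

    @property
    def width(self) -> int:
        return self.pssm.shape[0]


def build_profile(
    refs: MarkerReferenceSet,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    max_gap_frac: float = 0.5,
) -> ProfileModel:
    """PSSM over the alignment: per column, score(aa) =
    log2(((count + pc) / (N + 20*pc)) / background(aa)); background is
    uniform 1/20 by default. Columns with > max_gap_frac gaps drop out.
    """
    if len(refs.ids) < 5:
        raise ValueError("need >= 5 aligned references to build a profile")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    n, W0 = len(refs.sequences), refs.n_columns
    mat = np.full((n, W0), GAP_CODE, dtype=np.int8)
    for i, seq in enumerate(refs.sequences):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gap = (arr == ord("-")) | (arr == ord("."))
        codes = AA_CODE[arr]
        mat[i] = np.where(is_gap, GAP_CODE, codes)
    gap_frac = (mat == GAP_CODE).mean(axis=0)
    kept = np.flatnonzero(gap_frac <= max_gap_frac)
    mat = mat[:, kept]
    W = len(kept)
    pssm = np.zeros((W, 21))
    for c in range(W):
        col = mat[:, c]
        counts = np.bincount(col[(col >= 0) & (col < 20)], minlength=20)
        freqs = (counts + pseudocount) / (n + 20.0 * pseudocount)
        pssm[c, :20] = np.log2(freqs / background)
    order = np.argsort(refs.ids)
    return ProfileModel(
        pssm=pssm,
        kept_columns=kept,
        ref_ids=[refs.ids[i] for i in order],
        ref_groups=[refs.labels[refs.ids[i]] for i in order],
        ref_matrix=mat[order],
        pseudocount=pseudocount,
    )


def calibrate_threshold(
    profile: ProfileModel,
    read_length: int = 200,
    n_null: int = 10000,
    target_fpr: float = 1e-3,
    seed: int = 0,
    min_codons: int = 10,
) -> float:
    """Score threshold at the (1 - target_fpr) quantile of best-frame
    scores of random background reads of the configured length."""
    rng = np.random.default_rng([seed, 0x0F9])
    scores = np.empty(n_null)
    for i in range(n_null):
        codes = rng.integers(0, 4, size=read_length).astype(np.int8)
        best = search_frames_best(codes, profile.pssm, CODON_AA, min_codons)[0]
        scores[i] = best if best > -1e29 else -np.inf
    finite = scores[np.isfinite(scores)]
    if len(finite) == 0:
        raise ValueError("no null read produced a scorable segment")
    threshold = float(np.quantile(finite, 1.0 - target_fpr))
    profile.threshold = threshold
    profile.calibration_read_length = read_length
    return threshold


@dataclass
class MarkerAssignment:
    """One accepted marker read: frame, profile score and group call."""

    read_id: str
    sample_id: str
    frame: int  # 1-3 forward, 4-6 reverse
    score: float
    group: str | None = None
    nearest_ref: str | None = None
    identity: float = 0.0
    placement: int = 0  # profile column aligned to the first matched residue
    segment: np.ndarray | None = field(default=None, repr=False)  # matched residues


def search_reads(
    reads: list[tuple[str, str]],
    profile: ProfileModel,
    sample_id: str = "",
    min_codons: int = 10,
) -> list[MarkerAssignment]:
    """Six-frame PSSM scan; keep the best placement of each read when it
    reaches the calibrated threshold. Reads without a stop-free segment
    of >= min_codons codons are skipped and counted."""
    if profile.threshold is None:
        raise ValueError("profile threshold not calibrated")
    out = []
    n_short = 0
    for rid, seq in reads:
        codes = encode_nt(seq)
        best, strand, frame, seg_start, seg_len, place, ms, ml = search_frames_best(
            codes, profile.pssm, CODON_AA, min_codons
        )
        if best < -1e29:
            n_short += 1
            continue
        if best < profile.threshold:
            continue
        seg = _frame_segment(codes, strand, frame, seg_start, seg_len)
        out.append(
            MarkerAssignment(
                read_id=rid,
                sample_id=sample_id,
                frame=int(frame) + 1 + (3 if strand == 1 else 0),
                score=float(best),
                placement=int(place) + int(ms),
                segment=seg[int(ms) : int(ms) + int(ml)],
            )
        )
    if n_short:
        logger.info("search_reads: %d reads without a %d-codon segment", n_short, min_codons)
    return out


def _frame_segment(codes, strand, frame, seg_start, seg_len) -> np.ndarray:
    from ._kernels import revcomp_codes, translate_frame

    c = revcomp_codes(codes) if strand == 1 else codes
    aa = translate_frame(c, int(frame), CODON_AA)
    return aa[int(seg_start) : int(seg_start) + int(seg_len)]


def assign_group(candidate: MarkerAssignment, profile: ProfileModel) -> MarkerAssignment:
    """Nearest-reference call at the matched profile columns.

    Identity = matching residues / non-gap reference columns in the
    placement window; ties go to the reference covering more columns,
    then to the lexicographically smallest reference id."""
    seg = candidate.segment
    s = min(len(seg), profile.width - candidate.placement)
    window = profile.ref_matrix[:, candidate.placement : candidate.placement + s]
    segv = seg[:s]
    nongap = window != GAP_CODE
    denom = nongap.sum(axis=1)
    matches = ((window == segv[None, :]) & nongap).sum(axis=1)
    identity = np.divide(
        matches, denom, out=np.zeros(len(denom), dtype=float), where=denom > 0
    )
    best = int(np.lexsort((-denom, -identity))[0])  # ref_ids pre-sorted: lex tie-break
    candidate.group = profile.ref_groups[best]
    candidate.nearest_ref = profile.ref_ids[best]
    candidate.identity = float(identity[best])
    return candidate


def classify_reads(
    reads: list[tuple[str, str]],
    profile: ProfileModel,
    sample_id: str = "",
    min_codons: int = 10,
) -> list[MarkerAssignment]:
    """search_reads + assign_group in one pass."""
    return [assign_group(c, profile) for c in search_reads(reads, profile, sample_id, min_codons)]


@dataclass
class PartitionResult:
    """Per-sample marker-expression partition."""

    sample_id: str
    counts: dict  # group -> reads
    fractions: dict  # over host + T4like + T7like groups
    viral_fraction: float
    t4_fraction: float
    viral_host_ratio: float  # T4like : cyanobacteria
    viral_host_ratio_with_t7: float
    infected_fraction_estimate: float
    flagged: str | None = None  # 'empty' | 'no_host_reads'


def infected_fraction(ratio: float, alpha: float = 1.0) -> float:
    """I = r / (r + alpha): the infected fraction implied by a viral:host
    marker expression ratio r under per-cell expression ratio alpha."""
    if ratio < 0 or alpha <= 0:
        raise ValueError("need ratio >= 0 and alpha > 0")
    return ratio / (ratio + alpha)


def partition(
    assignments: list[MarkerAssignment],
    sample_id: str = "",
    host_groups: tuple[str, ...] = HOST_GROUPS,
    t4_group: str = T4_GROUP,
    t7_group: str = T7_GROUP,
    alpha: float = 1.0,
) -> PartitionResult:
    """Group counts and the headline fractions for one sample.

    Fractions are taken over host + T4-like + T7-like assignments; the
    viral:host ratio is T4-like / (sum of host groups), undefined
    (flagged) when no host reads were seen."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.group is None:
            raise ValueError("assignments must be group-assigned first")
        counts[a.group] = counts.get(a.group, 0) + 1
    part_groups = list(host_groups) + [t4_group, t7_group]
    total = sum(counts.get(g, 0) for g in part_groups)
    host = sum(counts.get(g, 0) for g in host_groups)
    t4 = counts.get(t4_group, 0)
    t7 = counts.get(t7_group, 0)
    if total == 0:
        return PartitionResult(
            sample_id=sample_id, counts=counts, fractions={g: 0.0 for g in part_groups},
            viral_fraction=0.0, t4_fraction=0.0, viral_host_ratio=0.0,
            viral_host_ratio_with_t7=0.0, infected_fraction_estimate=0.0, flagged="empty",
        )
    fractions = {g: counts.get(g, 0) / total for g in part_groups}
    flagged = None
    if host == 0:
        ratio = float("inf") if t4 else 0.0
        ratio7 = float("inf") if (t4 + t7) else 0.0
        flagged = "no_host_reads"
        est = 1.0 if t4 else 0.0
    else:
        ratio = t4 / host
        ratio7 = (t4 + t7) / host
        est = infected_fraction(ratio, alpha)
    return PartitionResult(
        sample_id=sample_id,
        counts=counts,
        fractions=fractions,
        viral_fraction=(t4 + t7) / total,
        t4_fraction=t4 / total,
        viral_host_ratio=ratio,
        viral_host_ratio_with_t7=ratio7,
        infected_fraction_estimate=est,
        flagged=flagged,
    )


def gp23_partition(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    gp23_refs: MarkerReferenceSet,
    read_length: int = 200,
    target_fpr: float = 1e-3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample group fractions of Gp23 (major capsid) transcripts,
    e.g. cyanophage vs. heterophage T4-like. Same profile machinery as
    psbA with a Gp23 reference set. Samples without accepted reads are
    flagged with NaN fractions."""
    profile = build_profile(gp23_refs)
    calibrate_threshold(profile, read_length=read_length, target_fpr=target_fpr, seed=seed)
    groups = gp23_refs.groups
    rows = {}
    for sample, reads in sorted(reads_by_sample.items()):
        assigns = classify_reads(reads, profile, sample)
        counts = {g: 0 for g in groups}
        for a in assigns:
            counts[a.group] = counts.get(a.group, 0) + 1
        total = sum(counts.values())
        if total == 0:
            rows[sample] = {g: float("nan") for g in groups}
        else:
            rows[sample] = {g: counts[g] / total for g in groups}
    return pd.DataFrame.from_dict(rows, orient="index")[groups]
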