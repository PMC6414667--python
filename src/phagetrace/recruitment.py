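"""Read recruitment: reference filtering, a seed-and-extend local
aligner, import of external alignments (SAM / 12-column tabular), and
per-position coverage.

The built-in aligner finds exact k-mer seeds, scores the best ungapped
segment on candidate diagonals and refines the best candidate with a
banded affine-gap (Gotoh) extension (match +1, mismatch -2, gap open 5,
gap extend 2). Percent identity counts gap columns as non-matches.
Internal coordinates are 0-based half-open; TSV outputs are 1-based
inclusive and say so in their headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import (
    banded_gotoh,
    best_ungapped_segment,
    collect_seed_diagonals,
    revcomp_codes,
)

logger = logging.getLogger(__name__)

_NT_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i

MATCH = 1
MISMATCH = -2
GAP_OPEN = 5
GAP_EXT = 2


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A0 C1 G2 T3, other 4)."""
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignmentHit:
    """One read-to-reference local alignment."""

    read_id: str
    ref_id: str
    ref_start: int  # 0-based half-open
    ref_end: int
    aligned_length: int  # alignment columns, gaps included
    percent_identity: float
    score: float
    strand: str  # '+' or '-'

    def __post_init__(self):
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(f"bad hit coordinates {self.ref_start}..{self.ref_end}")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")


@dataclass
class RecruitmentParams:
    """Recruitment filters; hit-length minima follow the molecule type."""

    min_hit_len_dna: int = 100
    min_hit_len_rna: int = 200
    min_identity: float = 70.0
    seed_kmer: int = 15
    best_hit_only: bool = True
    min_ref_len: int = 5000
    band_halfwidth: int = 8
    max_candidate_diagonals: int = 8

    def __post_init__(self):
        if min(self.min_hit_len_dna, self.min_hit_len_rna) < self.seed_kmer:
            raise ValueError("minimum hit lengths must be >= seed_kmer")
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity outside [0, 100]")

    def min_hit_len(self, molecule: str) -> int:
        if molecule.upper() == "DNA":
            return self.min_hit_len_dna
        if molecule.upper() == "RNA":
            return self.min_hit_len_rna
        raise ValueError(f"unknown molecule {molecule!r}")


@dataclass
class CoverageProfile:
    """Per-position read depth along one reference in one sample."""

    ref_id: str
    depth: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)


def filter_references(
    sequences: dict[str, str] | list[tuple[str, str]], min_ref_len: int = 5000
) -> dict[str, str]:
    """Keep references strictly longer than ``min_ref_len``, order preserved."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    kept = {name: seq for name, seq in items if len(seq) > min_ref_len}
    if not kept:
        logger.warning("filter_references: no reference longer than %d bp", min_ref_len)
    return kept


class ReferenceIndex:
    """Exact k-mer index over a reference set (sorted-array postings)."""

    def __init__(self, refs: dict[str, str], k: int = 15):
        self.k = k
        self.ref_ids = sorted(refs)  # lexicographic: stable tie-break order
        self.seqs = [refs[r] for r in self.ref_ids]
        self.codes = [encode_nt(s) for s in self.seqs]
        km_parts, ref_parts, pos_parts = [], [], []
        for ri, codes in enumerate(self.codes):
            if len(codes) < k:
                continue
            kmers = _rolling_kmers(codes, k)
            keep = kmers >= 0
            km_parts.append(kmers[keep])
            pos_parts.append(np.flatnonzero(keep).astype(np.int64))
            ref_parts.append(np.full(int(keep.sum()), ri, dtype=np.int64))
        if km_parts:
            km = np.concatenate(km_parts)
            order = np.argsort(km, kind="stable")
            self._kmers = km[order]
            self._refs = np.concatenate(ref_parts)[order]
            self._pos = np.concatenate(pos_parts)[order]
        else:
            self._kmers = np.empty(0, dtype=np.int64)
            self._refs = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)

    def seed_diagonals(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vote (ref_idx, diagonal) pairs hit by exact k-mer seeds.

        Returns (ref_idx, diag, votes) sorted by descending votes.
        """
        return collect_seed_diagonals(codes, self.k, self._kmers, self._refs, self._pos)


def _rolling_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack each k-mer into an integer; -1 where ambiguous bases occur."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    val = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for off in range(k):
        win = c[off : off + n]
        val = val * 4 + np.where(win < 4, win, 0)
        bad |= win >= 4
    val[bad] = -1
    return val


def _align_one(
    codes: np.ndarray,
    strand: str,
    index: ReferenceIndex,
    params: RecruitmentParams,
) -> list[tuple[float, str, AlignmentHit]]:
    """Candidate hits for one orientation of one read."""
    ref_idx, diags, _ = index.seed_diagonals(codes)
    if len(ref_idx) == 0:
        return []
    # pick leading diagonals, skipping ones inside an already-chosen band
    chosen: list[tuple[int, int]] = []
    for ri, d in zip(ref_idx.tolist(), diags.tolist()):
        if len(chosen) >= params.max_candidate_diagonals:
            break
        if any(cri == ri and abs(cd - d) <= params.band_halfwidth for cri, cd in chosen):
            continue
        chosen.append((ri, d))
    # cheap ungapped pre-score; the banded DP only refines the leaders
    scored = []
    for ri, d in chosen:
        ug, _, _ = best_ungapped_segment(codes, index.codes[ri], d, MATCH, MISMATCH)
        scored.append((int(ug), ri, d))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    top = scored[0][0]
    refine = [t for t in scored[:3] if t[0] >= top - 40] if params.best_hit_only else scored
    out = []
    for _, ri, d in refine:
        ref_codes = index.codes[ri]
        score, matches, cols, rs, re_, ts, te = banded_gotoh(
            codes, ref_codes, d, params.band_halfwidth, MATCH, MISMATCH, GAP_OPEN, GAP_EXT
        )
        if score <= 0 or cols == 0:
            continue
        pid = 100.0 * matches / cols
        hit = AlignmentHit(
            read_id="",
            ref_id=index.ref_ids[ri],
            ref_start=int(ts),
            ref_end=int(te),
            aligned_length=int(cols),
            percent_identity=pid,
            score=float(score),
            strand=strand,
        )
        out.append((float(score), index.ref_ids[ri], hit))
    return out


def align_reads(
    reads: list[tuple[str, str]],
    refs: dict[str, str],
    params: RecruitmentParams | None = None,
    molecule: str = "DNA",
    index: ReferenceIndex | None = None,
) -> list[AlignmentHit]:
    """Align reads to references; filter by length and identity.

    ``reads`` is a list of (read_id, sequence). With ``best_hit_only`` at
    most one hit per read is reported (highest score, ties to the
    lexicographically smallest ref_id). Reads shorter than the seed k-mer
    are skipped and counted in the log.
    """
    if not refs:
        raise ValueError("reference set is empty")
    params = params or RecruitmentParams()
    if index is None:
        index = ReferenceIndex(refs, k=params.seed_kmer)
    min_len = params.min_hit_len(molecule)
    hits: list[AlignmentHit] = []
    n_short = 0
    for read_id, seq in reads:
        if len(seq) < params.seed_kmer:
            n_short += 1
            continue
        codes = encode_nt(seq)
        cands = _align_one(codes, "+", index, params)
        cands += _align_one(revcomp_codes(codes), "-", index, params)
        cands = [
            c
            for c in cands
            if c[2].aligned_length >= min_len and c[2].percent_identity >= params.min_identity
        ]
        if not cands:
            continue
        if params.best_hit_only:
            cands.sort(key=lambda c: (-c[0], c[1]))
            cands = cands[:1]
        for _, _, hit in cands:
            hit.read_id = read_id
            hits.append(hit)
    if n_short:
        logger.info("align_reads: skipped %d reads shorter than k=%d", n_short, params.seed_kmer)
    return hits


TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def import_alignments(path: str | Path, dialect: str = "tabular") -> list[AlignmentHit]:
    """Read alignments from 12-column tabular (blast outfmt 6) or SAM.

    Coordinates are normalised to 0-based half-open; tabular hits with
    sstart > send are flagged as reverse strand. Tabular identities are
    taken as given; SAM identities are recomputed from CIGAR + NM.
    """
    path = Path(path)
    if dialect == "tabular":
        return _import_tabular(path)
    if dialect == "sam":
        return _import_sam(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _import_tabular(path: Path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns")
            try:
                pident = float(parts[2])
                length = int(parts[3])
                sstart, send = int(parts[8]), int(parts[9])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from exc
            if sstart <= send:
                strand, ref_start, ref_end = "+", sstart - 1, send
            else:
                strand, ref_start, ref_end = "-", send - 1, sstart
            hits.append(
                AlignmentHit(
                    read_id=parts[0],
                    ref_id=parts[1],
                    ref_start=ref_start,
                    ref_end=ref_end,
                    aligned_length=length,
                    percent_identity=pident,
                    score=bitscore,
                    strand=strand,
                )
            )
    return hits


def _import_sam(path: Path) -> list[AlignmentHit]:
    import pysam

    hits = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            stats = rec.get_cigar_stats()[0]
            m = stats[0] + stats[7] + stats[8]  # M + = + X
            ins = stats[1]
            dele = stats[2]
            cols = m + ins + dele
            try:
                nm = rec.get_tag("NM")
            except KeyError as exc:
                raise ValueError(f"SAM record {rec.query_name} lacks NM tag") from exc
            matches = m - (nm - ins - dele)
            pid = 100.0 * matches / cols if cols else 0.0
            hits.append(
                AlignmentHit(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    aligned_length=cols,
                    percent_identity=float(np.clip(pid, 0.0, 100.0)),
                    score=float(rec.mapping_quality),
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return hits


def compute_coverage(
    hits: list[AlignmentHit], ref_id: str, ref_len: int, sample_id: str = ""
) -> CoverageProfile:
    """Depth at position p = number of hits whose [ref_start, ref_end) spans p."""
    delta = np.zeros(ref_len + 1, dtype=np.int64)
    for h in hits:
        if h.ref_id != ref_id:
            continue
        if h.ref_start < 0 or h.ref_end > ref_len:
            raise ValueError(
                f"hit {h.read_id} at {h.ref_start}..{h.ref_end} outside {ref_id} (len {ref_len})"
            )
        delta[h.ref_start] += 1
        delta[h.ref_end] -= 1
    return CoverageProfile(ref_id=ref_id, depth=np.cumsum(delta[:-1]), sample_id=sample_id)
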