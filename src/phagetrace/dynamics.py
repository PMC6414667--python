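"""Abundance, normalisation, dissimilarity, clustering and persistence.

The abundance statistic is the trimmed mean coverage: the arithmetic mean
depth after discarding the 25% (by default) of contig positions with the
deepest coverage, which suppresses the bias from short conserved regions
that recruit non-specifically. Persistence follows the rule: a contig is
persistently active at a site when its metatranscriptome trimmed coverage
is >= 0.75x on at least three of the four sampling dates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .recruitment import CoverageProfile

logger = logging.getLogger(__name__)


@dataclass
class DynamicsParams:
    trim_fraction: float = 0.25
    persistence_cov: float = 0.75
    persistence_min_dates: int = 3
    n_dates: int = 4
    log_base: float = 10.0
    pseudocount: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction < 1.0):
            raise ValueError("trim_fraction must be in [0, 1)")
        if self.persistence_min_dates > self.n_dates:
            raise ValueError("persistence_min_dates cannot exceed n_dates")


def trimmed_mean_coverage(
    profile: CoverageProfile | np.ndarray, trim_fraction: float = 0.25
) -> float:
    """Mean depth after dropping the floor(trim_fraction * L) deepest
    positions (ties at the cutoff resolved by position index, lower index
    dropped first). Zero-depth positions stay in the mean."""
    depth = profile.depth if isinstance(profile, CoverageProfile) else np.asarray(profile)
    L = len(depth)
    if L == 0:
        raise ValueError("empty coverage profile")
    k = int(np.floor(trim_fraction * L))
    if k == 0:
        return float(np.mean(depth))
    # sort by depth descending, then by position ascending
    order = np.lexsort((np.arange(L), -depth))
    return float(np.mean(depth[order[k:]]))


def normalize_sample(row: np.ndarray, log_base: float = 10.0, pseudocount: float = 1.0) -> np.ndarray:
    """Bar heights relative to the highest log-transformed coverage:
    h_i = log(1 + c_i) / log(1 + max_j c_j); all zeros stay zero."""
    row = np.asarray(row, dtype=float)
    if row.size == 0:
        raise ValueError("empty abundance row")
    top = row.max()
    if top <= 0:
        return np.zeros_like(row)
    logs = np.log(pseudocount + row) / np.log(log_base)
    return logs / (np.log(pseudocount + top) / np.log(log_base))


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """1 - 2*sum(min(x_i, y_i)) / (sum x + sum y); two all-zero vectors
    are defined as dissimilarity 0 (with a warning)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative entries")
    denom = x.sum() + y.sum()
    if denom == 0:
        warnings.warn("Bray-Curtis of two all-zero vectors defined as 0", stacklevel=2)
        return 0.0
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


@dataclass
class PersistenceCall:
    ref_id: str
    site_status: dict  # site -> 'persistent' | 'ephemeral' | 'absent'
    n_dates_detected: dict  # site -> int
    global_status: str


def classify_persistence(
    coverages: pd.DataFrame,
    params: DynamicsParams | None = None,
) -> list[PersistenceCall]:
    """Classify each contig from RNA trimmed coverages.

    ``coverages`` has a (site, date) MultiIndex or 'site'/'date' columns
    plus one column per contig. Detected at (site, date) iff coverage >=
    persistence_cov; persistent at a site iff detected on >=
    persistence_min_dates dates; ephemeral iff detected at least once but
    fewer times; absent otherwise. Global status: persistent at any site
    -> persistent; else ephemeral if detected anywhere; else absent.
    """
    params = params or DynamicsParams()
    if not isinstance(coverages.index, pd.MultiIndex):
        coverages = coverages.set_index(["site", "date"])
    calls = []
    sites = coverages.index.get_level_values(0).unique()
    for ref in coverages.columns:
        site_status, ndet = {}, {}
        for site in sites:
            vals = coverages.loc[site][ref]
            if len(vals) < params.n_dates:
                warnings.warn(
                    f"{ref}@{site}: only {len(vals)} of {params.n_dates} dates present",
                    stacklevel=2,
                )
            n = int((vals >= params.persistence_cov).sum())
            ndet[site] = n
            if n >= params.persistence_min_dates:
                site_status[site] = "persistent"
            elif n >= 1:
                site_status[site] = "ephemeral"
            else:
                site_status[site] = "absent"
        statuses = set(site_status.values())
        if "persistent" in statuses:
            glob = "persistent"
        elif "ephemeral" in statuses:
            glob = "ephemeral"
        else:
            glob = "absent"
        calls.append(
            PersistenceCall(
                ref_id=ref, site_status=site_status, n_dates_detected=ndet, global_status=glob
            )
        )
    return calls


def cluster_contigs(
    abundance: pd.DataFrame, params: DynamicsParams | None = None
) -> tuple[list[str], str]:
    """Average-linkage hierarchical clustering of contigs (columns) on
    Bray-Curtis distances of log-transformed abundances.

    Returns (leaf order, Newick string). Deterministic; duplicate column
    labels are an error.
    """
    params = params or DynamicsParams()
    cols = list(abundance.columns)
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate contig labels")
    if len(cols) == 1:
        return cols, f"{cols[0]};"
    # stable order under label permutation: cluster in sorted-label order
    order0 = sorted(range(len(cols)), key=lambda i: cols[i])
    sorted_cols = [cols[i] for i in order0]
    logged = np.log(params.pseudocount + abundance[sorted_cols].to_numpy(dtype=float).T) / np.log(
        params.log_base
    )
    n = len(sorted_cols)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = bray_curtis(logged[i], logged[j])
    Z = hierarchy.linkage(squareform(dm, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [sorted_cols[i] for i in leaves]
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, sorted_cols)
    return leaf_order, newick


def _to_newick(node, labels) -> str:
    def rec(n, parent_dist):
        length = max(0.0, parent_dist - n.dist)
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        left = rec(n.left, n.dist)
        right = rec(n.right, n.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(node, node.dist) + ";"


def abundance_matrix(
    profiles: dict[str, dict[str, CoverageProfile]],
    params: DynamicsParams | None = None,
) -> pd.DataFrame:
    """Trimmed-mean-coverage matrix: rows = sample ids, columns = refs.

    ``profiles`` maps sample_id -> {ref_id: CoverageProfile}.
    """
    params = params or DynamicsParams()
    rows = {
        sample: {
            ref: trimmed_mean_coverage(prof, params.trim_fraction)
            for ref, prof in by_ref.items()
        }
        for sample, by_ref in profiles.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index(axis=1)
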