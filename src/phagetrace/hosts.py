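"""Phage-host matching from co-occurrence of infection activity and
taxon presence.

An actively infecting phage must have host cells present at the time of
sampling, so a candidate host ASV is scored by the fraction of
phage-active samples in which it is present. Abundance correlation is
only a tie-breaker: correlations between environmental bacteria and
viruses are hard to interpret on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ActivityProfile:
    phage_id: str
    active: dict  # sample/condition -> bool
    threshold: float


@dataclass
class HostCandidate:
    asv_id: str
    score: float
    correlation: float
    incompatible_samples: list[str] = field(default_factory=list)

    @property
    def incompatible(self) -> bool:
        return bool(self.incompatible_samples)


@dataclass
class HostRanking:
    phage_id: str
    candidates: list[HostCandidate]
    undefined: bool = False  # phage never active


def activity_profile(
    coverages: dict[str, float] | pd.Series, phage_id: str, threshold: float = 0.75
) -> ActivityProfile:
    """Active wherever RNA trimmed coverage >= threshold (strictly > 0
    when the threshold itself is 0)."""
    if isinstance(coverages, pd.Series):
        coverages = coverages.to_dict()
    if threshold == 0:
        active = {s: c > 0 for s, c in coverages.items()}
    else:
        active = {s: c >= threshold for s, c in coverages.items()}
    return ActivityProfile(phage_id=phage_id, active=active, threshold=threshold)


def consistency_score(
    activity: ActivityProfile,
    presence: dict[str, bool],
) -> float | None:
    """(# samples phage-active AND ASV-present) / (# samples phage-active);
    None (undefined) when the phage is never active."""
    if set(presence) != set(activity.active):
        raise ValueError("sample sets differ between activity and presence")
    active_samples = [s for s, a in activity.active.items() if a]
    if not active_samples:
        return None
    hit = sum(1 for s in active_samples if presence[s])
    return hit / len(active_samples)


def rank_hosts(
    activity: ActivityProfile,
    asv_rna: pd.DataFrame,
    phage_rna_coverage: dict[str, float] | pd.Series | None = None,
    presence_floor: float = 0.001,
) -> HostRanking:
    """Rank candidate ASVs for one phage.

    ``asv_rna``: rows = samples (matching the activity profile), columns
    = ASV ids, values = relative abundance; present iff >= presence_floor.
    Order: consistency score desc, then Pearson correlation between the
    phage RNA coverage and the ASV RNA abundance, then ASV id. Candidates
    scoring < 1 carry the list of violating samples.
    """
    samples = list(activity.active)
    if phage_rna_coverage is None:
        phage_vec = np.array([1.0 if activity.active[s] else 0.0 for s in samples])
    else:
        if isinstance(phage_rna_coverage, pd.Series):
            phage_rna_coverage = phage_rna_coverage.to_dict()
        phage_vec = np.array([float(phage_rna_coverage[s]) for s in samples])
    cands = []
    for asv in sorted(asv_rna.columns):
        abund = asv_rna.loc[samples, asv].to_numpy(dtype=float)
        presence = {s: bool(a >= presence_floor) for s, a in zip(samples, abund)}
        score = consistency_score(activity, presence)
        if score is None:
            return HostRanking(phage_id=activity.phage_id, candidates=[], undefined=True)
        viol = [s for s in samples if activity.active[s] and not presence[s]]
        if np.std(abund) > 0 and np.std(phage_vec) > 0:
            corr = float(np.corrcoef(phage_vec, abund)[0, 1])
        else:
            corr = 0.0
        if math.isnan(corr):
            corr = 0.0
        cands.append(HostCandidate(asv_id=asv, score=score, correlation=corr, incompatible_samples=viol))
    cands.sort(key=lambda c: (-c.score, -c.correlation, c.asv_id))
    return HostRanking(phage_id=activity.phage_id, candidates=cands)
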