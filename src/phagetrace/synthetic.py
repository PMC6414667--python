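"""Synthetic host+phage communities with full ground truth.

Generates viral and host populations with controlled microdiversity
(clonal, continuum, two-cloud), conserved islands, marker genes inserted
into genomes, per-sample DNA/RNA read sets (FASTQ), 16S ASV tables, and
the truth tables every downstream stage is tested against.

Divergence is i.i.d. substitution (no indels by default) so reference
coordinates stay stable. RNA reads for a phage are produced only while
its linked host is present and carries a nonzero infected fraction; with
per-cell expression ratio alpha the expected viral share of marker-gene
transcripts is alpha*I / (alpha*I + 1 - I).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NT = np.array(list("ACGT"))

CLOUD_MODELS = ("clonal", "continuum", "two_cloud", "single")

_DIVERGENCE_DEFAULTS = {
    "clonal": {"max_divergence": 0.02},
    "continuum": {"min_divergence": 0.0, "max_divergence": 0.20},
    # cloud draws sit strictly inside the admissible ranges (near <= 2%,
    # far 8-15%) so the population has a genuine discontinuity; clouds
    # flush against the gap edges blur into a continuum under read-level
    # binomial identity noise.
    "two_cloud": {
        "near_max": 0.015,
        "far_min": 0.10,
        "far_max": 0.15,
        "near_fraction": 0.4,
    },
    "single": {},
}


class ConfigurationError(ValueError):
    """Invalid population or design configuration."""


@dataclass
class PopulationSpec:
    """One viral or host population and its microdiversity model."""

    name: str
    kind: str  # 'viral' | 'host'
    cloud_model: str
    ancestor_length: int = 20000
    n_variants: int = 10
    divergence_params: dict = field(default_factory=dict)
    conserved_islands: list[tuple[int, int]] = field(default_factory=list)  # (start, length)
    marker_genes: list[tuple[str, str, int]] = field(default_factory=list)  # (gene, group, pos)

    def __post_init__(self):
        if self.kind not in ("viral", "host"):
            raise ConfigurationError(f"unknown population kind {self.kind!r}")
        if self.cloud_model not in CLOUD_MODELS:
            raise ConfigurationError(f"unknown cloud model {self.cloud_model!r}")
        if self.ancestor_length < 1000:
            raise ConfigurationError("ancestor_length must be >= 1000 bp")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        params = dict(_DIVERGENCE_DEFAULTS[self.cloud_model])
        params.update(self.divergence_params)
        self.divergence_params = params
        for key, val in params.items():
            if key.endswith(("divergence", "max", "min")) and not (0.0 <= val <= 0.30):
                raise ConfigurationError(f"divergence parameter {key}={val} outside [0, 0.30]")
        last_end = 0
        for start, length in sorted(self.conserved_islands):
            if start < 0 or length <= 0 or start + length > self.ancestor_length:
                raise ConfigurationError("island outside [0, ancestor_length)")
            if start < last_end:
                raise ConfigurationError("conserved islands overlap")
            last_end = start + length


@dataclass
class Population:
    """Realised population: ancestor, variants and their divergences."""

    spec: PopulationSpec
    ancestor: str
    variant_ids: list[str]
    variants: list[str]
    divergence: pd.DataFrame  # variant_id, target_divergence, realized_divergence
    marker_intervals: dict = field(default_factory=dict)  # gene -> (start, end, group)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def length(self) -> int:
        return self.spec.ancestor_length


def _random_nt(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(NT[codes])


def insert_marker_gene(
    sequence: str,
    marker: str,
    position: int,
    conserved_islands: list[tuple[int, int]] = (),
) -> str:
    """Overwrite ``sequence`` with ``marker`` at ``position`` (replacement,
    length preserved). Overlap with a conserved island is a configuration
    error; an empty marker is a no-op."""
    if not marker:
        return sequence
    if position < 0 or position + len(marker) > len(sequence):
        raise ConfigurationError("marker does not fit inside the sequence")
    for start, length in conserved_islands:
        if position < start + length and start < position + len(marker):
            raise ConfigurationError("marker overlaps a conserved island")
    return sequence[:position] + marker + sequence[position + len(marker):]


def _draw_divergences(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    p = spec.divergence_params
    n = spec.n_variants
    model = spec.cloud_model
    if model == "single":
        return np.zeros(n)
    if model == "clonal":
        return rng.uniform(0.0, p["max_divergence"], size=n)
    if model == "continuum":
        return rng.uniform(p["min_divergence"], p["max_divergence"], size=n)
    # two_cloud: a near-clonal cloud and a diverged one
    n_near = max(1, int(round(p["near_fraction"] * n)))
    near = rng.uniform(0.0, p["near_max"], size=n_near)
    far = rng.uniform(p["far_min"], p["far_max"], size=n - n_near)
    return np.concatenate([near, far])


def generate_population(
    spec: PopulationSpec,
    seed: int,
    marker_sequences: dict[str, str] | None = None,
) -> Population:
    """Build ancestor + variants for one population.

    Conserved islands and inserted marker regions are exempt from
    divergence, so they are column-identical across variants. Divergence
    is realised as exactly round(d * L) substitutions at mutable sites;
    the reported realized divergence is mismatches-to-ancestor / L.
    """
    rng = np.random.default_rng([int(seed), 0x5EED])
    L = spec.ancestor_length
    ancestor = _random_nt(rng, L)

    marker_intervals: dict[str, tuple[int, int, str]] = {}
    if spec.marker_genes:
        marker_sequences = marker_sequences or {}
        seq = _codes_to_str(ancestor)
        for gene, group, pos in spec.marker_genes:
            if gene not in marker_sequences:
                raise ConfigurationError(f"no nucleotide sequence supplied for marker {gene!r}")
            marker = marker_sequences[gene]
            seq = insert_marker_gene(seq, marker, pos, spec.conserved_islands)
            marker_intervals[gene] = (pos, pos + len(marker), group)
        from .recruitment import encode_nt

        ancestor = encode_nt(seq)

    exempt = np.zeros(L, dtype=bool)
    for start, length in spec.conserved_islands:
        exempt[start : start + length] = True
    for start, end, _ in marker_intervals.values():
        exempt[start:end] = True
    mutable = np.flatnonzero(~exempt)

    targets = _draw_divergences(spec, rng)
    variant_ids, variants, rows = [], [], []
    for vi, d in enumerate(targets):
        k = int(round(d * L))
        if k > len(mutable):
            raise ConfigurationError(
                f"target divergence {d:.3f} needs {k} substitutions but only "
                f"{len(mutable)} mutable sites exist"
            )
        codes = ancestor.copy()
        if k:
            sites = rng.choice(mutable, size=k, replace=False)
            codes[sites] = (codes[sites] + rng.integers(1, 4, size=k, dtype=np.int8)) % 4
        realized = float(np.mean(codes != ancestor))
        vid = f"{spec.name}.v{vi:03d}"
        variant_ids.append(vid)
        variants.append(_codes_to_str(codes))
        rows.append((vid, float(d), realized))
    table = pd.DataFrame(rows, columns=["variant_id", "target_divergence", "realized_divergence"])
    return Population(
        spec=spec,
        ancestor=_codes_to_str(ancestor),
        variant_ids=variant_ids,
        variants=variants,
        divergence=table,
        marker_intervals=marker_intervals,
    )


@dataclass
class SampleDesign:
    """Site x date x molecule sample grid and its generative parameters.

    ``abundances`` maps population -> scalar or {"site_date": value}.
    ``infected_fraction`` is keyed by phage population: the fraction of
    the linked host's cells that phage is infecting in each sample.
    ``rna_weights`` optionally overrides the RNA expression weight of a
    population directly (used for survey-style planted activity).
    """

    sites: list[str]
    dates: list[str]
    seed: int
    molecules: list[str] = field(default_factory=lambda: ["DNA", "RNA"])
    abundances: dict = field(default_factory=dict)
    infected_fraction: dict = field(default_factory=dict)
    infection_links: dict = field(default_factory=dict)  # phage -> host
    expression_ratio_alpha: float = 1.0
    n_reads: int | dict = 2000  # scalar or per-sample-id
    read_length: int | dict = 150  # scalar or per-molecule {'DNA': .., 'RNA': ..}
    error_rate: float = 0.001
    rna_weights: dict | None = None

    def __post_init__(self):
        if not self.sites or not self.dates:
            raise ConfigurationError("sites and dates must be nonempty")
        if self.expression_ratio_alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        depths = self.n_reads.values() if isinstance(self.n_reads, dict) else [self.n_reads]
        if any(n < 0 for n in depths):
            raise ConfigurationError("n_reads must be >= 0")

    def n_reads_for(self, sample_id: str) -> int:
        if isinstance(self.n_reads, dict):
            return int(self.n_reads.get(sample_id, 0))
        return int(self.n_reads)

    def read_length_for(self, molecule: str) -> int:
        if isinstance(self.read_length, dict):
            return int(self.read_length[molecule])
        return int(self.read_length)

    @property
    def conditions(self) -> list[str]:
        return [f"{s}_{d}" for s in self.sites for d in self.dates]

    def sample_ids(self) -> list[str]:
        return [f"{c}_{m}" for c in self.conditions for m in self.molecules]

    def lookup(self, mapping: dict, pop: str, cond: str, default: float = 0.0) -> float:
        val = mapping.get(pop, default)
        if isinstance(val, dict):
            return float(val.get(cond, default))
        return float(val)


@dataclass
class GroundTruth:
    """Per-sample truth produced alongside simulated reads."""

    read_counts: pd.DataFrame  # index sample_id, columns populations
    divergences: pd.DataFrame
    viral_marker_fraction: pd.DataFrame  # sample_id, host, expected_fraction
    activity: pd.DataFrame  # index RNA sample_id, columns phage pops (bool)
    infection_links: dict


def _sample_weights(
    community: dict[str, Population], design: SampleDesign, cond: str, molecule: str
) -> dict[str, float]:
    weights = {}
    total_inf: dict[str, float] = {}
    for phage, host in design.infection_links.items():
        total_inf[host] = total_inf.get(host, 0.0) + design.lookup(
            design.infected_fraction, phage, cond
        )
    for name, pop in community.items():
        a = design.lookup(design.abundances, name, cond)
        if molecule == "DNA":
            weights[name] = a
            continue
        if design.rna_weights is not None and name in design.rna_weights:
            weights[name] = design.lookup(design.rna_weights, name, cond)
            continue
        if pop.spec.kind == "host":
            weights[name] = a * max(0.0, 1.0 - total_inf.get(name, 0.0))
        else:
            host = design.infection_links.get(name)
            if host is None:
                weights[name] = 0.0
            else:
                a_host = design.lookup(design.abundances, host, cond)
                i = design.lookup(design.infected_fraction, name, cond)
                weights[name] = (
                    a_host * i * design.expression_ratio_alpha if a_host > 0 and i > 0 else 0.0
                )
    return weights


def simulate_reads(
    community: dict[str, Population], design: SampleDesign
) -> tuple[dict[str, list[tuple[str, str]]], GroundTruth]:
    """Draw single-end reads for every sample in the design.

    DNA reads follow population abundances; RNA reads follow expression
    weights (uninfected host cells express the host genome, infected
    cells the phage genome scaled by alpha). Deterministic under the
    design seed. Read ids carry their truth:
    sample|population|variant|start|strand|serial.
    """
    from .recruitment import encode_nt

    pops = list(community)
    codes = {
        name: [encode_nt(v) for v in pop.variants] for name, pop in community.items()
    }
    reads: dict[str, list[tuple[str, str]]] = {}
    count_rows = {}
    activity_rows = {}
    marker_rows = []
    for si, cond in enumerate(design.conditions):
        for mi, mol in enumerate(design.molecules):
            sample_id = f"{cond}_{mol}"
            rng = np.random.default_rng([design.seed, si, mi])
            weights = _sample_weights(community, design, cond, mol)
            wvec = np.array([weights[p] for p in pops], dtype=float)
            if mol == "RNA":
                activity_rows[sample_id] = {
                    p: weights[p] > 0 for p in pops if community[p].spec.kind == "viral"
                }
                for phage, host in design.infection_links.items():
                    i_tot = sum(
                        design.lookup(design.infected_fraction, ph, cond)
                        for ph, h in design.infection_links.items()
                        if h == host
                    )
                    alpha = design.expression_ratio_alpha
                    denom = alpha * i_tot + (1.0 - i_tot)
                    marker_rows.append(
                        (sample_id, host, alpha * i_tot / denom if denom > 0 else 0.0)
                    )
            sample_reads: list[tuple[str, str]] = []
            n_sample = design.n_reads_for(sample_id)
            if n_sample > 0:
                if wvec.sum() <= 0:
                    raise ConfigurationError(f"zero total abundance in sample {sample_id}")
                counts = rng.multinomial(n_sample, wvec / wvec.sum())
            else:
                counts = np.zeros(len(pops), dtype=int)
            count_rows[sample_id] = dict(zip(pops, (int(c) for c in counts)))
            serial = 0
            for pop_name, n_pop in zip(pops, counts):
                if n_pop == 0:
                    continue
                pop = community[pop_name]
                rl = min(design.read_length_for(mol), pop.length)
                vidx = rng.integers(0, len(pop.variants), size=n_pop)
                starts = rng.integers(0, pop.length - rl + 1, size=n_pop)
                strands = rng.integers(0, 2, size=n_pop)
                n_err = rng.binomial(rl, design.error_rate, size=n_pop)
                for v, st, fwd, ne in zip(vidx, starts, strands, n_err):
                    frag = codes[pop_name][v][st : st + rl].copy()
                    if ne:
                        sites = rng.choice(rl, size=ne, replace=False)
                        frag[sites] = (frag[sites] + rng.integers(1, 4, size=ne)) % 4
                    if not fwd:
                        frag = (3 - frag)[::-1]
                    rid = (
                        f"{sample_id}|{pop_name}|{pop.variant_ids[v]}|{st}|"
                        f"{'+' if fwd else '-'}|r{serial}"
                    )
                    sample_reads.append((rid, _codes_to_str(frag)))
                    serial += 1
            reads[sample_id] = sample_reads
    div = pd.concat(
        [p.divergence.assign(population=p.name) for p in community.values()],
        ignore_index=True,
    )
    truth = GroundTruth(
        read_counts=pd.DataFrame.from_dict(count_rows, orient="index").fillna(0).astype(int),
        divergences=div,
        viral_marker_fraction=pd.DataFrame(
            sorted(set(marker_rows)), columns=["sample_id", "host", "expected_fraction"]
        ),
        activity=pd.DataFrame.from_dict(activity_rows, orient="index").fillna(False),
        infection_links=dict(design.infection_links),
    )
    return reads, truth


def generate_asv_table(
    abundances: dict[str, dict[str, float]], conditions: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Relative-abundance ASV table, rows = samples summing to 1.

    ``abundances`` maps ASV id -> {condition: raw abundance}; absent
    (condition, ASV) pairs are 0. All-zero rows are left unnormalised and
    returned in the flag list.
    """
    asvs = sorted(abundances)
    data = np.array(
        [[float(abundances[a].get(c, 0.0)) for a in asvs] for c in conditions]
    )
    if (data < 0).any():
        raise ConfigurationError("negative ASV abundance")
    totals = data.sum(axis=1)
    flagged = [c for c, t in zip(conditions, totals) if t == 0]
    norm = np.divide(data, totals[:, None], out=np.zeros_like(data), where=totals[:, None] > 0)
    return pd.DataFrame(norm, index=conditions, columns=asvs), flagged


# ---------------------------------------------------------------------------
# synthetic marker-gene reference sets


@dataclass
class MarkerSetConfig:
    """Synthetic aligned marker-protein reference set parameters.

    inter_group_divergence is the expected pairwise amino-acid divergence
    between group consensuses (each diverges half of it from the shared
    ancestor); within_group_divergence separates references of one group.
    """

    groups: tuple[str, ...]
    n_per_group: int = 8
    length_aa: int = 360
    inter_group_divergence: float = 0.15
    within_group_divergence: float = 0.02
    seed: int = 0


def generate_marker_references(cfg: MarkerSetConfig):
    """Aligned synthetic marker proteins with group labels (gap-free)."""
    from .markers import AA_ORDER, MarkerReferenceSet

    rng = np.random.default_rng([cfg.seed, 0xA17])
    aa = np.array(list(AA_ORDER))
    L = cfg.length_aa
    ancestor = rng.integers(0, 20, size=L)

    def mutate(base: np.ndarray, frac: float) -> np.ndarray:
        out = base.copy()
        k = int(round(frac * L))
        if k:
            sites = rng.choice(L, size=k, replace=False)
            out[sites] = (out[sites] + rng.integers(1, 20, size=k)) % 20
        return out

    ids, seqs, labels = [], [], {}
    for group in cfg.groups:
        consensus = mutate(ancestor, cfg.inter_group_divergence / 2.0)
        for i in range(cfg.n_per_group):
            ref = mutate(consensus, cfg.within_group_divergence)
            rid = f"{group}.ref{i:02d}"
            ids.append(rid)
            seqs.append("".join(aa[ref]))
            labels[rid] = group
    return MarkerReferenceSet(ids=ids, sequences=seqs, labels=labels)


_CODONS: dict[str, list[str]] = {}


def _codon_choices() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
    return _CODONS


def back_translate(protein: str, seed: int = 0) -> str:
    """Nucleotide coding sequence with random synonymous codons + TAA stop."""
    table = _codon_choices()
    rng = np.random.default_rng([seed, 0xBAC])
    parts = [table[aa][rng.integers(0, len(table[aa]))] for aa in protein]
    return "".join(parts) + "TAA"


def simulate_marker_reads(
    genes_by_group: dict[str, list[str]],
    weights: dict[str, float],
    n_reads: int,
    read_length: int = 200,
    error_rate: float = 0.001,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Reads drawn from marker nucleotide genes, group truth in read ids."""
    from .recruitment import encode_nt

    rng = np.random.default_rng([seed, 0x4EAD])
    groups = sorted(genes_by_group)
    w = np.array([max(0.0, float(weights.get(g, 0.0))) for g in groups])
    if n_reads == 0:
        return []
    if w.sum() <= 0:
        raise ConfigurationError("zero total marker weight")
    counts = rng.multinomial(n_reads, w / w.sum())
    reads = []
    serial = 0
    for g, n in zip(groups, counts):
        genes = [encode_nt(s) for s in genes_by_group[g]]
        for _ in range(n):
            gene = genes[rng.integers(0, len(genes))]
            rl = min(read_length, len(gene))
            st = int(rng.integers(0, len(gene) - rl + 1))
            frag = gene[st : st + rl].copy()
            ne = rng.binomial(rl, error_rate)
            if ne:
                sites = rng.choice(rl, size=ne, replace=False)
                frag[sites] = (frag[sites] + rng.integers(1, 4, size=ne)) % 4
            if rng.integers(0, 2) == 0:
                frag = (3 - frag)[::-1]
            reads.append((f"mk{serial}|{g}", _codes_to_str(frag)))
            serial += 1
    return reads


def write_fastq(path: str | Path, reads: list[tuple[str, str]]) -> None:
    """Phred+33 FASTQ with uniform quality I (Q40)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
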