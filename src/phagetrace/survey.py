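"""Survey-scale synthetic scenario: a 3-site x 4-date x {DNA, RNA}
sampling grid over a community of 69 assembled viral contigs, two
cyanobacterial hosts carrying psbA, unassembled T4-like and T7-like
cyanophages expressing viral psbA, and Gp23 read pools.

Planted structure (the study conditions the generator emulates):

* 7 of 69 contigs persistently active (>= 3 of 4 dates per site) with
  2 persistent at all three sites and none persistent only at POLA;
  the other 62 appear on 0-2 dates per site.
* one contig ("the cyanopodovirus") active at all three sites only in
  October; its host ASV (Synechococcus) present everywhere while the
  Prochlorococcus ASV is absent from POLA.
* per-sample T4-like infected fraction drawn U(0.38, 0.62) and a fixed
  small T7-like fraction 0.065, which under alpha=1 yields a T4-like
  share of cyanobacterial+viral psbA of ~50 +/- 7% and a T4:cyano
  expression ratio averaging ~1.2.
* Gp23 transcript pools with a cyanophage share drawn U(0.10, 0.20)
  per sample, the rest T4-like heterophage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerReferenceSet
from .synthetic import (
    MarkerSetConfig,
    Population,
    PopulationSpec,
    SampleDesign,
    back_translate,
    generate_marker_references,
    generate_population,
    simulate_marker_reads,
)

SITES = ["POLA", "SPOT", "CAT"]
DATES = ["Jul", "Oct", "Jan", "Apr"]

PSBA_GROUPS = ("cyano_synechococcus", "cyano_prochlorococcus", "T4like", "T7like")
GP23_GROUPS = ("cyanophage_T4like", "heterophage_T4like")


@dataclass
class SurveyConfig:
    n_contigs: int = 69
    n_persistent: int = 7
    contig_length: int = 10000
    host_length: int = 10000
    read_length: int = 150  # metagenome reads
    rna_read_length: int = 250  # metatranscriptome reads
    error_rate: float = 0.001
    marker_length_aa: int = 360
    coverage_lo: float = 2.0  # planted active trimmed-coverage range (x)
    coverage_hi: float = 6.0
    host_expected_reads: float = 4000.0  # cyano compartment reads per RNA sample
    dna_reads_per_sample: int = 6000
    gp23_reads_per_sample: int = 2000
    i4_lo: float = 0.38
    i4_hi: float = 0.62
    i7: float = 0.065
    alpha: float = 1.0
    seed: int = 0


@dataclass
class SurveyScenario:
    config: SurveyConfig
    community: dict  # name -> Population
    design: SampleDesign
    contig_ids: list[str]
    persistent_contigs: list[str]
    podo_contig: str  # the October cyanopodovirus
    psba_refs: MarkerReferenceSet
    gp23_refs: MarkerReferenceSet
    psba_genes: dict  # group -> [nt]
    asv_dna: pd.DataFrame
    asv_rna: pd.DataFrame
    true_i4: dict  # condition -> planted T4-like infected fraction
    gp23_share: dict  # condition -> planted cyanophage share
    gp23_reads: dict = field(default_factory=dict)  # RNA sample -> reads

    @property
    def references(self) -> dict:
        return {c: self.community[c].variants[0] for c in self.contig_ids}


def _activity_pattern(cfg: SurveyConfig, rng: np.random.Generator):
    """Planted per-(contig, site) active-date sets."""
    contigs = [f"vc{i + 1:02d}" for i in range(cfg.n_contigs)]
    persistent = contigs[: cfg.n_persistent]
    active: dict[str, dict[str, set]] = {c: {s: set() for s in SITES} for c in contigs}
    for idx, c in enumerate(persistent):
        if idx < 2:
            p_sites = SITES  # persistent at all three sites
        else:
            p_sites = ["SPOT", "CAT"][: 1 + idx % 2]  # never only at POLA
        for s in SITES:
            if s in p_sites:
                n = int(rng.integers(3, 5))
                active[c][s] = set(rng.choice(DATES, size=n, replace=False))
            else:
                n = int(rng.integers(0, 3))
                active[c][s] = set(rng.choice(DATES, size=n, replace=False))
    podo = contigs[cfg.n_persistent]  # first non-persistent: the cyanopodovirus
    for s in SITES:
        active[podo][s] = {"Oct"}
    for c in contigs[cfg.n_persistent + 1 :]:
        for s in SITES:
            n = int(rng.integers(0, 3))
            active[c][s] = set(rng.choice(DATES, size=n, replace=False))
    return contigs, persistent, podo, active


def build_survey(cfg: SurveyConfig | None = None, seed: int | None = None) -> SurveyScenario:
    """Construct the community, design and auxiliary read pools."""
    cfg = cfg or SurveyConfig()
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng([cfg.seed, 0x50C])

    contigs, persistent, podo, active = _activity_pattern(cfg, rng)
    conds = [f"{s}_{d}" for s in SITES for d in DATES]

    # marker reference sets and nucleotide genes
    psba_refs = generate_marker_references(
        MarkerSetConfig(groups=PSBA_GROUPS, length_aa=cfg.marker_length_aa, seed=cfg.seed * 7 + 1)
    )
    gp23_refs = generate_marker_references(
        MarkerSetConfig(groups=GP23_GROUPS, length_aa=cfg.marker_length_aa, seed=cfg.seed * 7 + 2)
    )
    psba_genes: dict[str, list[str]] = {g: [] for g in PSBA_GROUPS}
    for i, rid in enumerate(psba_refs.ids):
        psba_genes[psba_refs.labels[rid]].append(back_translate(psba_refs.sequences[i], seed=i))
    gp23_genes: dict[str, list[str]] = {g: [] for g in GP23_GROUPS}
    for i, rid in enumerate(gp23_refs.ids):
        gp23_genes[gp23_refs.labels[rid]].append(back_translate(gp23_refs.sequences[i], seed=100 + i))

    # community: contigs + hosts + unassembled cyanophages
    community: dict[str, Population] = {}
    for i, c in enumerate(contigs):
        spec = PopulationSpec(
            name=c, kind="viral", cloud_model="single",
            ancestor_length=cfg.contig_length, n_variants=1,
        )
        community[c] = generate_population(spec, seed=cfg.seed * 1000 + i)
    marker_len = 3 * cfg.marker_length_aa + 3
    marker_pos = (cfg.host_length - marker_len) // 2
    host_marker = {
        "host_syn": ("psbA_syn", "cyano_synechococcus"),
        "host_pro": ("psbA_pro", "cyano_prochlorococcus"),
        "phage_t4_syn": ("psbA_t4", "T4like"),
        "phage_t4_pro": ("psbA_t4", "T4like"),
        "phage_t7_syn": ("psbA_t7", "T7like"),
        "phage_t7_pro": ("psbA_t7", "T7like"),
    }
    marker_nt = {
        "psbA_syn": psba_genes["cyano_synechococcus"][0],
        "psbA_pro": psba_genes["cyano_prochlorococcus"][0],
        "psbA_t4": psba_genes["T4like"][0],
        "psbA_t7": psba_genes["T7like"][0],
    }
    for j, (name, (gene, group)) in enumerate(host_marker.items()):
        kind = "host" if name.startswith("host") else "viral"
        spec = PopulationSpec(
            name=name, kind=kind, cloud_model="clonal",
            ancestor_length=cfg.host_length, n_variants=2,
            divergence_params={"max_divergence": 0.01},
            marker_genes=[(gene, group, marker_pos)],
        )
        community[name] = generate_population(
            spec, seed=cfg.seed * 1000 + 500 + j, marker_sequences=marker_nt
        )

    # planted infected fractions and expression weights
    true_i4 = {c: float(rng.uniform(cfg.i4_lo, cfg.i4_hi)) for c in conds}
    infected_fraction = {
        "phage_t4_syn": dict(true_i4),
        "phage_t4_pro": dict(true_i4),
        "phage_t7_syn": {c: cfg.i7 for c in conds},
        "phage_t7_pro": {c: cfg.i7 for c in conds},
    }
    links = {
        "phage_t4_syn": "host_syn",
        "phage_t4_pro": "host_pro",
        "phage_t7_syn": "host_syn",
        "phage_t7_pro": "host_pro",
    }

    # abundances: hosts (Prochlorococcus absent from POLA), contig DNA
    read_equiv = cfg.contig_length / cfg.rna_read_length
    rna_weights: dict[str, dict[str, float]] = {}
    for c in contigs:
        w = {}
        for s in SITES:
            for d in DATES:
                if d in active[c][s]:
                    w[f"{s}_{d}"] = float(rng.uniform(cfg.coverage_lo, cfg.coverage_hi)) * read_equiv
        rna_weights[c] = w

    abundances: dict[str, dict[str, float]] = {}
    abundances["host_syn"] = {c: 0.6 * cfg.host_expected_reads for c in conds}
    abundances["host_pro"] = {
        c: (0.0 if c.startswith("POLA") else 0.4 * cfg.host_expected_reads) for c in conds
    }
    for p in ("phage_t4_syn", "phage_t4_pro", "phage_t7_syn", "phage_t7_pro"):
        abundances[p] = {c: 0.05 * cfg.host_expected_reads for c in conds}
    for c in contigs:
        w = rna_weights[c]
        abundances[c] = {
            cond: 0.8 * w.get(cond, 0.0)
            + 0.2 * np.mean([w.get(f"{cond.split('_')[0]}_{d}", 0.0) for d in DATES])
            for cond in conds
        }

    # per-sample read depths: RNA depth tracks the planted weights
    n_reads: dict[str, int] = {}
    for cond in conds:
        contig_reads = sum(rna_weights[c].get(cond, 0.0) for c in contigs)
        n_reads[f"{cond}_RNA"] = int(round(contig_reads + cfg.host_expected_reads))
        n_reads[f"{cond}_DNA"] = cfg.dna_reads_per_sample

    design = SampleDesign(
        sites=SITES,
        dates=DATES,
        seed=cfg.seed,
        abundances=abundances,
        infected_fraction=infected_fraction,
        infection_links=links,
        expression_ratio_alpha=cfg.alpha,
        n_reads=n_reads,
        read_length={"DNA": cfg.read_length, "RNA": cfg.rna_read_length},
        error_rate=cfg.error_rate,
        rna_weights=rna_weights,
    )

    # ASV tables (16S): Synechococcus everywhere, Prochlorococcus not at POLA
    asv_abund = {
        "Synechococcus_ASV10": {c: 0.35 for c in conds},
        "Prochlorococcus_ASV4": {c: (0.0 if c.startswith("POLA") else 0.25) for c in conds},
        "SAR11_ASV1": {c: float(rng.uniform(0.2, 0.4)) for c in conds},
        "Roseo_ASV7": {c: float(rng.uniform(0.05, 0.2)) for c in conds},
    }
    from .synthetic import generate_asv_table

    asv_dna, _ = generate_asv_table(asv_abund, conds)
    rna_bias = {
        a: {c: v * float(rng.uniform(0.6, 1.4)) for c, v in per.items()}
        for a, per in asv_abund.items()
    }
    asv_rna, _ = generate_asv_table(rna_bias, conds)

    # Gp23 transcript pools per RNA sample
    gp23_share = {c: float(rng.uniform(0.10, 0.20)) for c in conds}
    gp23_reads = {}
    for ci, cond in enumerate(conds):
        share = gp23_share[cond]
        gp23_reads[f"{cond}_RNA"] = simulate_marker_reads(
            gp23_genes,
            {"cyanophage_T4like": share, "heterophage_T4like": 1.0 - share},
            n_reads=cfg.gp23_reads_per_sample,
            read_length=cfg.rna_read_length,
            error_rate=cfg.error_rate,
            seed=cfg.seed * 10000 + ci,
        )

    return SurveyScenario(
        config=cfg,
        community=community,
        design=design,
        contig_ids=contigs,
        persistent_contigs=persistent,
        podo_contig=podo,
        psba_refs=psba_refs,
        gp23_refs=gp23_refs,
        psba_genes=psba_genes,
        asv_dna=asv_dna,
        asv_rna=asv_rna,
        true_i4=true_i4,
        gp23_share=gp23_share,
        gp23_reads=gp23_reads,
    )
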