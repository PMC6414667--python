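"""Stage orchestration and tabular IO for the recruitment pipeline.

Every stage consumes and produces documented intermediate files (FASTA /
FASTQ / 12-column tabular hits / TSV with '#' header comments / JSON),
so stages can be re-run independently and external aligner output can be
substituted via :func:`phagetrace.recruitment.import_alignments`.
Reruns with an identical config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    DynamicsParams,
    abundance_matrix,
    bray_curtis,
    classify_persistence,
    cluster_contigs,
    normalize_sample,
)
from .hosts import activity_profile, rank_hosts
from .markers import (
    MarkerReferenceSet,
    build_profile,
    calibrate_threshold,
    classify_reads,
    gp23_partition,
    partition,
)
from .recruitment import (
    AlignmentHit,
    RecruitmentParams,
    ReferenceIndex,
    align_reads,
    compute_coverage,
    filter_references,
)
from .spectrum import classify_spectrum, detect_islands, identity_histogram
from .survey import SurveyConfig, SurveyScenario, build_survey
from .synthetic import read_fastq, simulate_reads, write_fasta, write_fastq

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, chash: str, notes: list[str] | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# phagetrace {__version__} config={chash}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        for n in notes or []:
            fh.write(f"# {n}\n")
        df.to_csv(fh, sep="\t")


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def hits_to_tabular(hits: list[AlignmentHit], path: str | Path, chash: str):
    """12-column blast-like tabular; reverse strand encoded sstart > send."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# phagetrace {__version__} config={chash}\n")
        fh.write("# qseqid sseqid pident length mismatch gapopen qstart qend "
                 "sstart send evalue bitscore (1-based inclusive)\n")
        for h in hits:
            if h.strand == "+":
                sstart, send = h.ref_start + 1, h.ref_end
            else:
                sstart, send = h.ref_end, h.ref_start + 1
            mism = int(round((1.0 - h.percent_identity / 100.0) * h.aligned_length))
            fh.write(
                f"{h.read_id}\t{h.ref_id}\t{h.percent_identity:.2f}\t{h.aligned_length}"
                f"\t{mism}\t0\t1\t{h.aligned_length}\t{sstart}\t{send}\t0\t{h.score:.1f}\n"
            )


def write_marker_fasta(refs: MarkerReferenceSet, path: str | Path):
    with open(path, "w") as fh:
        for rid, seq in zip(refs.ids, refs.sequences):
            fh.write(f">{rid} group={refs.labels[rid]}\n{seq}\n")


def read_marker_fasta(path: str | Path) -> MarkerReferenceSet:
    ids, seqs, labels = [], [], {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        group = "other"
        for tok in rec.description.split():
            if tok.startswith("group="):
                group = tok[len("group="):]
        labels[rec.id] = group
    return MarkerReferenceSet(ids=ids, sequences=seqs, labels=labels)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(scenario: SurveyScenario, outdir: Path, chash: str) -> dict:
    """Write references, per-sample FASTQ, marker sets, ASV and truth tables."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "references.fasta", scenario.references)
    write_fasta(
        outdir / "genomes.fasta",
        {
            f"{name}.{vid}": seq
            for name, pop in scenario.community.items()
            for vid, seq in zip(pop.variant_ids, pop.variants)
        },
    )
    reads, truth = simulate_reads(scenario.community, scenario.design)
    for sample, rlist in reads.items():
        write_fastq(outdir / "reads" / f"{sample}.fastq", rlist)
    for sample, rlist in scenario.gp23_reads.items():
        write_fastq(outdir / "reads" / f"{sample}.gp23.fastq", rlist)
    write_marker_fasta(scenario.psba_refs, outdir / "psba_refs.faa")
    write_marker_fasta(scenario.gp23_refs, outdir / "gp23_refs.faa")
    write_tsv(truth.read_counts, outdir / "truth_read_counts.tsv", chash)
    write_tsv(truth.divergences.set_index("variant_id"), outdir / "truth_divergences.tsv", chash)
    write_tsv(truth.activity.astype(int), outdir / "truth_activity.tsv", chash)
    write_tsv(
        truth.viral_marker_fraction.set_index("sample_id"),
        outdir / "truth_viral_marker_fraction.tsv", chash,
    )
    write_tsv(scenario.asv_dna, outdir / "asv_dna.tsv", chash)
    write_tsv(scenario.asv_rna, outdir / "asv_rna.tsv", chash)
    meta = {
        "persistent_contigs": scenario.persistent_contigs,
        "podo_contig": scenario.podo_contig,
        "true_i4": scenario.true_i4,
        "gp23_share": scenario.gp23_share,
    }
    with open(outdir / "scenario.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return {"samples": sorted(reads), "n_references": len(scenario.references)}


def stage_recruit(
    refs: dict[str, str],
    reads_by_sample: dict[str, list[tuple[str, str]]],
    params: RecruitmentParams,
    outdir: Path | None = None,
    chash: str = "",
) -> dict[str, list[AlignmentHit]]:
    """Align every sample against the (length-filtered) reference set."""
    refs = filter_references(refs, params.min_ref_len)
    index = ReferenceIndex(refs, k=params.seed_kmer)
    hits_by_sample = {}
    for sample in sorted(reads_by_sample):
        molecule = "RNA" if sample.endswith("RNA") else "DNA"
        hits = align_reads(reads_by_sample[sample], refs, params, molecule, index=index)
        hits_by_sample[sample] = hits
        if outdir is not None:
            hits_to_tabular(hits, Path(outdir) / "hits" / f"{sample}.tsv", chash)
    return hits_by_sample


def coverage_profiles(
    hits_by_sample: dict[str, list[AlignmentHit]], refs: dict[str, str]
) -> dict[str, dict]:
    profiles: dict[str, dict] = {}
    for sample, hits in hits_by_sample.items():
        by_ref: dict[str, list[AlignmentHit]] = {r: [] for r in refs}
        for h in hits:
            by_ref[h.ref_id].append(h)
        profiles[sample] = {
            r: compute_coverage(by_ref[r], r, len(refs[r]), sample) for r in refs
        }
    return profiles


def stage_dynamics(
    abundance: pd.DataFrame, params: DynamicsParams, outdir: Path, chash: str
) -> dict:
    """Normalised heights, Bray-Curtis matrices, persistence, clustering."""
    outdir = Path(outdir)
    heights = abundance.apply(
        lambda row: pd.Series(
            normalize_sample(row.to_numpy(), params.log_base, params.pseudocount),
            index=row.index,
        ),
        axis=1,
    )
    write_tsv(heights, outdir / "normalized_heights.tsv", chash)

    summary: dict = {}
    for mol in ("DNA", "RNA"):
        rows = [s for s in abundance.index if s.endswith(mol)]
        if not rows:
            summary[f"bray_curtis_{mol}"] = None
            continue
        sub = abundance.loc[rows]
        n = len(rows)
        bc = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                bc[i, j] = bc[j, i] = bray_curtis(sub.iloc[i].to_numpy(), sub.iloc[j].to_numpy())
        bcdf = pd.DataFrame(bc, index=rows, columns=rows)
        write_tsv(bcdf, outdir / f"bray_curtis_{mol}.tsv", chash)
        off = bc[np.triu_indices(n, 1)]
        summary[f"median_bray_curtis_{mol}"] = float(np.median(off)) if len(off) else None

    rna_rows = [s for s in abundance.index if s.endswith("RNA")]
    if rna_rows:
        cov = abundance.loc[rna_rows].copy()
        idx = pd.MultiIndex.from_tuples(
            [tuple(s.rsplit("_", 2)[:2]) for s in rna_rows], names=["site", "date"]
        )
        cov.index = idx
        calls = classify_persistence(cov, params)
        rows = []
        for c in calls:
            row = {"global_status": c.global_status}
            for site, st in c.site_status.items():
                row[f"{site}_status"] = st
                row[f"{site}_dates_detected"] = c.n_dates_detected[site]
            rows.append(pd.Series(row, name=c.ref_id))
        pers = pd.DataFrame(rows)
        pers.index.name = "ref_id"
        write_tsv(pers, outdir / "persistence.tsv", chash)
        counts = pers["global_status"].value_counts().to_dict()
        summary["persistence_counts"] = {k: int(v) for k, v in sorted(counts.items())}
    else:
        logger.warning("no RNA samples: persistence stage skipped")
        summary["persistence_counts"] = None

    if abundance.shape[1] >= 2:
        leaf_order, newick = cluster_contigs(abundance, params)
        (outdir / "contig_dendrogram.nwk").write_text(newick + "\n")
        summary["leaf_order"] = leaf_order
    return summary


def stage_spectrum(
    hits_by_sample: dict[str, list[AlignmentHit]],
    refs: dict[str, str],
    outdir: Path,
    chash: str,
    molecule: str = "DNA",
) -> dict:
    """Pooled per-reference identity histograms, class calls and islands."""
    outdir = Path(outdir)
    pooled: dict[str, list[AlignmentHit]] = {r: [] for r in refs}
    samples = [s for s in hits_by_sample if s.endswith(molecule)]
    for s in samples:
        for h in hits_by_sample[s]:
            pooled[h.ref_id].append(h)
    hist_rows, class_rows, island_rows = [], [], []
    classes = {}
    for ref in sorted(refs):
        hist = identity_histogram(pooled[ref], ref, molecule)
        sc = classify_spectrum(hist)
        classes[ref] = sc.label
        class_rows.append(
            pd.Series(
                {
                    "label": sc.label,
                    "frac_ge98": round(sc.frac_ge98, 4),
                    "frac_90_97": round(sc.frac_90_97, 4),
                    "occupied_span": sc.occupied_span,
                },
                name=ref,
            )
        )
        for b, (w, c) in enumerate(zip(hist.weights, hist.counts)):
            if w > 0:
                hist_rows.append((ref, 70 + b, float(w), int(c)))
        prof = compute_coverage(pooled[ref], ref, len(refs[ref]), molecule)
        if len(prof) >= 500:
            for isl in detect_islands(prof, pooled[ref]):
                island_rows.append(
                    (ref, isl.start + 1, isl.end, round(isl.enrichment, 2),
                     round(isl.median_identity, 2))
                )
    write_tsv(
        pd.DataFrame(hist_rows, columns=["ref_id", "bin_lo", "aligned_bases", "hits"]).set_index("ref_id"),
        outdir / f"identity_histograms_{molecule}.tsv", chash,
    )
    cls = pd.DataFrame(class_rows)
    cls.index.name = "ref_id"
    write_tsv(cls, outdir / f"spectrum_classes_{molecule}.tsv", chash)
    write_tsv(
        pd.DataFrame(
            island_rows, columns=["ref_id", "start", "end", "enrichment", "median_identity"]
        ).set_index("ref_id"),
        outdir / f"islands_{molecule}.tsv", chash,
    )
    return {"classes": classes, "n_islands": len(island_rows)}


def stage_markers(
    rna_reads: dict[str, list[tuple[str, str]]],
    psba_refs: MarkerReferenceSet,
    outdir: Path,
    chash: str,
    alpha: float = 1.0,
    target_fpr: float = 1e-3,
    seed: int = 0,
    read_length: int = 150,
    gp23_reads: dict[str, list[tuple[str, str]]] | None = None,
    gp23_refs: MarkerReferenceSet | None = None,
) -> dict:
    """psbA partition per RNA sample (+ optional Gp23 partition)."""
    outdir = Path(outdir)
    profile = build_profile(psba_refs)
    calibrate_threshold(profile, read_length=read_length, target_fpr=target_fpr, seed=seed)
    rows = []
    for sample in sorted(rna_reads):
        assigns = classify_reads(rna_reads[sample], profile, sample)
        res = partition(assigns, sample, alpha=alpha)
        rows.append(
            pd.Series(
                {
                    "n_marker_reads": sum(res.counts.values()),
                    "t4_fraction": round(res.t4_fraction, 4),
                    "viral_fraction": round(res.viral_fraction, 4),
                    "viral_host_ratio": round(res.viral_host_ratio, 4),
                    "infected_fraction_estimate": round(res.infected_fraction_estimate, 4),
                    "flagged": res.flagged or "",
                },
                name=sample,
            )
        )
    psba = pd.DataFrame(rows)
    psba.index.name = "sample_id"
    write_tsv(psba, outdir / "psba_partition.tsv", chash)
    out = {
        "mean_t4_fraction": float(psba["t4_fraction"].mean()),
        "sd_t4_fraction": float(psba["t4_fraction"].std(ddof=1)),
        "mean_viral_host_ratio": float(psba["viral_host_ratio"].mean()),
        "sd_viral_host_ratio": float(psba["viral_host_ratio"].std(ddof=1)),
        "mean_infected_fraction": float(psba["infected_fraction_estimate"].mean()),
    }
    if gp23_reads and gp23_refs is not None:
        g = gp23_partition(gp23_reads, gp23_refs, read_length=200, target_fpr=target_fpr, seed=seed)
        g.index.name = "sample_id"
        write_tsv(g.round(4), outdir / "gp23_partition.tsv", chash)
        out["mean_gp23_cyanophage_fraction"] = float(g["cyanophage_T4like"].mean())
    return out


def stage_hosts(
    rna_abundance: pd.DataFrame,
    asv_rna: pd.DataFrame,
    phages: list[str],
    outdir: Path,
    chash: str,
    threshold: float = 0.75,
    presence_floor: float = 0.001,
) -> dict:
    """Rank candidate host ASVs for each listed phage."""
    outdir = Path(outdir)
    conds = [s.rsplit("_", 1)[0] for s in rna_abundance.index]
    rows = []
    result = {}
    for phage in phages:
        cov = dict(zip(conds, rna_abundance[phage].to_numpy(dtype=float)))
        act = activity_profile(cov, phage, threshold)
        ranking = rank_hosts(act, asv_rna.loc[conds], cov, presence_floor)
        result[phage] = [(c.asv_id, c.score) for c in ranking.candidates]
        for rank, c in enumerate(ranking.candidates, 1):
            rows.append(
                pd.Series(
                    {
                        "rank": rank,
                        "asv_id": c.asv_id,
                        "consistency_score": round(c.score, 4),
                        "correlation": round(c.correlation, 4),
                        "incompatible_samples": ";".join(c.incompatible_samples),
                    },
                    name=phage,
                )
            )
    df = pd.DataFrame(rows)
    df.index.name = "phage_id"
    write_tsv(df, outdir / "host_rankings.tsv", chash)
    return result


def run_pipeline(config: dict) -> dict:
    """Run every stage on the survey scenario described by ``config``.

    Returns the machine-readable summary (also written to summary.json).
    """
    config = dict(config)
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "results/run"))
    # hash only the scientific configuration, not where it is written
    chash = config_hash({k: v for k, v in config.items() if k != "outdir"})
    outdir.mkdir(parents=True, exist_ok=True)

    survey_cfg = SurveyConfig(**config.get("survey", {}))
    survey_cfg.seed = seed
    scenario = build_survey(survey_cfg)
    sim_info = stage_simulate(scenario, outdir, chash)

    params = RecruitmentParams(**config.get("recruitment", {}))
    reads = {
        s: read_fastq(outdir / "reads" / f"{s}.fastq") for s in sim_info["samples"]
    }
    refs = filter_references(scenario.references, params.min_ref_len)
    hits = stage_recruit(refs, reads, params, outdir, chash)

    dyn_params = DynamicsParams(**config.get("dynamics", {}))
    profiles = coverage_profiles(hits, refs)
    abundance = abundance_matrix(profiles, dyn_params)
    write_tsv(abundance.round(4), outdir / "abundance_matrix.tsv", chash,
              ["trimmed mean coverage (x)"])
    dyn_summary = stage_dynamics(abundance, dyn_params, outdir, chash)
    dyn_summary.pop("leaf_order", None)

    spec_summary = stage_spectrum(hits, refs, outdir, chash, molecule="DNA")

    mk_cfg = config.get("markers", {})
    rna_reads = {s: r for s, r in reads.items() if s.endswith("RNA")}
    marker_summary = stage_markers(
        rna_reads,
        scenario.psba_refs,
        outdir,
        chash,
        alpha=float(mk_cfg.get("alpha", 1.0)),
        target_fpr=float(mk_cfg.get("target_fpr", 1e-3)),
        seed=seed,
        read_length=scenario.config.rna_read_length,
        gp23_reads=scenario.gp23_reads,
        gp23_refs=scenario.gp23_refs,
    )

    host_cfg = config.get("hosts", {})
    rna_abund = abundance.loc[[s for s in abundance.index if s.endswith("RNA")]]
    # candidate hosts for a cyanophage: the cyanobacterial ASVs
    candidates = host_cfg.get(
        "candidates", ["Prochlorococcus_ASV4", "Synechococcus_ASV10"]
    )
    host_summary = stage_hosts(
        rna_abund,
        scenario.asv_rna[[c for c in candidates if c in scenario.asv_rna.columns]],
        host_cfg.get("phages", [scenario.podo_contig]),
        outdir,
        chash,
        threshold=float(host_cfg.get("threshold", 0.75)),
        presence_floor=float(host_cfg.get("presence_floor", 0.001)),
    )

    summary = {
        "config": config,
        "config_hash": chash,
        "seed": seed,
        "n_references": sim_info["n_references"],
        "dynamics": dyn_summary,
        "spectrum": {"n_islands": spec_summary["n_islands"]},
        "markers": marker_summary,
        "hosts": host_summary,
        "truth": {
            "persistent_contigs": scenario.persistent_contigs,
            "podo_contig": scenario.podo_contig,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
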