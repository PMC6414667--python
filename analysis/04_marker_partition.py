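"""Partition psbA and Gp23 expression into viral vs. bacterial origin.

Scans every metatranscriptome read set against the PS-II D1 profile,
assigns accepted reads to Synechococcus / Prochlorococcus / T4-like /
T7-like, and reports the per-sample T4-like share of cyanobacterial +
cyanophage psbA, the T4:cyanobacteria expression ratio, and the derived
infected-fraction estimate I = r / (r + alpha) with alpha = 1. The same
machinery partitions Gp23 transcripts into cyanophage vs. heterophage.

Reads results/survey/, writes results/markers/.
"""

from pathlib import Path

from phagetrace.pipeline import read_marker_fasta, stage_markers
from phagetrace.synthetic import read_fastq

INDIR = Path("results/survey")
OUTDIR = Path("results/markers")
SEED = 1


def main():
    rna = {
        p.stem: read_fastq(p)
        for p in sorted((INDIR / "reads").glob("*_RNA.fastq"))
    }
    gp23 = {
        p.name[: -len(".gp23.fastq")]: read_fastq(p)
        for p in sorted((INDIR / "reads").glob("*.gp23.fastq"))
    }
    summary = stage_markers(
        rna,
        read_marker_fasta(INDIR / "psba_refs.faa"),
        OUTDIR, "-",
        alpha=1.0, target_fpr=1e-3, seed=SEED, read_length=250,
        gp23_reads=gp23, gp23_refs=read_marker_fasta(INDIR / "gp23_refs.faa"),
    )
    print(
        f"T4-like share of cyano+viral psbA: "
        f"{100 * summary['mean_t4_fraction']:.0f} +/- "
        f"{100 * summary['sd_t4_fraction']:.0f} % across samples"
    )
    print(
        f"T4-like : cyanobacteria expression ratio: "
        f"{summary['mean_viral_host_ratio']:.2f} +/- {summary['sd_viral_host_ratio']:.2f}"
    )
    print(
        f"implied infected fraction (alpha=1): "
        f"{100 * summary['mean_infected_fraction']:.0f} % of cyanobacteria"
    )
    print(
        f"cyanophage share of Gp23 transcripts: "
        f"{100 * summary['mean_gp23_cyanophage_fraction']:.0f} %"
    )
    print(f"outputs under {OUTDIR}/")


if __name__ == "__main__":
    main()
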