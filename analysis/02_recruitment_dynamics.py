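"""Recruit reads, compute trimmed-coverage abundance, and call
spatiotemporal infection dynamics.

Aligns every sample's reads to the 69 viral contigs, computes the
trimmed mean coverage matrix (top 25% deepest positions excluded),
normalised bar heights, Bray-Curtis dissimilarities, the persistence
classification (>= 0.75x RNA coverage on >= 3 of 4 dates per site), and
the contig dendrogram.

Reads results/survey/, writes results/dynamics/.
"""

from pathlib import Path

from phagetrace.dynamics import DynamicsParams, abundance_matrix
from phagetrace.pipeline import (
    coverage_profiles,
    stage_dynamics,
    stage_recruit,
    write_tsv,
)
from phagetrace.recruitment import RecruitmentParams, filter_references
from phagetrace.synthetic import read_fasta, read_fastq

INDIR = Path("results/survey")
OUTDIR = Path("results/dynamics")


def main():
    refs = filter_references(read_fasta(INDIR / "references.fasta"))
    reads = {
        p.stem: read_fastq(p)
        for p in sorted((INDIR / "reads").glob("*.fastq"))
        if not p.name.endswith(".gp23.fastq")
    }
    params = RecruitmentParams()
    hits = stage_recruit(refs, reads, params, OUTDIR, "-")
    n_hits = sum(len(h) for h in hits.values())
    print(f"recruited {n_hits} hits across {len(hits)} samples")

    dyn = DynamicsParams()
    abundance = abundance_matrix(coverage_profiles(hits, refs), dyn)
    write_tsv(abundance.round(4), OUTDIR / "abundance_matrix.tsv", "-",
              ["trimmed mean coverage (x)"])
    summary = stage_dynamics(abundance, dyn, OUTDIR, "-")
    counts = summary["persistence_counts"]
    print(f"persistence: {counts}")
    print(f"median Bray-Curtis (RNA): {summary['median_bray_curtis_RNA']:.2f}; "
          f"(DNA): {summary['median_bray_curtis_DNA']:.2f}")
    print(f"outputs under {OUTDIR}/")


if __name__ == "__main__":
    main()
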