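"""Percent-identity recruitment spectra and conserved islands.

Pools the metagenomic hits per contig, builds 1-point identity
histograms over [70, 100], classifies each contig's population structure
(clonal / continuum / gapped / sparse) and scans coverage for short
conserved high-identity islands that would bias plain mean coverage.

Reads results/survey + results/dynamics hits, writes results/spectrum/.
"""

from collections import Counter
from pathlib import Path

from phagetrace.pipeline import stage_spectrum
from phagetrace.recruitment import import_alignments
from phagetrace.synthetic import read_fasta

REFS = Path("results/survey/references.fasta")
HITS = Path("results/dynamics/hits")
OUTDIR = Path("results/spectrum")


def main():
    refs = read_fasta(REFS)
    hits = {p.stem: import_alignments(p, "tabular") for p in sorted(HITS.glob("*.tsv"))}
    summary = stage_spectrum(hits, refs, OUTDIR, "-", molecule="DNA")
    counts = Counter(summary["classes"].values())
    print(f"spectrum classes over {len(refs)} contigs: {dict(counts)}")
    print(f"conserved islands detected: {summary['n_islands']}")
    print(f"outputs under {OUTDIR}/")


if __name__ == "__main__":
    main()
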