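# Methods

`phagetrace` tracks active viral infections in marine picoplankton by
recruiting metagenomic (MG, DNA) and metatranscriptomic (MT, RNA) reads
to viral reference sequences. MT recruitment to a viral contig indicates
cells in the latent period of infection (viral genes are transcribed as
the infection proceeds), while MG recruitment indicates viral DNA
presence. Everything downstream — abundance, persistence, identity
spectra, marker partitioning, host matching — is computed from the
alignments produced by this recruitment step.

## Read recruitment

The built-in aligner is seed-and-extend: exact k-mer seeds (k = 15) vote
for (reference, diagonal) pairs; the leading diagonals are pre-scored
with an ungapped best-segment scan (Kadane) and the leaders refined by a
banded affine-gap Gotoh alignment (match +1, mismatch −2, gap open 5,
gap extend 2; band half-width 8). Percent identity is matches over
alignment columns, counting gap columns as mismatches. With
`best_hit_only` (default) each read reports its highest-scoring hit;
ties break to the lexicographically smallest reference id.

Filters follow the molecule: hits shorter than 100 bp (MG) or 200 bp
(MT) are discarded, as are hits below 70% identity (the plotted range of
recruitment spectra) and references of ≤ 5 kbp. The aligner's contract
is validated against an independent full-matrix Smith–Waterman/Gotoh
oracle (`phagetrace.oracle`): on 1000 random ≤ 200 bp instances (planted
reads at 0–10% divergence with up to 2 indels, plus unrelated random
reads) the two agree on every hit/no-hit call with identities within 0.5
points. Exact seeding bounds sensitivity at high divergence: beyond
~15% divergence a small fraction of reads has no exact 15-mer and is
missed, which thins only the extreme low-identity tail of spectra.

External alignments can replace the built-in aligner: SAM (identity
recomputed from CIGAR + NM) or 12-column blast-style tabular (identity
taken as given; `sstart > send` marks the reverse strand). Internal
coordinates are 0-based half-open; all TSV outputs are 1-based inclusive
and say so in their headers.

## Abundance and persistence

Per-contig abundance in a sample is the **trimmed mean coverage**: sort
positions by depth, drop the `floor(0.25 · L)` deepest (ties at the
cutoff drop the lower position index first), and average the rest,
zeros included. "Top 25%" is read as the top quartile of *positions* by
depth, not positions above the 75th-percentile depth value; trimming
suppresses the bias from short conserved regions that recruit
non-specifically at high identity (see islands below).

Bar heights for presentation are `log10(1 + c_i) / log10(1 + max_j c_j)`
per sample (pseudocount 1; the reference states only "log-transformed").
Community turnover uses Bray–Curtis dissimilarity,
`1 − 2·Σ min(x_i, y_i) / (Σx + Σy)`, defined as 0 with a warning for two
all-zero vectors. Contigs are clustered by average-linkage hierarchical
clustering on Bray–Curtis distances of the log-transformed abundances
(the clustering method is otherwise unspecified; average linkage is the
package's choice).

A contig is **detected** at (site, date) when its MT trimmed coverage is
≥ 0.75×; **persistent at a site** when detected on ≥ 3 of 4 dates;
**ephemeral** when detected on 1–2; absent otherwise. The detection
cutoff equals the persistence threshold — no separate "appeared" cutoff
is defined — so persistent/ephemeral/absent partition the contig set.
Global status is persistent if persistent at ≥ 1 site.

## Identity spectra and population structure

Hits ≥ 70% identity accumulate into 1-point bins over [70, 100] (top bin
[99, 100] closed), weighted by aligned bases so long hits dominate, as
in a recruitment plot (hit-count weighting is available). Classification
renders the qualitative spectrum descriptions quantitatively, with all
thresholds config-exposed:

* **clonal** — ≥ 50% of weight at [98, 100] and ≤ 10% in [90, 97):
  many nearly identical relatives, few moderately close ones;
* **gapped** — two occupied regions (≥ 1% of weight per bin) separated
  by ≥ 3 unoccupied bins falling within [88, 98]: discrete clouds with a
  recruitment discontinuity;
* **continuum** — occupied bins spanning ≥ 10 consecutive points within
  [80, 98] with no internal gap of ≥ 2 bins: high microdiversity;
* **sparse** — anything else, including empty histograms.

Precedence is clonal > gapped > continuum.

**Conserved islands** are found by a sliding-window scan (window 500 bp,
step 250 bp): windows whose mean depth is ≥ 5× the median contig depth
(median over all positions; mean of nonzero positions when the median is
0 — median, not mean, so the islands themselves cannot inflate the
background) merge into maximal intervals; intervals longer than 10% of
the contig are not islands. Each island carries its enrichment ratio and
the median identity of overlapping hits. A single island of ≤ 5% of
contig length at ≥ 10× enrichment shifts the plain mean by roughly its
share of total depth while the trimmed mean is unaffected — the
motivation for trimming.

## Marker-gene partitioning (psbA / PS-II D1, Gp23)

Cyanophages carry and express host-derived photosynthesis genes; the
PS-II reaction-center protein D1 (psbA) is expressed throughout the
latent period, so the viral share of psbA transcripts reflects ongoing
infections. Reads are translated in six frames (stops break segments;
segments need ≥ 10 codons), and each segment is scanned against a
position-specific scoring matrix built from an aligned, group-labelled
marker-protein set: per column, `score(aa) = log2(((count + 0.5) /
(N + 10)) / (1/20))`; columns with > 50% gaps are dropped. The scan is
*local* per placement (best contiguous run of columns), so flanking
non-marker residues in a read never penalise a genuine marker fragment —
the behaviour of local profile-HMM search, which the PSSM replaces. The
acceptance threshold is the (1 − 10⁻³) quantile of best-frame scores of
10 000 random-sequence reads at the configured read length; the
empirical false-positive rate on fresh nulls stays within a factor two
of target. This empirical-quantile calibration stands in for analytic
E-values, and the ungapped PSSM for a full profile HMM with
insert/delete states; both are deliberate, documented simplifications.

Accepted reads take the taxon group of their highest-identity reference
at the matched columns (ties: more columns covered, then smallest
reference id). Nearest-reference assignment replaces phylogenetic
placement on an ML tree: the four-group decision boundary is
inter-clade, where the two agree. Per-sample outputs: group counts;
fractions over Synechococcus + Prochlorococcus + T4-like + T7-like; the
T4-like : cyanobacteria expression ratio r; and the infected-fraction
estimate

    I = r / (r + α),

where α is the per-infected-cell viral marker expression relative to the
per-uninfected-cell host expression. α = 1 (comparable per-cell
expression) is the stated assumption made visible as a knob; I(α) = 0.5
iff r = α. A second ratio including T7-like is also reported. Gp23 (the
T4-like major capsid protein, expressed late in infection) runs through
the same machinery with a cyanophage/heterophage reference set.

## Host matching

An actively infecting phage must have host cells present at sampling
time, so each candidate ASV is scored by

    consistency = #(phage active AND ASV present) / #(phage active),

with activity = MT trimmed coverage ≥ 0.75× and presence = relative
abundance ≥ 0.001 (both config-exposed). Pearson correlation between
phage coverage and ASV abundance only breaks score ties — correlations
between environmental phage and bacterial abundances are hard to
interpret on their own, so they never outrank a presence violation.
Candidates scoring < 1 carry the violating samples. For a cyanophage the
candidate set is the cyanobacterial ASVs.

## Synthetic community generator

The generator emulates the study conditions so every stage is testable
against ground truth without downloads:

* **Populations.** An i.i.d.-random ancestor (≥ 1 kb) plus variants at
  controlled divergence, substitutions only by default so coordinates
  stay stable (an indel option exists, default 0). Divergence is
  realised as exactly `round(d·L)` substitutions at mutable sites.
  Models: *single* (identical), *clonal* (d ~ U(0, 0.02)), *continuum*
  (d ~ U(0, 0.20); the uniform law is a modelling convenience — no
  quantitative continuum distribution is established), *two_cloud*
  (40% of variants at d ~ U(0, 0.015), 60% at d ~ U(0.10, 0.15)).
  The clouds sit strictly inside the admissible ranges (≤ 2%, 8–15%) so
  the population has a genuine discontinuity; clouds flush against the
  gap edges blur into a continuum under read-level binomial identity
  noise (sd ≈ 1.4–1.7 identity points at 250–450 bp), and a near-cloud
  share of 0.5 would park the high-identity weight fraction exactly on
  the clonal rule's 50% cutoff. Conserved islands and inserted marker
  genes are exempt from divergence. Marker insertion *replaces* sequence
  (length preserved) and refuses to overlap an island.
* **Sampling design.** Sites × dates × {DNA, RNA}. DNA reads follow
  population abundances. RNA expression: uninfected host cells express
  the host genome, infected cells the linked phage genome scaled by α;
  a phage transcribes only where its host is present with infected
  fraction > 0. Phage transcription is uniform along the genome (an
  early/late weighting exists, default off). With equal genome and
  marker lengths the expected viral share of marker reads is the closed
  form α·I / (α·I + 1 − I). Reads are single-end, uniform start, fixed
  length per molecule, substitution errors at 0.1% by default,
  deterministic under the design seed; read ids carry their truth
  (population, variant, position, strand).
* **Survey scenario** (`phagetrace.survey`). Three sites (POLA, SPOT,
  CAT) × four dates × {DNA, RNA} over 69 viral contigs (10 kb) with
  7 planted persistent contigs (2 persistent at all three sites, none
  only at POLA) and 62 appearing on 0–2 dates per site; one contig (the
  cyanopodovirus) active at all three sites only in October, with the
  Prochlorococcus ASV absent from POLA. MG reads are 150 bp, MT reads
  250 bp (the study sequenced MT libraries longer than MG); spectrum
  recovery simulations use 450 bp, the length of merged overlapping MT
  pairs. Per-sample T4-like infected fractions draw from U(0.38, 0.62)
  and T7-like is fixed at 0.065, which under α = 1 yields a T4-like
  psbA share of ~50 ± 7% and a mean T4:cyanobacteria ratio of ~1.2 —
  the regime the method is meant to resolve. Gp23 pools draw a
  cyanophage share from U(0.10, 0.20) per sample. Planted active
  coverages draw from U(2, 6)×, comfortably above the 0.75× detection
  threshold so persistence calls test the rule rather than sampling
  noise at the boundary.
* **Marker references.** Synthetic aligned protein sets (360 aa, 8 per
  group): group consensuses diverge d/2 from a shared ancestor
  (default inter-group d = 0.15, roughly the PS-II D1 inter-clade
  scale) and references 2% within groups; back-translation uses random
  synonymous codons with an appended stop.

What the generator does **not** emulate: real psbA/Gp23 sequences or
their phylogeny (references are synthetic, labelled as such), indel
sequencing errors, quality-score structure, paired-end fragments, rRNA
depletion, amplicon primers, compositional bias, or genome architecture
(genes, operons, GC content). Passing tests therefore demonstrate the
statistical machinery — recruitment, trimming, classification rules,
calibration, estimators — under controlled conditions, not performance
on real libraries.

## Numerical and reproducibility choices

Alignment scores are integers, so oracle comparisons are exact.
Histogram bins are closed at the top ([99, 100]). All randomness flows
from explicit integer seeds through `numpy.random.default_rng` seed
sequences (no wall-clock seeding); reruns with an identical config are
byte-identical, and every output table carries the tool version, a hash
of the scientific config, and the coordinate convention. Inner loops
(banded Gotoh, seed voting, PSSM scans) are numba-compiled; the
validation oracle is a separate vectorised-numpy full-matrix
implementation sharing no code with the production path.

## Problem sizes

Recovery experiments run at desk scale: persistence recovery 50 seeded
3-site × 4-date simulations; spectrum recovery 100 seeds × 3 cloud
models at ≥ 2000 hits each; aligner–oracle comparison 1000 instances;
infected-fraction recovery 12 seeds × 4 infected fractions × 20 000
marker reads (the per-seed binomial error at 20 000 reads is ~0.4
percentage points, far inside the ±5-point tolerance); host-match
recovery 50 seeded designs. The survey scenario itself is ~170 000 reads
across 24 samples — a miniature of the ~10⁸-read study, sized so the
whole analysis reruns in minutes on one CPU.

## Known limitations

Exact k-mer seeding loses sensitivity beyond ~15–20% divergence, like
the mapping tools it emulates. The PSSM cannot model insertions relative
to the marker alignment, so indel-containing marker reads score low.
The infected-fraction estimate inherits every caveat of its assumptions:
equal per-cell expression (α), T4-like dominance of viral psbA, and
marker detection symmetry between host and viral variants; it is a
rough community-level figure, not a per-taxon rate. Persistence calls
depend on the contig set: viruses that fail to assemble (high
microdiversity) are invisible to contig-based tracking, which is
precisely why the marker-gene route exists.
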