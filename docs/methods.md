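# Methods

This note records the models behind each stage, the parameters that matter,
what the simulator does and does not emulate, and the design choices made
where the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and codon conventions

All coordinates are 0-based, half-open. Codon index 0 is the start codon;
the stop codon is never part of any occupancy vector (terminating ribosomes
are a different process from elongation). Codons are stored as DNA; RNA
spelling (`AAU`) is accepted at every user-facing boundary. The 61 sense
codons in lexicographic order are the fixed axis of occupancy vectors.

## Synthetic data

`generate_transcriptome` draws, per gene, a total codon count uniform in
`length_range` (start and stop included — an unambiguous sizing rule),
internal codons i.i.d. from a 61-way weight vector (uniform by default,
stop codons excluded by construction), a uniformly chosen stop codon, and a
lognormal relative mRNA abundance (σ = 1 by default, the order-of-magnitude
spread typical of yeast mRNA levels; σ = 0 gives the equal-abundance
control used in calibration experiments). Optional 5′/3′ UTRs (default 0)
exist so that reads can be placed upstream of the start codon when a test
needs the initiation-peak geometry.

`simulate_footprints` is the generative inverse of the A-site assignment
rule. A read picks a gene ∝ abundance × Σ(dwell over its eligible codons),
then an A-site codon ∝ its dwell multiplier; the 5′ end sits exactly 15 nt
upstream of that codon and the length is uniform on 28–31 nt (the gel cut;
no within-cut length distribution is established, so uniform is
assumed), truncated at the transcript end. Codons whose read would run off
either end are excluded up front — equivalent to resampling. Length
variation is therefore entirely 3′-sided, which makes truth recovery exact.
Contaminant reads are substrings of a bundled synthetic 2-kb fixed-seed
decoy ("rRNA" stand-in; the filter only needs a decoy). Base qualities are
constant Q40; quality trimming is tested with explicitly constructed
low-quality fixtures instead. Substitution errors are i.i.d. per base.

Not emulated: ligation/PCR bias, UMI structure, paired ends, initiation or
termination pausing, secondary-structure-dependent contamination, and 5′
heterogeneity of real footprints. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to every artifact of real libraries.

`simulate_bisulfite_reads` emits each reference cytosine as C with
probability f + (1 − f)·ε (f = true methylation fraction, ε =
non-conversion rate, default 0.01) and as T otherwise; non-C bases carry
an optional sequencing error. The observed C fraction at a site therefore
converges to f + (1 − f)·ε, which is what the caller estimates.

## Read processing

* **Adapter** matching is 3′-anchored and exact, requiring ≥ 6 nt of the
  adapter prefix; the published workflow names the adapter but not its
  matcher, and exact matching is reproducible and sufficient for synthetic
  reads. Quality trimming removes 3′ bases below Q30; size selection keeps
  25–35 nt.
* **Contaminant filtering** replaces seeded alignment with an exact shared
  k-mer test (k = 20, either strand). Mismatch tolerance is deliberately
  not reproduced; for decoy filtering the k-mer rule is adequate and
  dependency-free.
* **Alignment** is ungapped, full-length, unique-best over the
  transcriptome with ≤ 2 mismatches. Candidates come from three disjoint
  8-mer seeds (pigeonhole: with ≤ 2 substitutions one seed is exact), then
  verified base by base. Reads whose best score ties across genes are
  dropped; ties within a gene resolve to the leftmost offset
  (deterministic, conservative).
* **Periodicity QC** histograms 5′ ends in ±20 nt around start codons per
  read length; the score is the modal-frame fraction, accepted at ≥ 0.6
  with ≥ 100 window reads. The optional single-largest-bin-at-−12 check
  encodes the initiation peak (A-site on codon 1 puts the 5′ end 12 nt
  upstream of the start). The bundled pipeline config disables that check:
  the simulator models elongating ribosomes on UTR-less transcripts, so
  the peak cannot exist in its output; the score and count criteria remain
  active. On real libraries the check should be on.
* **A-site assignment** is read start +15 nt. A phase-2 site receives the
  +1 nt correction; phase-1 reads are discarded and counted rather than
  shifted −1 — the sources state only a "+1 nt" correction, and inventing
  a −1 rule would be guesswork. A-sites outside the CDS or on the stop are
  discarded and counted. Refusing to run with an empty accepted-length set
  is an error by design: unvetted lengths must never be analyzed silently.

Every stage reports a count ledger; `input = output + Σ removal causes`
is enforced by tests.

## Codon occupancy

Occupancy divides A-site codon proportions by a usage normalizer. The
primary normalizer is **local**: the codon proportions over the 3 codons
directly 3′ of each A-site, truncated at the stop. It is self-weighting —
whatever mix of genes and abundances produced the reads also produces the
contexts — which keeps the estimator calibrated under abundance variation.
The alternative (`usage_mode="transcriptome"`), usage compiled from the
CDSs represented in the footprints, suits single-sample analyses. Codons
with < 30 A-site reads (configurable) or zero usage are reported missing,
never infinite.

Condition ratios pair replicate i with replicate i (mean ± SEM over the
pairs); `all-pairs` and `ratio-of-means` are available because a reported
"mean ± SEM, n = 3" does not pin down the pairing convention. SEM of
C-vs-U pair ratios uses first-order propagation.

A note on scale: because A-site proportions are normalized, injecting a
dwell multiplier d on one codon yields an expected ratio d/(1 + f·(d−1))
with f ≈ 1/61, i.e. a ~1–3% shrinkage toward 1, and all other codons shift
by the reciprocal factor. At depth 2×10⁵ the per-codon sampling CV is
~1.7% (A-site multinomial) ⊕ ~1% (local usage), so recovered ratios
scatter a few percent around these expectations; the acceptance script
reports the measured values.

**tAI** follows the standard two-formula scheme: w(c) sums
(1 − s) × tGCN over the Watson–Crick anticodon and the standard eukaryotic
wobble partner (G34:U3 s = 0.41, I34:C3 0.28, I34:A3 0.9999, U34:G3 0.68;
Watson–Crick classes 0; A34 read as inosine; ATG and TGG decoded by their
Watson–Crick anticodons only), normalized by max w. Codons with no decoder
receive the geometric mean of nonzero weights before normalization (keeps
1/tAI finite) and are flagged. Both parameter tables are editable TSVs; the
bundled gene-copy table is a synthetic stand-in with a complete eukaryotic
repertoire, labelled as such.

The 1/tAI–occupancy Spearman correlation uses replicate-averaged occupancy
(the per-replicate alternative is a one-liner on the profiles); mid-ranks
for ties; a constant vector yields a missing ρ with a warning.

**Relative enrichment** of a codon at offsets −90…+90 from the A-site
divides the observed codon proportion at each offset by the proportion
expected if each read's A-site were uniform over its gene's sense codons
(read-count weighted, truncated at CDS edges). Offset 0 reproduces A-site
occupancy under that same normalizer, which is the invariant the tests
check.

## Translation efficiency

TE is footprint count over mRNA count, each scaled by its library size;
genes with < 10 RNA reads per replicate are unstable and reported missing.
Differential TE is a deliberately transparent substitute for black-box
engines: per-replicate log2 TE with a 0.5 pseudocount (finite at zero
counts), **median-centered per replicate** — total-count normalization is
composition-sensitive, and a few strongly shifted genes would otherwise
drag every other gene's apparent TE the opposite way; centering encodes
the standard majority-unchanged assumption of median-of-ratios size
factors — then a Welch t-test per gene and Benjamini–Hochberg adjustment,
reported at the conventional thresholds (p < 0.05, adjusted p < 0.1).
Degenerate zero-variance genes get p = 1 when means agree and p = 0
otherwise.

Stretch flags: ≥ 2 consecutive codons of one Q amino acid (Asp, His, Asn,
Tyr; synonymous codons continue a run) or ≥ 3 consecutive codons from the
8-codon Q set. The comparison statistic is the difference of medians of
per-gene ΔlogTE between conditions (flagged − unflagged); per-condition TE
is available via `statistic="te"`; either reading of the comparison is
defensible.
The pre-adjustment test is a two-sided rank-sum (the sources name only the
BH step), recorded in output metadata; groups under 5 genes report no
p-value.

## tRNA methylation

Alignment is exhaustive ungapped scanning in C→T-collapsed space — with a
reference set of a few dozen ~76-nt tRNAs, exhaustive search is exact and
needs no external aligner. Reads tied across references in collapsed space
are ambiguous and dropped. Duplicate handling defaults to **keep**:
removing collapse-identical reads biases methylation fractions, because
reads differing only in C/T state are collapse-identical by construction;
`remove` mode reproduces the summarization that treats them as duplicates,
and the chosen mode is part of the output metadata. The unconversion filter
drops reads whose C fraction at configured known-unmethylated sites
exceeds 0.5 (a genuinely converted read at ε = 1% essentially never does).

Calling: λ is supplied or estimated as the pooled unconverted fraction at
known-unmethylated sites; per site with ≥ 10 reads the p-value is the
Poisson upper tail P(X ≥ k) at mean n·λ. Status is methylated when
p < 0.05 and the fraction ≥ 0.1 (the floor stops high-coverage sites with
trivial fractions from being flagged on p-value alone), unmethylated when
p ≥ 0.05, else ambiguous. `adjust_calls` applies BH across sites for
de-novo scans. Reported percent methylation is the raw unconverted
fraction ×100, so its expectation is 100·(f + (1−f)·λ); at λ = 0.01 the
inflation is at most 1 point and vanishes as f → 1. A per-reference
numbering map translates conventional tRNA positions (e.g. 38) to sequence
offsets when references include variable loops or CCA tails.

## Pipeline and reporting

The run-all driver chains the stages on simulated inputs, writing each
stage's TSV, a YAML echo of the effective configuration, and a JSON run
log with per-stage counts; rerunning with the same config and seed is
byte-identical (verified by checksum in tests). All child seeds derive
from the single config seed. Stage failures abort with the stage name.

The β-galactosidase activity is 1000 × OD420 / (V × t × OD600): volume,
incubation time and cell density all belong in the denominator — an
activity that grew with incubation time would defeat the assay's purpose.
Group comparisons use a two-sided Welch t-test (the assay convention
reports significance stars without naming a test); groups with zero variance and
equal means report p = 1, unequal means p = 0.

## Problem sizes used by tests and the acceptance script

Calibration and recovery experiments run on 150-gene, 250–350-codon
equal-abundance fixtures at 1–2×10⁵ footprints per sample — equal
abundances because these are null controls of the estimator, and an
abundance-weighted small fixture adds an edge-window composition bias
unrelated to the property under test. The read-level exactness check uses
a 10-gene fixture at 10⁵ reads; the differential-TE experiments use 500
genes × 10⁵ counts × 3 replicates; bisulfite recovery uses depth 10⁴.
The bundled pipeline config simulates 20 genes × 2×10⁴ reads × 3
replicates × 2 conditions.

## Known limitations

* Ungapped alignment only; no indels, splicing, or SAM/BAM output.
* The contaminant filter has no mismatch tolerance.
* Phase-1 reads are discarded, slightly reducing usable depth on real
  libraries with 5′ heterogeneity.
* The differential-TE substitute tests log-ratio means; it does not model
  count overdispersion jointly across the two assays the way dedicated
  bivariate engines do.
* The Poisson methylation test treats reads as independent; RT-primer
  demultiplexing and structure-aware alignment are out of scope.
* tAI values depend entirely on the supplied tGCN table; the bundled table
  is synthetic and must be replaced for organism-specific conclusions.
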