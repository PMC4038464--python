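# Methods notes

This note records the models, the parameter choices that matter, and the
places where the design was genuinely open — in enough detail that a reader
can judge what passing tests do and do not demonstrate.

## Split-read mapping

Reads are trimmed 2 bp per end and cut into three equal 32 bp parts
(`3·32 + 2·2 = 100`); each part must match the genome exactly. The index is
a plain suffix array over the concatenated chromosomes separated by `#`
sentinels (which sort before all bases and can never occur inside an
ACGT-only match, so hits cannot span chromosomes). Construction is
prefix-doubling (O(n log² n), numpy `lexsort`); correctness is defined by
the naive sorted-suffix oracle in the test suite, not by the construction.

Placement combines part hits under three rules, all configurable:

- collinearity: one chromosome, one strand, parts in read order;
- gaps: both inter-part gaps in [0, `max_gap`], default 100,000 — a
  generous intron bound; a gap of 0 is a contiguous read;
- uniqueness: exactly one consistent combination across both strands, else
  the read is dropped (counted as ambiguous or unplaced). Median-based
  quantification is robust to dropped reads, and fractional assignment of
  multireads would add unverifiable complexity.

No mismatches are tolerated within a part: the three-part split is itself
the damage-tolerance device, and `min_parts=2` optionally rescues reads
with one unmatchable part (the rescued middle-part case requires genomic
room of at least one part length between the flanking parts). An important
consequence, visible in every mapping summary: a read whose 32 bp part
straddles an exon-exon junction cannot be placed, because the part's
genomic image is not contiguous. With the toy geometry below this discards
~40% of reads; they are missing roughly uniformly across genes, so the
median-coverage estimate is attenuated but not rank-distorted.

The batch mapper packs 32-mers into uint64 keys (2 bits per base, leading
base in the high bits so integer order equals lexicographic order) and
resolves the dominant one-hit-per-part case with `searchsorted`; reads with
repetitive parts fall back to the per-read reference path. The suite
asserts batch == per-read on simulated samples.

## Quantification

Each placed part increments per-base depth over the bases it covers; a
transcript's expression is the median of depth across its exonic bases in
genomic order, zeros included (excluding zeros would leave unexpressed
genes undefined; including them is the natural reading of a median "across
the transcript"). Even-length medians average the two middle order
statistics. Counting is unstranded — the library's strandedness is not
modelled. Genes with several transcripts are represented by the longest
transcript by default; a union-of-exons mode merges all isoforms' exons
(the toy annotation is one transcript per gene, so this is an extension
point rather than an exercised path).

## Differential expression

Quantile normalization maps each sample onto the across-sample mean order
statistics. Ties within a sample receive the mean of the reference values
over the tied ranks; as a consequence exact idempotence and exact
sorted-column equality hold for tie-free data, while tied runs collapse
onto their group mean.

The noise level ν is the peak of the pooled post-normalization expression
distribution: histogram of ln(1+x) over [min, max] with 100 equal bins
(configurable), modal bin center, ties broken toward the lower bin,
ν = exp(center) − 1. A deterministic binning rule replaces the human
eyeball that would otherwise read the peak off a plot; one pooled ν is used
for the whole matrix (the noise is a property of the system, not of a
sample). If all values are equal, ν is that value.

Ratios are ln((case + ν)/(mean(controls) + ν)). Adding ν strictly shrinks
every nonzero ratio, which is the mechanism that keeps low-expression genes
out of the large-fold-change list. Responders are |ln ratio| ≥ 0.2,
inclusive at the boundary. The comparison scheme is fixed by sample
metadata: transgenic vs mean of controls; each ethanol sample vs its paired
control. For multi-replicate summaries ("induced by ethanol") the default
combination is *all replicates*, with *any* available.

GO relevance ranks are consumed as data, never computed: the gene's rank-1
term, else the rank-1 term of its mapped human orthologue, else
"unannotated".

## Synthetic study

The generator emulates the statistical structure the analysis assumes, at a
scale where the full pipeline runs in seconds:

- one 400 kb chromosome, 200 non-overlapping genes of 2–5 exons (80–300 bp)
  with 60–300 bp introns;
- baseline expression log-normal (meanlog 3, sdlog 1); 30% of genes form a
  tight low-expression "noise floor" cluster (meanlog 1.8, sdlog 0.4),
  which is what gives the pooled distribution the low-value peak the noise
  estimator reads; 5% are designated UPR genes carrying a true ln-fold
  induction of 1.0 in the two ethanol samples and the transgenic sample;
- five samples (2 controls, 2 paired ethanol, 1 transgenic), Poisson(100k)
  reads each, drawn per gene proportionally to expression, start uniform
  over the spliced transcript, strand Bernoulli(0.5), error-free by default.

Scale rationale. Responders must be a small minority of both gene count and
expression mass: induced genes displace read share from everything else
(sequencing depth is compositional), and quantile normalization can only
undo that shift up to its rank resolution. At 50 genes with a 20% UPR
fraction the residual shift alone (~0.3 on the ln scale) swamps the 0.2
cutoff; at 200 genes with a 5% fraction the residual is a few hundredths.
Depth of 100k reads/sample keeps per-gene coverage at tens-fold so the
median estimator's sampling noise (driven by ~L/96 effectively independent
coverage blocks per transcript, because one read covers 96 trimmed bases)
stays well below the cutoff.

Scoring definitions. *Sensitivity* is the fraction of (UPR gene,
comparison) pairs called up. The *null responder rate* is measured over
true-null, well-expressed genes — baseline genes whose true expression is
at least 3× the noise-floor scale exp(noise_meanlog). Genes below that are
the population the ν-regularization exists to silence; judging the cutoff's
specificity on them would conflate the two mechanisms.

Images: 256² px RGB fields; droplets are hard-edged disks (radius 2–5 px,
dark red, low green) stamped at integer centers so the recorded truth area
is the exact rasterised pixel count; nuclei are pale blue-cyan disks whose
green intensity matches the background, so the hematoxylin channel does not
bleed into the inverted-green droplet channel; background is an oriented
linear gradient (amplitude 25) plus Gaussian pixel noise (sd 2). Objects
are placed by rejection sampling with a 3 px clearance — overlapping
droplets would make the count ambiguous against truth — and a bounded-retry
failure raises a placement error.

Assay tables: Ct values are true cycle numbers plus Gaussian noise (sd
0.25); the true fold (default 4, the scale of the transgenic atf6
induction) enters as a −log2(fold) shift of the case samples. Steatosis
incidence uses the study's group rates (13% untreated vs 53%
ethanol-treated) with 100 larvae per group.

What the generator does **not** model: sequencing errors beyond uniform
substitution, PCR duplicates, 3′ bias, isoform mixtures, overlapping or
out-of-focus droplets, optical PSF, staining variability. Passing recovery
tests therefore demonstrates correctness of the analysis logic under the
stated assumptions, not robustness to these real-data effects.

## Image quantification

The droplet signal is the inverted green channel (dtype-aware: max − g).
Background is the grey opening by a disk of radius 50 px (the
rolling-ball-equivalent default of common image tools), subtracted and
clipped at zero; the radius must exceed every droplet and be smaller than
the image. Binarisation is Otsu's threshold computed on the nonzero pixels
only (the subtracted background is exactly zero over most of the field and
would otherwise dominate the histogram); components use 8-connectivity;
droplets are components ≥ 5 px². Nuclei are 8-connected components of the
clipped blue-dominance map b − (r+g)/2, Otsu-thresholded, with area
≥ 50 px²; a manual count always overrides detection.

## Assay statistics

Fisher's exact test is two-sided by the minimum-likelihood convention: the
p-value sums hypergeometric probabilities (log-gamma arithmetic) of all
margin-fixed tables whose probability does not exceed the observed table's,
with a 1e−7 relative tolerance on the comparison so floating-point
near-ties count as ties. A zero margin yields p = 1 and an undefined odds
ratio. "Chi-square with Fisher's exact" is internally inconsistent
terminology; the exact test is primary (clutch counts are small), and
chi-square (with optional Yates correction) is provided as a secondary
statistic. The t-test family defaults to the equal-variance Student test
(Welch behind a flag), with explicit degenerate handling: zero variance and
zero effect gives p = 1; zero variance with a nonzero effect is flagged
with p → 0. One-sample tests on fold changes are intended for ln(fold)
against 0, testing fold against 1 multiplicatively.

Circularity is 4πA/P² with A the pixel count and P the 8-connected Moore
boundary chain through pixel centers, diagonal steps weighted √2
(termination by Jacob's criterion so shapes that revisit the start pixel
trace fully). This estimator is exact for axis-aligned rectangles (the
n×n square tends to π/4 from above) but overestimates smooth contours by
~5% averaged over orientations, so digitized disks score ≈ 0.91 rather
than 1 — a documented digitization bias, asserted as such by the tests. A
`perimeter="calibrated"` mode applies the Kulpa factor 0.9481, centering
disks at ≈ 1.0 at the cost of biasing polygonal shapes; the default stays
with the uncorrected chain because its value is interpretable against the
exact-rectangle anchor and the bias is constant across comparable shapes.

## Numerical and degenerate-input choices

- Suffix array: sentinel `#` (ASCII 35) sorts before A/C/G/T/N; queries
  containing N return no hits (N is never matched).
- Empty coverage profiles, empty genomes, empty gene sets, zero-variance
  t-tests, zero control medians, zero nuclei, all-zero droplet signals and
  both-bands-zero splicing inputs all have explicit, tested behaviours
  (error or flagged-undefined) rather than NaNs.
- Regularized ratio with ν = 0 and case = controls = 0 is reported as 0
  with a degenerate flag on the result record.
- All simulator outputs are pure functions of (config, seed); independent
  artifacts draw from independently keyed generators, so adding fields does
  not perturb read simulation.

## Problem sizes used by the test and acceptance runs

Unit tests run reduced configurations (30–60 genes, 3k–20k reads) chosen so
the whole suite stays interactive; the end-to-end recovery checks run the
full default study across 30 seeds, and the acceptance script uses 5 seeds
for the study loop, 20 stained fields, and single runs for the remaining
assays. These sizes are the package's own defaults for routine validation;
all of them scale up through `SimulationConfig`.
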