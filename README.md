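# steatoseq

A reusable implementation of the computational analysis behind a zebrafish
fatty-liver (hepatic steatosis) study design: a custom split-read mRNA-seq
mapper, median-coverage expression quantification, noise-regularized
differential expression, oil-red-O lipid-droplet image quantification, and
the supporting assay statistics — together with a synthetic-data generator
that produces every pipeline input with known ground truth.

## Who this is for

Groups analysing bulk liver RNA-seq from small-animal steatosis models (and
matched histology/qPCR assays) who want the original in-house analysis
available as a tested, scriptable library rather than a one-off pipeline.

## The methods at the core

**Split-read exact mapping.** Each single-end 100 bp read is trimmed by 2 bp
at both ends and split into three 32 bp parts. Parts are matched *exactly*
against the genome by binary search over a suffix array; a read is placed
when its three parts land on one chromosome and strand, in read order, with
both inter-part gaps in [0, `max_gap`] (gaps absorb introns, giving N-gapped
alignments such as `32M50N64M`). Reads with zero or multiple consistent
placements are counted and discarded — splitting is itself the mismatch
tolerance, so no within-part mismatches are allowed.

**Median-coverage expression.** Every placed part increments coverage at
each exonic base it overlaps; the expression of a gene is the *median* of
per-base coverage across its transcript (zeros included). The estimator is
deliberately length-free — no TPM/FPKM.

**Noise-regularized differential expression.** Samples are quantile
normalized; the noise level ν is read off as the peak of the pooled
expression distribution (histogram of ln(1+x), modal bin); ratios are

&nbsp;&nbsp;&nbsp;&nbsp;ln((case + ν) / (mean(controls) + ν))

so weakly expressed genes shrink toward zero, and a gene responds when
|ln ratio| ≥ 0.2 (inclusive). The transgenic sample is compared against the
mean of the controls; each ethanol sample against its paired control.

**Droplet quantification.** Oil red O absorbs ~510 nm, so the inverted
green channel carries the droplet signal; a rolling-ball-equivalent grey
opening (disk radius 50 px) removes the background, Otsu's threshold
binarises, and 8-connected components ≥ 5 px² are counted, with per-nucleus
statistics from the hematoxylin (blue-dominant) counterstain.

**Assay statistics.** qPCR comparative-threshold values
dCt = 2^−(Ct_gene − Ct_rpp0) with median-based fold changes; steatosis
incidence by two-sided Fisher's exact test (minimum-likelihood convention,
chi-square as secondary); unpaired/paired/one-sample t-tests; xbp1
splicing percentages from band intensities; liver circularity 4πA/P².

## Worked example

Run the full synthetic study — 200 genes on a 400 kb chromosome, five liver
samples (two controls, two paired ethanol, one transgenic) at 100k reads
each, with ten designated UPR genes induced at a true ln-fold of 1.0:

```python
from steatoseq import pipeline
from steatoseq.config import SimulationConfig

result = pipeline.run_study(SimulationConfig(seed=1))
print(f"noise peak nu            : {result.nu:.2f}")
print(f"UPR sensitivity          : {result.upr_sensitivity:.3f}")
print(f"null responder rate      : {result.null_responder_rate:.3f}")
print(f"expression Spearman rho  : {result.expression_spearman:.3f}")
print(f"mapping (ctrl_1)         : {result.mapping_stats['ctrl_1']}")
print(f"UPR overlap counts       : {pipeline.upr_overlap_counts(result)}")
```

prints

```
noise peak nu            : 4.34
UPR sensitivity          : 1.000
null responder rate      : 0.169
expression Spearman rho  : 0.921
mapping (ctrl_1)         : {'total': 99961, 'unique': 60275, 'ambiguous': 0, 'unplaced': 39686}
UPR overlap counts       : {'ethanol_induced': 10, 'tg_induced': 10, 'intersection': 10}
```

Reading the numbers: the noise peak sits at the low-expression cluster
(coverage ≈ 4), all ten UPR genes clear the 0.2 cutoff in every comparison
(`sensitivity 1.0`), ~17% of well-expressed null genes are flagged in this
particular seed (the average across seeds is ≈ 0.09), estimated expression
ranks track the simulated truth (ρ ≈ 0.92), and ~60% of reads place
uniquely — the rest mostly straddle exon junctions inside a 32 bp part,
which exact matching cannot place.

The same study is available from the shell:

```sh
steatoseq simulate --outdir sim --seed 1
steatoseq index --fasta sim/genome.fa --out genome.idx
steatoseq map --idx genome.idx --fastq sim/ctrl_1.fastq --out ctrl_1.tsv
steatoseq quant --placements ctrl_1.tsv --gtf sim/annotation.gtf \
    --fasta sim/genome.fa --out ctrl_1.expr.tsv
steatoseq de --matrix matrix.tsv --meta sim/samples.tsv --outdir de_out
steatoseq droplets --images sim --out droplets.tsv
steatoseq stats --mode fisher --in sim/incidence.tsv --out fisher.json
```

## Layout

- `src/steatoseq/synthdata.py` — study generator (reference, reads, stained
  fields, assay tables) with ground truth
- `src/steatoseq/splitmap.py` — suffix-array index, split-read placement,
  SAM/TSV export
- `src/steatoseq/quantify.py` — coverage and median expression
- `src/steatoseq/diffexpr.py` — quantile normalization, noise peak,
  regularized ratios, responder calling, gene-set overlap, GO assignment
- `src/steatoseq/lipidimage.py` — droplet segmentation and per-nucleus stats
- `src/steatoseq/assaystats.py` — dCt, Fisher/chi-square, t-tests,
  splicing fraction, circularity, protein normalization
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
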