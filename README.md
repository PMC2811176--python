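# helpscan

Differential DNA-methylation analysis for HELP-assay microarray data:
matched case/control scanning of log2(HpaII/MspI) ratio matrices with
permutation-calibrated significance, fold-change-weighted ranking,
genomic annotation, and power planning for follow-up studies.

## The problem

The HELP assay (HpaII tiny fragment Enrichment by Ligation-mediated PCR)
compares two genomic representations of the same sample: one cut by the
methylation-sensitive enzyme HpaII, one by its methylation-insensitive
isoschizomer MspI. Per genomic fragment, the ratio

&nbsp;&nbsp;&nbsp;&nbsp;x = log2(HpaII / MspI)

reports methylation state — x < 0 for methylated fragments (HpaII could
not cut), x > 0 for hypomethylated ones. Cohort studies of, e.g.,
intrauterine growth restriction assay ~10^6 such fragments in matched
case/control neonates and ask which loci shifted methylation.

The statistical obstacles this package addresses are (i) genome-wide
multiplicity with very small cohorts, handled by calibrating the
significance cut on a permutation null ("no locus in any relabeled
dataset got below the cut"), (ii) ranking loci when subtle mean shifts
matter more than variance flukes, and (iii) planning the cohort size a
future study needs when true effects are subtle (~0.6 log2 units against
within-group noise of ~0.32).

## What is implemented

* `io_model` — ratio matrices (TSV, `chrom:a-b` 1-based keys converted
  to 0-based half-open internally), sample sheets encoding the matched
  design, BED tracks, 6-column gene models.
* `synthetic_data` (`helpscan.synthetic`) — matched-cohort generator with
  bimodal baselines, planted per-locus shifts ~ Normal(0.60, 0.20) with
  random sign, noise SD 0.32, optional sex-linked loci, plus linked
  annotation tracks and bisulphite percent-methylation tables with known
  ground truth.
* `preprocess` — quantile normalization (rank-preserving,
  tie-averaging), median centering, all-pairs Pearson QC, Ward
  minimum-variance dendrograms (Newick output).
* `diffscan` — per-locus paired t-test scan, zero-threshold methylation
  state calls, within-pair sign-flip and full-relabel permutation nulls,
  the round-ladder threshold rule, the SAM-like ranking score
  |mean paired diff| / (sd of paired diffs + s0), two-tier candidate
  selection with p-value histograms.
* `annotate` — half-open interval overlap flags (CpG islands, CG
  clusters, conserved elements, repeats), strand-aware promoter
  (10 kb upstream of TSS) / gene-body assignment with bidirectional
  promoter calls, right-tailed hypergeometric enrichment scores,
  candidate-table reports.
* `power` — effect-size estimation from a scan's top loci; Monte Carlo
  and exact noncentral-t power of the two-sided equal-variance
  two-sample t-test; grid + sample-size recommendation.
* `concordance` — cross-platform agreement (array ratio vs bisulphite
  percent, expected strongly negative R) and site-level group tests.
* `pipeline` / `helpscan` CLI — one-seed reproducible orchestration of
  simulate → normalize → qc → scan → annotate → power → concord with a
  JSON provenance record.

The `analysis/` directory holds numbered drivers that run the full
narrative on the synthetic cohort and write tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_normalize_qc.py
python analysis/03_scan_candidates.py
python analysis/04_effect_size_power.py
```

which prints (abridged):

```
10000 loci x 10 samples; 100 planted differential loci
pairwise Pearson R range: 0.976 - 0.977 (high inter-sample consistency, ...)
permutation floor 4.06e-07 -> alpha* = 1e-07 (full_relabel, 200 permutations)
significant tier: 0 loci; moderate tier: 12
fraction of the top 100 rank-score loci that are truly planted: 0.50

Monte Carlo power (rows: per-group n; columns: alpha):
alpha  1.000000e-10  1.000000e-05  5.000000e-02
5             0.000         0.003         0.738
10            0.000         0.102         0.977
15            0.002         0.440         0.999
25            0.117         0.938         1.000
35            0.580         0.998         1.000
50            0.971         1.000         1.000
100           1.000         1.000         1.000

smallest per-group n with power >= 0.90 at alpha = 1e-5: 25
```

Reading this: with only 5 pairs, genome-wide calibrated significance is
nearly unreachable for 0.6-log2-unit effects (power 0.003 at alpha =
1e-5) even though the rank score still surfaces planted loci; a study
design needs about 25 subjects per group before subtle methylation
differences clear a genome-wide threshold with 90% power.

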