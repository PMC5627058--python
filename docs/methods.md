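# Methods

`meriptools` implements a comparative MeRIP-seq (m⁶A-seq) analysis for two
tissues with two biological replicates each, together with a synthetic-data
generator that provides ground truth for validating every stage. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic validation does and does not show.

## The measurement model

MeRIP-seq immunoprecipitates methylated RNA fragments with an anti-m⁶A
antibody and sequences them alongside a non-IP "input" library from the
same fragmented poly(A) RNA. Methylated intervals show locally elevated IP
coverage relative to input; the normalized IP/input coverage ratio ("fold
enrichment") over an interval is the working proxy for methylation level.
The method has fragment-scale (~100 nt) resolution: it cannot place
methylation at single-nucleotide resolution, and near transcript 5′ ends it
cannot distinguish internal m⁶A from cap-adjacent m⁶Am — which is why the
5′UTR-length diagnostic below exists.

All coordinates are transcript-space, 0-based half-open. One transcript
represents each gene (the longest; ties broken by transcript id for
determinism), because peak topology is only meaningful in a fixed
transcript frame.

## Read preprocessing

Four steps in fixed order, each idempotent:

1. **Adapter removal** — the read is cut at the leftmost position where a
   full-length copy of `GATCGGAAGA` matches with ≤ 2 mismatches.
   Only full 10-mer windows are considered; partial adapter prefixes at the
   3′ end are left alone (the simpler rule, exactly testable).
2. **3′ quality trimming** — the maximal trailing run of bases with
   Phred < 20 is removed; internal low-quality bases are kept.
3. **Retention** — keep reads strictly longer than 20 nt in which strictly
   more than 70% of bases have Phred strictly above 25.
4. **Mappability length filter** — keep reads strictly longer than 50 nt.

All thresholds are strict inequalities; boundary reads (length exactly 20
or 50, quality fraction exactly 0.70) are dropped. Zero-length reads are
dropped without computing the quality fraction.

## Expression

FPKM = count · 10⁹ / (length · total), computed from the pooled input
(non-IP) replicate libraries only; a fragment is assigned to the gene whose
selected transcript contains its midpoint (midpoint assignment avoids
double counting at boundaries). Genes with FPKM strictly greater than 0.2
are called expressed; a gene landing exactly on 0.2 is not.

## Peak calling

Windows of 100 nt tiled every 50 nt (fragmentation-scale resolution;
both configurable) cover each transcript; a transcript shorter than one
window gets a single whole-transcript window. A read counts toward every
window containing its midpoint. Per window the 2×2 table
`[ip, ip_total − ip; input, input_total − input]` is scored with a
one-sided Fisher's exact test (computed as the hypergeometric upper tail,
which is the same number), and fold enrichment is
`((ip + 0.5)/ip_total) / ((input + 0.5)/input_total)` — the 0.5
pseudocount keeps the ratio finite and mildly shrinks noisy low counts.
P-values are Benjamini–Hochberg adjusted across all windows of the sample
(genome-wide FDR, not per transcript); windows with q < 0.05 that overlap
or abut on one transcript merge into peaks.

A merged peak takes the minimum window q. Its fold enrichment is
recomputed from summed counts, **keeping the per-window pseudocounts in
the sums**: `(Σ(ipᵢ+0.5)/ip_total) / (Σ(inputᵢ+0.5)/input_total)`. This is
a weighted mediant of the window fold enrichments and therefore always
lies between their minimum and maximum; adding a single pseudocount to the
span totals instead can escape that envelope (two windows with ip=1,
input=0 give windows FE≈3 but a merged FE≈5).

The stage is exposed statsmodels-style: `PeakEnrichmentModel` holds the
window count table (`from_reads` builds it), `fit(fdr=0.05)` returns a
`PeakCallingResults` with the tested window table, the merged `Peak` list
and a text `summary()`.

## Replicate concordance and common/specific classification

Within a tissue, replicate peaks are concordant when their overlap exceeds
50% of the **shorter** peak's length (strict inequality; the denominator
is configurable — the shorter-peak choice is the permissive, symmetric
reading). Matching is best-overlap-first with each peak used at most once;
the emitted interval is the union, its level the mean of the replicate
log2 fold enrichments.

Across tissues, a concordant peak is

* **common** — it overlaps (≥ 1 nt) a concordant peak of the other tissue;
* **specific** — it overlaps no FDR-significant peak of *either raw
  replicate* of the other tissue (absence must be checked against the raw
  replicate calls, not only the concordant set);
* **ambiguous** — otherwise (present in exactly one replicate of the other
  tissue). The two defining criteria are not exhaustive; the explicit
  third label makes the partition total, and ambiguous peaks are excluded
  from downstream common/specific analyses.

Genes inherit labels from their (non-ambiguous) peaks: any common peak
makes the gene a commonly methylated RNA (CMR); otherwise specific peaks
of exactly one tissue make it a specifically methylated RNA (SMR) of that
tissue; specific peaks of both tissues make it `mixed`. CMR precedence and
the gene-level summary (mean of peak log2 fold enrichments) are
conventions — neither a precedence rule nor a gene-level aggregation is
forced by the definitions, so both are deliberate, documented choices.
Genes whose only peaks are ambiguous are not classified; genes with no
peaks are reported `unmethylated` when the caller supplies the gene
universe (e.g. all expressed genes).

Level comparisons (tissue vs tissue, CMR vs SMR, list vs all) report
medians of log2 fold enrichment and a two-sided Wilcoxon rank-sum p
(exact for small tie-free samples). Because CMR sets are typically much
larger than SMR sets, `subsample_control` redraws size-matched CMR subsets
(10 draws by default, seed-deterministic, without replacement) and reruns
the comparison, separating a genuine level difference from a
sample-size artefact.

## Peak topology

**Metagene profile.** Each of 5′UTR, CDS and 3′UTR is rescaled to 100 bins
(300 bins total; lncRNAs use 100 bins over the whole transcript). Each
peak contributes one count to the bin containing its midpoint — one bin
per peak, the conventional reduction. Bins are right-closed at exact
boundaries: a midpoint sitting exactly at fraction k/100 of its segment
belongs to bin k−1, so a midpoint at exactly half the CDS falls in CDS bin
49 (global bin 149). Profiles are percentages of all profiled peaks and
sum to 100 whenever at least one peak is profiled.

**Five regions.** 5′UTR, start-codon region, CDS, stop-codon region,
3′UTR, with thresholds read strictly (UTR "long" means > 100 nt, CDS
"long" means > 200 nt; boundary lengths fall to the short rules):

* long UTRs and long CDS: the codon regions are the 200-nt windows centred
  on the start/stop codons;
* a short UTR (≤ 100 nt) is absorbed into the adjacent codon region,
  which keeps its CDS-side half-window (min(100, ⌊c/2⌋) nt), preserving
  the 200-nt intent as far as the CDS allows;
* a short CDS (≤ 200 nt) takes precedence: the CDS is split at its
  midpoint into start-codon and stop-codon halves, the windows do not
  extend into long UTRs, and short UTRs still join the adjacent half.

The rules yield a disjoint cover of the transcript (property-tested over
all eight short/long combinations). A peak overlapping several regions is
assigned by priority stop > start > CDS > 3′UTR > 5′UTR.

**m⁶Am diagnostic.** `utr5_filter` reports the fraction of genes with
start-codon-region peaks whose 5′UTR is strictly longer than 100 nt;
cap-adjacent m⁶Am can masquerade as start-codon m⁶A only on short-5′UTR
transcripts, so a high fraction argues the start-codon signal is genuine
m⁶A.

## Motif enrichment

A count-based consensus scorer: overlapping k-mer occurrences (k = 5, the
GGACU/DRACH length) are counted in peak sequences and in a matched
background; enrichment is the pseudocounted frequency ratio and the
p-value a one-sided binomial upper tail at the background rate, BH
adjusted, ranked by q then enrichment. The default background draws
same-length windows from non-peak regions of the same transcripts, which
controls for transcript composition; a mononucleotide-shuffle background
is available. Reverse complements are never collapsed — methylation is
strand-specific. The scorer is a deliberate stand-in for PWM/EM motif
discovery tools; it recovers a planted consensus robustly but does not
produce position weight matrices or degenerate-motif logos.

## Gene-set overlays

External lists (one id per line, deduplicated, exact case-sensitive
matching; unmatched ids are counted and reported, not dropped) are joined
to per-gene peak tables. A list gene counts as methylated in a tissue when
it carries ≥ 1 concordant peak there — per-tissue status, independent of
the common/specific split. Outputs: percentage methylated, mean peaks per
methylated gene, the five-region distribution of the list's peaks, and
the list's log2 fold enrichments for ECDF and median comparisons against
all methylated genes.

## The synthetic-data generator

`SimConfig` defaults define the simulated study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 300 | genes, one single-exon transcript each |
| frac_lncrna | 0.10 | minority lncRNA class (no CDS, 100-bin profiles) |
| utr5/cds/utr3 ranges | 50–300 / 150–1800 / 50–400 nt | include UTRs < 100 nt and CDS < 200 nt so every edge rule is exercised |
| n_common / n_specA / n_specB | 150 / 25 / 25 | 200 truth peaks, 75% shared — the share the comparative analysis expects |
| peak_width | 200 nt | planted peak span |
| enrichment_fold | 8 | IP mean multiplier inside active truth peaks |
| base_depth | 50 | mean input reads per 100-nt window |
| dispersion | 100 | NB size r; var = μ + μ²/r |
| motif / motif_plant_rate | GGACT / 0.8 | consensus written at peak centres |

Counts per 100-nt tile are negative binomial; reads are 100-nt intervals
around uniform midpoints within their tile, so window re-counting recovers
the generating counts exactly away from transcript ends. Replicates are
independent draws; each generation stage uses its own seed stream, so any
stage is reproducible in isolation.

**Dispersion.** r = 100 (φ = 0.01) is technical-scale overdispersion. The
within-sample IP-vs-input contrast compares two libraries made from the
same tissue RNA, where the residual variation is library sampling, not
biological replication; biological variability enters the simulation as
independent replicate draws instead. This matters for interpretation: an
exact-test caller applied to a pair with biological-scale overdispersion
(r ≈ 10) overcalls badly (empirical FDR ~0.3 in this generator), so the
recovery guarantees validated here speak to within-sample technical noise
only. On real data with noisier input material the Fisher test is
anti-conservative, and count-model callers with estimated dispersion are
the appropriate upgrade — a known limitation of the exact-test design.

The generator also emits QC-stage FASTQ: exactly round(f·n) reads carry
the adapter (with 0–2 substitutions) at a random internal position, and
non-adapter reads are rejection-sampled to contain no window within the
trimmer's mismatch tolerance, making the planted fraction exact ground
truth. A configurable fraction of reads gets a trailing low-quality run to
exercise the 3′ trimmer and retention filter.

What the generator does **not** emulate: splice isoforms, genome-space
alignment (reads are emitted in transcript coordinates; the aligner is
external to this pipeline), sequencing errors, strand artefacts,
GC/mappability bias, and expression heterogeneity (all transcripts share
one base depth, so expression–methylation correlations are null by
construction in the default study). Passing the validation suite
therefore demonstrates correctness of the implemented operations under
the stated statistical model, not performance on real libraries.

## Numerical conventions and degenerate inputs

* GTF is 1-based closed on disk, converted to 0-based half-open in memory;
  BED is 0-based half-open; FASTQ is Phred+33.
* Empty p-value lists adjust to empty; a single p is its own q; ties are
  preserved by the step-up rule.
* Fisher p-values are computed vectorized as hypergeometric survival
  values (identical to the exact test by construction, verified in tests
  against exhaustive tail enumeration).
* `compare_levels` refuses empty sets; the expression–methylation
  correlation refuses < 3 methylated genes; `utr5_filter` and overlays
  refuse empty gene sets — silent NaNs are never returned.
* Metagene flatness is validated as an aggregate chi-square statistic
  within 3 SD of its expectation under uniformity (300 bins make a
  per-bin 3-SE criterion a guaranteed multiple-testing failure at any
  sample size).
* Validation problem sizes (300-gene study for recovery, 450-gene null
  for type-I control, 10⁴ midpoints for flatness, 10 seeds for motif
  recovery) are chosen so each check has clear statistical power while
  the whole suite stays quick on one CPU.

## Known limitations

* Fisher's exact test assumes no extra-binomial noise between IP and
  input; see the dispersion discussion above.
* Single-transcript, single-exon gene models: no isoform-aware topology,
  no spliced genome-space projection.
* The motif stage ranks exact k-mers only.
* Two tissues only; no differential-methylation model beyond rank-sum
  comparisons; no batch correction.
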