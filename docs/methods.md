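# Methods

This note records the models, defaults and numerical choices behind
`agsmeth`, and what the synthetic-data generators do and do not emulate.

## Synthetic data model

The generators exist so that every downstream stage can be tested against a
known ground truth without any sequencing data.

**Genome.** Sequences are i.i.d. bases with P(G)+P(C) equal to a target GC
fraction (default 0.42, a human-like value). Inside a planted skew block the
forward strand obeys P(G) − P(C) = skew · GC, so the windowed skew statistic
(G−C)/(G+C) converges to the planted `skew` value. Real genomes are of course
not i.i.d.: there are no CpG islands, no isochores, no repeats with biased
composition. Consequences: CpG density is uniform (~GC²/4 per bp), and digest
fragment lengths are geometric-like rather than the heavier-tailed real
distribution. Tests passing on these genomes demonstrate correctness of the
*algorithms*, not robustness to compositional heterogeneity.

**Methylome.** A domain plan assigns each genomic interval a label (HMD or
PMD) and a mean methylation level; defaults mirror the fibroblast study
design: HMD means in [0.60, 1.00] (default 0.85), PMD means in [0.25, 0.55]
(default 0.40). Per-CpG methylation probability is Beta-distributed around
the domain mean with concentration 30 (so an HMD at 0.85 has site-level SD
≈ 0.064). A pure Binomial at the domain mean would make segmentation
unrealistically easy; concentration 30 gives within-domain scatter comparable
to what smoothed WGBS tracks show. Read depth per CpG dyad is
Poisson(mean coverage), split Binomial(n, ½) between strands; zero-coverage
sites are dropped. Default coverage is 8× for the end-to-end study and 10×
for recovery experiments — the low-coverage regime the pipeline is designed
for is a few reads per site. Unmethylated cytosines read as C with the
bisulfite conversion-failure probability (default 0.005). Non-CpG cytosines
(CHG/CHH) are emitted unmethylated apart from conversion failures; to bound
table sizes only a seeded sample of them (default 20,000 sites) is emitted,
which is far more than the conversion-rate estimator needs.

**Peak sets.** The unit of occupancy is the restriction fragment. Fragments
are labeled common (positive in control and AGS samples), unique to one
sample, or absent; unique fragments can be placed with a relative weight on
fragments whose midpoint falls in a chosen feature (how intergenic bias is
planted). Two replicates per sample independently drop positive fragments
with a configurable probability; replicate merging is set union, so dropout
only removes a fragment from the merged sample when both replicates lose it.

**Clones.** Each clone is the bisulfite image of the amplicon: CpG cytosines
stay C when the site's Bernoulli methylation state is true, read T otherwise;
non-CpG cytosines convert to T except for conversion failures. No sequencing
error or chimeras are simulated.

All randomness flows from one master seed through named substreams
(`genome`, `methylome:<sample>`, `peaks`, `clones`, ...), so stages can be
re-run individually with identical results.

## Methylome QC and quantification

Plus- and minus-strand calls of a CpG dyad are summed into one record at the
plus-strand C; totals are conserved exactly. The conversion rate is
Σ(total−meth)/Σtotal over CHG+CHH cytosines. Coverage filtering discards CpG
units below 4× or above the sample's own 99.9th coverage percentile (linear
interpolation). One subtlety: re-computing the percentile on already-filtered
tie-free data can cascade (the new 99.9th percentile falls below the new
maximum), so strict idempotence of the rule as stated is impossible; the
filter therefore reports the cut it used, and re-application with that
recorded `upper_value` is a no-op. In practice the filter is applied once per
sample.

Regional methylation defaults to the coverage-weighted ratio
100·Σmeth/Σtotal rather than the mean of per-site percentages, because at
3–8× coverage per-site percentages are dominated by sampling noise; the
site-mean mode is exposed for comparison. Metaplots pool sites across
anchors (per-gene averaging is not the default); minus-strand anchors are
mirrored into transcriptional orientation, and bin 0 is the first downstream
bin.

The one-sided paired Wilcoxon signed-rank test (H₁: first sample less
methylated) drops zero differences, uses the exact null for ≤25 informative
pairs and the normal approximation with continuity correction beyond; the
test suite checks it against exhaustive sign enumeration.

## Domain segmentation

Observations are coverage-weighted methylation fractions in fixed 1-kb
windows; empty windows emit a missing symbol. 1 kb resolves the 25-kb
training regions while keeping ≥ a few dozen CpG observations per window at
realistic coverage. Emissions are discrete: K = 20 equal bins over [0, 1]
with add-one smoothing, trained from randomly drawn 25-kb regions stratified
by their weighted methylation — 25–55% regions train the PMD state, 60–100%
the HMD state, the (0.55, 0.60) gap is left unlabeled. Discrete emissions
keep training closed-form and mirror the discrete architecture of classic
genome-segmentation HMMs; a Beta-Binomial emission would model coverage
explicitly but would also be re-estimated iteratively, which the stratified
design deliberately avoids. Transitions are fixed, not re-estimated:
p(stay) = 1 − window/expected-domain-length with a 100-kb expected domain,
and the missing symbol contributes equal likelihood to both states so gaps
are decoded by the transition structure alone. Decoding is Viterbi in log
space with ties broken toward HMD (ties occur only in degenerate cases, e.g.
a switch point inside a run of missing windows, where the paths are exactly
equally probable). Domains shorter than 10 kb are absorbed, shortest first,
into the flanking domain with the closer mean methylation; count sums are
recombined so bp and counts are conserved and output labels alternate.

Training needs at least `min_pool` (default 200) regions per stratum and
fails loudly naming the stratum it could not fill (e.g. a uniformly
methylated genome has no PMD stratum).

## Peak universe and classification

The in-silico digest uses the five-enzyme cocktail of the standard DRIP
protocol (HindIII, EcoRI, BsrGI, XbaI, SspI; all palindromic, each
recognition site counted once) and is configurable; fragments tile each
chromosome exactly. A fragment is peak-positive when overlap/min(fragment,
peak length) ≥ 0.25 for some peak — the `min` makes short fragments inside
broad peaks positive; a 1-bp mode is available by setting the fraction to a
near-zero value. Classification: common = positive in control and ≥1 AGS
sample; control-unique = positive only in control; AGS-unique per subtype =
positive in the subtype and negative in control (a fragment may be unique to
several subtypes; it is reported per subtype and once in the pooled
AGS-specific union). Whether "unique" should also exclude other AGS subtypes
is genuinely open; the control-only definition is used and recorded in the
classification metadata.

## Enrichment statistics

The % length overlap statistic pools base pairs (100 · query∩feature /
query bp); a per-peak mean is exposed as an option. The null model replaces
every query peak with a length-matched interval drawn from inside the
*common* peak set — a common peak is chosen with probability proportional to
its number of valid start positions, then the start is uniform — which
controls for the base composition and location of peak-able sequence.
Genome-wide uniform placement is a separate operation used for domain
location analysis. The empirical p is (1+k)/(n+1) with n = 500 shuffles, so
the smallest attainable p is 1/501 ≈ 0.002; a result is flagged significant
under the joint rule p < 0.002 and fold change vs common deviating more than
20% from 1.

Direction handling: by default the p-value is computed in the direction of
the observed deviation from the null median. Because the direction is chosen
after seeing the data, this behaves like a two-sided test and rejects ~2α of
null datasets at level α; calibration experiments therefore fix the
alternative (`enriched`), for which rejection at α = 0.05 lands at the
expected ≈5% (the discrete attainable level is 25/501).

GC-skew blocks come from a deliberately simple windowed caller (not a full
HMM): 500-bp windows every 100 bp, |skew| ≥ 0.1, and a block requires at
least 7 consecutive qualifying windows of the same sign and 300 bp of span.
The sustained-run requirement is what keeps false calls on skew-free
sequence to a few percent of the genome while recovering planted 0.3-skew
blocks essentially whole; with isolated qualifying windows accepted, noise
alone would cover tens of percent.

Domain occupancy assigns each peak by its midpoint with the half-open rule
(a midpoint on a boundary belongs to the domain starting there); midpoints
in unsegmented gaps are reported as unassigned.

## Degenerate inputs and numerical conventions

Coordinates are 0-based half-open throughout; BED and bedGraph are emitted
0-based. Statistics that are undefined on their input (empty query, zero
CHG/CHH coverage, all pairs tied, all-missing site) raise a typed error or
return NaN with a flag rather than a default value. Zero fold-change
denominators are signalled as infinite fold, distinctly from an error.
Percentiles use linear interpolation. Viterbi runs entirely in log space;
emission pmfs are strictly positive after smoothing so no −∞ arises from
training.

## Problem sizes

The recovery experiments use a 10-Mb two-chromosome genome at 10× coverage
for segmentation (bp-level Jaccard of called vs planted PMDs ≥ 0.90 with
wide margin), 200 seeded datasets of 100 null peaks for Monte Carlo
calibration, 2,000 biased unique peaks on a 3-Mb genome for detection, and
an 8-Mb end-to-end study with one control and one AGS-like sample. These
sizes make every distributional check comfortably identifiable while the
whole suite runs in well under an hour on one CPU.

## Known limitations

- The i.i.d. genome model lacks CpG islands, repeats and isochore structure;
  enrichment results on real annotations will face correlated features the
  Monte Carlo null handles only through the common-set conditioning.
- The two-state HMM has no copy-number or replication-timing covariates and
  assumes a single global emission model per sample.
- The GC-skew caller is windowed, not model-based; its calls agree with
  planted blocks but are not a SkewR replacement on real genomes.
- Clone alignment assumes fixed-locus amplicons; heavily rearranged clones
  are rejected rather than locally re-aligned.
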