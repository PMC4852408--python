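# Methods

## Coordinate conventions and interval arithmetic

All coordinates are 1-based and inclusive at both ends — the convention in
which CNV tables print positions — so a span's size is `end − start + 1`.
BED input/output converts at the boundary (`start + 1` on read). Chromosome
labels are normalised by stripping a `chr` prefix; X/Y stay as letters.

Sizes in megabases are rounded half-away-from-zero to two decimals using
integer arithmetic (`(bp + 5000) // 10000 / 100`), which is exact and
reproduces printed sizes such as 1.00 Mb for a 996,392 bp span. Two rows of
the packaged table are known discrepancies between printed size and
coordinate-derived size (1q41: 0.16 vs 0.15 Mb; 9q34.2: 0.01 vs 0.00 Mb);
the fixture keeps both values and neither row is used to validate the size
arithmetic. Reciprocal overlap is `min(overlap/|a|, overlap/|b|)`; it is 1
exactly when the spans coincide.

## The copy-number HMM

The caller is a transparent five-state HMM standing in for the
black-box caller the underlying study used. States are integer copy numbers
0–4 with diploid CN2 as the null.

**Emissions.** LRR is Gaussian with per-state means −3.0, −0.45, 0.0, +0.30,
+0.55 and common sd 0.15 — standard literature values for SNP-array
intensities; all are overridable. BAF is a uniform density for CN0 (no
allelic signal) and otherwise an equal-weight mixture over the genotype
clusters attainable at that copy number (CN1: {0, 1}; CN2: {0, ½, 1}; CN3:
{0, ⅓, ⅔, 1}; CN4: {0, ¼, ½, ¾, 1}) with common sd 0.03. Components are
normals truncated to [0, 1]; the boundary clusters at 0 and 1 therefore act
as folded half-normals, which absorbs the point masses produced by clipped
homozygous markers. Mixture weights are equal rather than
genotype-frequency weighted: the decoder only needs the cluster *positions*
to separate states, and equal weights keep the emission model free of an
allele-frequency assumption.

**Transitions and priors.** A sticky diagonal with stay probability 0.999
and the remaining mass uniform off-diagonal; initial distribution 0.996 on
CN2 and 0.001 elsewhere. Transitions are not distance-scaled; at the 2.1 kb
median marker spacing of the emulated platform a constant per-marker switch
penalty is adequate, and distance scaling is a noted extension.

**Decoding and scoring.** Chromosomes are decoded independently by Viterbi
in log space. Maximal runs of a common non-diploid state become candidate
calls spanning the run's first to last marker. Each candidate is scored by
a log₁₀ Bayes factor defined as the summed per-marker emission
log-likelihood ratio of the called state against CN2 — a deterministic,
additive surrogate for a full marginal-likelihood Bayes factor, whose
computation the emulated caller never specifies. Ties in the Viterbi argmax
resolve to the lowest state index (numpy argmax), which is deterministic.

**Call and sample QC.** Candidates need ≥ 5 consecutive aberrant markers
and LBF ≥ 30 (the study's printed threshold, kept even though it is
stricter than common tool defaults). Samples with > 10 surviving calls or
LRR sd > 0.3 (sample sd, ddof = 1) fail QC and are dropped whole. The
">10 CNVs" rule is implemented as the fixed printed value rather than a
cohort-derived two-sigma threshold, which the phrasing leaves ambiguous.
Hemizygous X in males is not modelled; all samples use the diploid
baseline (a known limitation, not a correctness issue for the synthetic
cohorts, which are autosomal).

## Filter cascade

Criteria are evaluated as a conjunction, so evaluation order cannot change
survivors; tightening any threshold can only shrink the survivor set.

* **Telomere/HLA (I).** Exclude on ≥ 1 bp overlap with a single combined
  exclusion track (equivocal telomeric windows ∪ HLA region). The source
  phrasing "covered both … and …" read literally would almost never fire;
  OR over a combined track is standard practice.
* **Gene content (II).** ≥ 1 bp overlap with ≥ 1 gene interval.
* **Segmental duplications (III).** Excluded only when the *union* of
  segdup intervals covers every base of the call ("segdups only");
  partial overlap keeps the call but blocks qPCR confirmation downstream.
* **Control frequency (IV).** Fraction of distinct control samples with a
  same-type call at ≥ 50 % reciprocal overlap; exclusion is strict (> 1 %),
  so exactly 1 % survives. The denominator defaults to 1,307 and is a
  parameter, so desk-scale synthetic cohorts can override it.
* **DGV entries (V).** Count of same-type catalogue records at ≥ 50 %
  reciprocal overlap; > 10 excludes. The catalogue is a local TSV; no live
  database access.
* **Size gate** (genome-wide pass only). Rounded size ≥ 1.00 Mb. The gate
  compares the *rounded* two-decimal size because the reference survivor
  list reports a 996,392 bp call as a 1.00 Mb survivor; a raw
  `bp > 1,000,000` rule would contradict it.

The region-targeted pass re-evaluates calls overlapping (≥ 1 bp) a track of
previously disease-associated regions under criteria I–V with the size gate
lifted. A call that already survives genome-wide is reported only in the
genome-wide block (`pass_regional` false). This keeps the two survivor
blocks disjoint for *any* input — necessary because several genome-wide
survivors (22q11.1, Xp22.31) do lie inside listed disease regions — and
reproduces the reference 7 + 6 split. Frequencies are reported rounded to
4 decimals; the verdict object keeps the raw fraction.

## Trio segregation and ΔΔCt

Confirmability is `segdup_relation ≠ partial`. Parental carrier status may
come from parental qPCR copy numbers or from parental CNV calls at ≥ 50 %
reciprocal overlap (the pipeline's simulation mode uses calls). Labels:
maternal/paternal when exactly one parent carries, de novo when neither
does, not confirmed when either status is unknown. Both parents carrying is
reported as `biparental_ambiguous` rather than forced into a single-parent
label.

ΔΔCt: replicate Cts are aggregated by arithmetic mean (no outlier
rejection, no amplification-efficiency correction);
ΔΔCt = ΔCt(sample) − ΔCt(calibrator) with ΔCt = Ct(target) − Ct(reference),
and CN = 2·2^(−ΔΔCt), integerised half-away-from-zero. Copy number is
strictly decreasing in ΔΔCt with CN(0) = 2 exactly.

## Synthetic cohorts

The generator emulates a HumanOmniExpress-like platform. Marker gaps are
exponential with the scale set so the *median* gap is 2,100 bp — only the
platform's median spacing is known, and the exponential is the
maximum-entropy gap distribution given a median. Positions are drawn once
per genome and shared by all samples. Per sample, LRR is drawn from the
caller's state-conditional Gaussians (noise sd 0.15 by default) and BAF
from genotype clusters with binomial allele weights at allele frequency
0.5, Gaussian scatter sd 0.03, clipped to [0, 1]. Trio parents flagged as
carriers inherit the child's events verbatim. Planned events within one
sample must not overlap (config error otherwise). Every generator is a
pure function of (config, seed).

What the generator does **not** model: GC waves, batch effects, marker
call-rate failures, sex chromosomes, allele-frequency spectra, or the
platform's true (non-exponential) spacing distribution. Recovery results on
these cohorts are therefore an upper bound on real-array performance; the
cascade and segregation logic, by contrast, are exercised on exactly the
kind of annotated call tables they would see in production.

**Problem sizes.** Recovery experiments use one 4 Mb chromosome (~1,900
markers), 30-marker events at |LRR shift| ≥ 0.3, 20 replicate cohorts —
small enough to iterate on quickly, large enough that the binomial
uncertainty on a ≥ 95 % recovery criterion is well resolved (40 events,
20 null samples). The Viterbi optimality check enumerates all 5^n paths for
n ≤ 10 on 50 random emission instances.

## Packaged fixture

`cnvscreen.fixtures` ships the 13-CNV study table (coordinates, types,
carrier sex/phenotype, inheritance, printed control frequencies) plus
*synthetic* annotation: gene, segdup, exclusion and disease-region tracks,
DGV-like records and control-cohort carriers constructed so the cascade
reproduces the table's annotation pattern — per-call gene counts, partial
segdup overlap for exactly the three unconfirmable calls, and carrier
counts giving the printed frequencies at n = 1307. The printed frequency
0.0022 for the 22q11.1 duplication is not exactly reproducible (3/1307
rounds to 0.0023); the fixture stores the printed value as metadata and the
cascade reports the computed 0.0023. The disease-region track includes a
19q13.42 window (hosting one of the regional CNVs) although that band is
absent from the published prior-region list; the study's own regional
analysis evidently used a broader region set than the list it cites.
Decoy calls each violate exactly one cascade rule and never survive, and
removing them does not change the survivor set.

## Known limitations

* The LBF is an emission-ratio score, not a marginal-likelihood Bayes
  factor; its threshold (30) is comparable only in spirit to the original
  tool's.
* No sex-aware calling; hemizygous X events in males would be mis-modelled.
* The cohort-level discovery statistics of the original study (raw call
  counts, QC-failure counts) depend on real arrays and are out of scope;
  the property suites above replace them.
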