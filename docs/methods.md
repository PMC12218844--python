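# Methods

This note documents the models, estimators and numerical choices behind
`triodnm`, and what the synthetic-data generator does and does not emulate.

## Detection model

A candidate de novo mutation (DNM) is a biallelic SNV where both parents
are homozygous reference (0/0) and the offspring heterozygous (0/1). The
symmetric configuration (parents 1/1, child 0/1) would represent a
back-mutation of the alternate allele; these are vastly rarer than forward
mutations and are excluded, as is any trio with a missing genotype (counted
in the skipped-site log rather than silently dropped).

The filter cascade has three stages, each recorded in an ordered
per-candidate trail so the funnel is auditable:

1. **Site filters** — hard thresholds on the joint-genotyping INFO
   statistics. Defaults follow the widely published germline SNV
   recommendations: fail when QD < 2, FS > 60, MQ < 40, SOR > 3,
   MQRankSum < −12.5 or ReadPosRankSum < −8. A statistic absent from INFO
   passes with a logged warning by default, because rank-sum statistics are
   undefined wherever a genotype class is empty — exactly the
   homozygous-parent sites this pipeline lives on. Every threshold and the
   missing-value policy are config fields.
2. **Individual filters** — child depth inside (0.5·DP_trio, 2·DP_trio),
   where DP_trio is defined as the mean of the three members' depths at the
   site (a definition the estimator inputs need but that is genuinely open;
   the choice is config-replaceable); child allelic balance AB =
   alt/(ref+alt) within [0.3, 0.7], endpoints passing, since the removal
   conditions are the strict inequalities AB < 0.3 and AB > 0.7; genotype
   quality ≥ 20 for all three members; and at most one parental read
   carrying the child's variant. The AB filter applies to the child only;
   a config switch extends it to parents.
3. **Validation** — a deterministic stand-in for visual curation of
   alignments. A candidate is rejected when fragment evidence shows more
   than one parental read carrying its variant, or fewer than two child
   reads carrying it; candidates without any evidence are conservatively
   rejected as unvalidatable. FDR = rejected / all candidates entering
   validation, pooled across trios. Two human readers agreeing on a
   screenshot is not a reproducible computation; this rule is the
   documented, parameterised replacement.

Filter evaluation order affects only which failure is recorded first, never
the pass/fail set — each stage is evaluated unconditionally.

Sex chromosomes are excluded by a chromosome blacklist (default `chrY`,
`chrXIX`, the sex chromosomes of the target system).

## Rate estimators

Per offspring: µ = n·(1−FDR) / (2·CS·(1−FNR)). Pooled, zero-inflated:
µ = Σ n_curated / (2·ΣCS·(1−mean FNR)); offspring with zero curated DNMs
contribute callable size but no counts, which is what anchors the estimator
against upward bias in sparse cohorts. Since curated counts already have
validation failures removed, the pooled numerator carries no residual FDR
term.

**Callable genome size** counts sites where the child depth filter passes
and both parents are homozygous (reference *or* alternate — the definition
is about detectability, not about the violation pattern). On real-scale
data this requires per-site depth everywhere, so the simulator emits a
depth survey (every 997th base by default; a prime stride avoids aliasing
with any periodic feature) and CS is the survey pass fraction scaled by the
autosome total. The same callable rule restricted to a mask gives masked
callable sizes for stratified rates (CpG islands, repeats).

**FNR** uses obligate heterozygotes: at 0/0 × 1/1 parental sites the child
is heterozygous by inheritance, so the fraction of such children removed by
the AB window estimates the filter's loss directly. At depth d with
symmetric sampling this converges to the binomial tail
P(AB ∉ [0.3, 0.7] | Binomial(d, ½)), which the tests use as a closed-form
oracle. Fewer than 50 qualifying sites yields an explicit "unavailable"
status, never a silent zero.

**Shared DNMs** (identical family/chrom/pos/alt across full sibs) collapse
to one unique event for spectrum and landscape analyses but enter the
pooled numerator once per carrier offspring — each carrier's genome
independently carries the mutation, so per-genome rates must count it per
carrier while event-level statistics must not double-count.

**Confidence intervals.** Default: mean ± 1.96·SE across per-offspring
rates. Alternatives: a seeded nonparametric bootstrap over offspring, and
exact (Garwood, chi-square-based) Poisson limits on the pooled numerator.
The normal-SE default matches a per-trio-distribution view of the cohort;
the Poisson option is the right one for a single offspring or very sparse
counts (the normal method refuses n = 1 and points there).

**Pedigree verification.** Parent-offspring pairs are checked by
method-of-moments IBD estimation from IBS counts at sites with intermediate
allele frequency (frequencies estimated from all cohort samples), plus the
opposing-homozygote rate. A true parent-offspring pair has
(Z0, Z1, Z2) ≈ (0, 1, 0); |Z1 − 1| beyond a tolerance (default 0.35, wide
enough to absorb frequency-estimation noise in small cohorts) flags the
pair. Fewer than 200 usable sites is an explicit insufficient-data status.

## Spectrum and context

Mutations are collapsed onto the pyrimidine/A-reference strand, giving six
classes (A>C, A>T, A>G, C>A, C>G, C>T) with C>T at CpG dinucleotides split
out as a seventh; A>G and the two C>T classes are transitions. The
strong-to-weak test compares S>W vs W>S counts (S = C:G, W = A:T;
within-class changes excluded) against expectations proportional to the
callable GC and AT fractions — per-base mutational opportunity. All
chi-square statistics are the closed-form Pearson sum with upper-tail
p-values from the chi-square distribution.

**CpG islands** use the Gardiner-Garden–Frommer criteria: length ≥ 200 bp,
GC ≥ 50%, observed/expected CpG ≥ 0.6 with obs/exp = CpG·L/(C·G); all three
thresholds are config fields. An island is defined as the union of
overlapping *maximal satisfying intervals* (intervals meeting all three
criteria contained in no larger satisfying interval). The production scan
seeds candidate blocks from passing fixed-length windows and resolves each
block exhaustively using the fact that, with E(s) the largest satisfying
end for start s, the maximal intervals are exactly those (s, E(s)) whose
E(s) exceeds every earlier start's E. A quadratic all-substring
implementation of the same definition serves as the test oracle. One
property of the averaged criteria is worth knowing: a strong island can
"lend" GC to flanking sequence, so reported boundaries extend beyond the
truly CpG-rich core in proportion to its GC excess; on depleted (< 50% GC)
backgrounds the extension is bounded and islands remain well separated.
Merged unions are reported with their recomputed GC and obs/exp, which can
sit slightly below the thresholds their parts satisfied.

Islands are classified against gene models with priority
TSS > TTS > exonic > intronic > intergenic (TSS/TTS = ±500 bp around
transcript start/end), the regulatory classes taking precedence because
they carry the interpretive weight. DNM feature annotation translates
reference vs mutant codons (strand- and phase-aware from GFF3 CDS records)
into synonymous/missense; exonic-but-non-CDS positions in coding
transcripts are UTR; transcripts without CDS records are treated as
non-coding and excluded from effect calling. An invalid CDS phase demotes
the call to `exonic_unresolved` rather than guessing.

## Parent-of-origin phasing

An informative site is a heterozygous child site where enumeration of
consistent (paternal allele, maternal allele) assignments leaves exactly
one option — which requires at least one homozygous parent. Fragments
carrying the DNM alternate allele plus an informative-site allele vote for
the parent that allele maps to. The origin is called when the winning
parent has ≥ 1 vote and the other has 0 (both thresholds configurable);
any conflict yields "unknown". This deliberately conservative rule makes
phasing accuracy 100% on error-free data and makes the unknown fraction
monotone in the error rate. α = p/(1−p) with a Wilson binomial interval on
p transformed to the odds scale (the interval method is configurable; the
odds transform of a p-interval is monotone, hence exact).

## Landscape statistics

Windows default to 5 Mb advancing by 1 Mb; terminal windows shorter than
the window size are retained with their true length and flagged. Per
window: unique-DNM count (each DNM counted in every overlapping window),
recombination rate (Δgenetic / Δphysical from piecewise-linear
interpolation of the linkage map, clamped at map ends — no extrapolation),
CpG dinucleotide density, protein-coding gene density (genes assigned by
start coordinate so disjoint windows partition them; an overlap-weighted
mode would be the alternative), and callable bp. Pearson correlations carry
an autocorrelation caveat flag because overlapping windows are serially
dependent; no block correction is applied. Poisson GLMs
(count ~ factor, offset log callable bp, one factor per model) use
maximum likelihood via statsmodels; a constant factor short-circuits to
slope 0 rather than fighting the intercept. The mediation path analysis is
two OLS stages on z-scored window statistics — mediator ~ exposure, then
outcome ~ mediator + exposure — with the indirect effect as the product of
standardized coefficients and a Sobel test; a Poisson-GLM outcome stage is
available as a sensitivity variant. Collinearity beyond a condition-number
threshold logs a warning but still reports coefficients.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

- **Reference**: iid background at 44% GC with CpG depletion applied by
  relocating the G of 75% of CG dinucleotides to distant A/T positions
  (composition-preserving, creating no new CpGs; residual obs/exp ≈ 0.25).
  Designated island intervals are overwritten with CG-block sequence
  (block rate 0.2) hitting a requested GC, giving obs/exp ≈ 0.8–0.95.
- **Parents**: heterozygous sites at 10⁻³/bp per parent (a typical marine
  fish heterozygosity), hom-alt sites at a quarter of that rate so
  obligate-heterozygote (0/0 × 1/1) sites exist for the FNR estimator;
  Mendelian transmission per site per offspring.
- **Mutations**: per-offspring post-PGC counts ~ Poisson(2·L_eff·µ·(1−s))
  where L_eff weighs CpG bases by the rate multiplier (default 10, the
  order observed for methylated-CpG deamination) and s is the pre-PGC
  share (default 0.1; the number of primordial germ cells is not
  observable, so this is a free parameter). Pre-PGC events arrive per
  family as Poisson(2·L_eff·µ·2s) in one parent and transmit to each sib
  independently with probability ½, keeping the expected per-offspring
  count at 2·L_eff·µ regardless of s; events inherited by no sampled sib
  are dropped. Parent of origin is Bernoulli with odds α (default 1 — no
  sex bias). Alternate alleles follow a 55% transition share, with C>T/G>A
  deamination at 70% for CpG events. All events land where both parents
  are 0/0.
- **Observations**: depth ~ Poisson(45); alternate reads binomial with a
  per-read error channel (default 10⁻³); genotypes re-called by maximum
  likelihood over {0/0, 0/1, 1/1} with GQ as the phred gap to the
  second-best genotype, so miscalls emerge from the data. INFO statistics
  are drawn from the passing side of the default filters; injected
  artifact sites (child forced heterozygous; Poisson(0.5) per offspring)
  carry either ≥ 2 parental variant reads or thin child support in the
  fragment evidence so the validator catches them, and half receive a
  failing site statistic to exercise the earlier stage too.
- **Read evidence**: per DNM carrier, unlinked fragments covering the
  mutation on both haplotypes plus linked fragments tying the mutant
  allele to each polymorphic site within the fragment length (500 bp),
  consistent with the carrier haplotype, with per-base error flips.
- **Determinism**: every stage draws from a generator derived from
  (seed, stage index); identical configs give byte-identical output files.

What it does **not** emulate: read-level alignment artifacts (mapping
error, duplicates, strand bias — the INFO statistics are drawn, not
computed from reads), depth overdispersion (depth is Poisson, adequate for
exercising the 0.5×–2× window; a negative-binomial knob would be the
extension), indels and structural variants, sex chromosomes, linked
selection or any population structure in the parents. Passing tests
therefore demonstrate the correctness of the estimators and their error
corrections under the stated sampling model, not robustness to alignment
pathology.

### Problem sizes

Per-base simulations in the tests use 1–2 chromosomes of 50–500 kb with
planted rates of 10⁻⁵–5×10⁻⁴/bp so that dozens to thousands of events
exist at megabase scale; all rate machinery is per-bp, so results scale
with length. Rate-recovery experiments at the realistic callable size
(3×10⁸ bp, µ ≈ 5×10⁻⁹) use the event-level simulator, which samples
mutation counts and the detection funnel directly — a per-base genome adds
nothing to that question. The acceptance script averages the pooled
estimator over 50 event-level cohorts of 40 offspring to report a
Monte-Carlo-stable recovery value.

## Known limitations

- The IGV/two-reader visual curation step of real pipelines is replaced by
  a deterministic evidence rule; FDR estimates are only as good as that
  rule's resemblance to human curation.
- CS from a depth survey is a ratio estimate; with the default stride its
  sampling error is ≲ 1% at megabase scale and shrinks with genome size.
- The CGI definition's boundary-dilution property (above) biases island
  lengths upward relative to core CpG-rich spans.
- Window correlations are reported on overlapping windows without
  autocorrelation correction, flagged as such.
- The mediation analysis is associational; with observational window
  statistics the "direct/indirect" decomposition inherits all the usual
  caveats of path models.
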