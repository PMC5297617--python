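# Methods

## Design and estimands

The package targets a North Carolina design II: every one of *f* female
(CMS) inbreds crossed to every one of *m* male (restorer) inbreds, no
selfs or reciprocals, the *f·m* F1s grown in a randomized complete block
design with *r* replicates. The observation model is

y_fmk = μ + g_f + g_m + s_fm + b_k + e_fmk,

where g are general combining abilities (GCA), s the specific combining
ability (SCA) matrix under zero-sum constraints (Σ_f g_f = Σ_m g_m = 0,
every row and column of s sums to zero), b_k block effects and e plot
error. Literature on such trials often cites Griffing's method 2, but
that method includes selfed parents, which a CMS × restorer factorial
cannot produce; the estimators implemented are the line × tester /
two-way factorial least-squares ones, which are the standard adaptation
and coincide with the moment estimators on balanced data:

ĝ_f = ȳ_f·· − μ̂, ĝ_m = ȳ·m· − μ̂, ŝ_fm = ȳ_fm· − ȳ_f·· − ȳ·m· + μ̂.

Balance is a hard precondition: an incomplete cross × replicate table is
rejected with the missing cell named, and no imputation is attempted.
The ANOVA is the balanced two-factor-with-blocks partition
(SS_crosses = SS_female + SS_male + SS_female×male; error df
(fm−1)(r−1)); all systematic rows are tested against the error mean
square. Whether the original field analyses included block effects in
the effect estimates is immaterial on balanced data — marginal means are
unchanged — so blocks appear in the ANOVA while effects stay mean-based.

Parent comparisons use LSD = t(1−α/2, df_e)·√(2·MSe/n) at α = 0.01,
where n for a female's GCA mean is r·m (and symmetrically r·f for
males). The compact letter display is the deterministic maximal-runs
algorithm on means sorted descending: runs of means whose pairwise
differences all fall below the LSD get one letter, runs contained in an
earlier run are absorbed, and "a" always marks the top group. CV% is
100·√MSe / grand mean.

## Single-marker association with combining ability

Both parents are homozygous, so an F1's zygosity at a SNP is determined:
heterozygous iff the parents carry different alleles. Each site
partitions the design's crosses into heterozygous / homozygous /
excluded (a missing parental call excludes that parent's crosses at that
site); the three sets always cover the f·m crosses exactly. The response
is the per-cross mean over replicates. A locus is testable when both
groups have at least `min_group = 5` crosses — the floor is a package
choice to rule out degenerate 1-vs-80 comparisons. The test is a
two-sided two-sample t-test; Welch's form is the default (the pooled
form is available, and is the variant a mean-difference permutation test
reproduces). R² is the squared point-biserial correlation between the
group indicator and the response, which for the pooled statistic equals
t²/(t² + df). Locus heterosis is 100·(mean_het − mean_hom)/mean_hom,
undefined when the homozygous mean is zero. A significant locus
(p < α = 0.01, no multiple-testing correction by default,
Benjamini–Hochberg behind a flag) is classed favorable or unfavorable by
the sign of mean_het − mean_hom.

Per-trait summaries report the average percent heterosis two ways —
the mean of per-locus heterosis values, and the heterosis formula
applied to the cross-count-weighted pooled group means — because the two
differ whenever locus group sizes differ, and published tables of this
kind do not always say which convention they used. Parent-level counts
attribute a significant locus to every parent carrying the alternate
allele there. The functional filter keeps loci whose coding effect is
synonymous/missense/nonsense or whose region is a splice site.

### Calibration caveat (important limitation)

The t-test treats the per-cross means as independent draws, but under
the very model the trial is built on they are not: crosses sharing a
parent share that parent's GCA. The marker partition is itself defined
by parental genotypes, so group membership is clustered by parent and
the within-group variance underestimates the variance of the group-mean
difference. Measured by simulation with genotypes independent of
phenotype: with σ_gca = 1, σ_sca = 0.3, σ_error = 1 (r = 4) the nominal
α = 0.01 test rejects ≈ 11% of null loci; with the parental structure
removed (σ_gca = σ_sca = 0) it rejects ≈ 1.0%, confirming the statistic
itself is implemented correctly. A label-permutation reference suffers
the same miscalibration, because uniform label shuffles are not
exchangeable with genotype-induced partitions of clustered means. The
practical reading: single-marker scans of this kind over-declare
associations roughly in proportion to the GCA share of variance, and raw
P < 0.01 locus counts from such scans should be treated as enriched
candidate sets, not calibrated discoveries. The package reports both
null rates in its acceptance output rather than hiding the gap.

## SNP descriptive layer

Substitutions are transitions iff {ref,alt} ⊆ {A,G} or ⊆ {C,T} (4 of the
12 ordered pairs), otherwise transversions; the Ts/Tv ratio errors on
zero transversions. Window densities use 0-based half-open windows
[k·w, (k+1)·w) with w = 200 kb by default; a 1-based site at p falls in
window ⌊(p−1)/w⌋, and per-chromosome window counts sum to the
chromosome's site total for any w. Hotspots are windows with strictly
more than 30 SNPs (the strict inequality matters at exactly 30), sorted
by count descending.

The annotator assigns region by precedence exon > splice site > intron >
intergenic across overlapping gene models; splice sites are the first
and last 2 intronic bases (the common annotation-tool convention —
`splice_margin` is a parameter). Exon includes UTRs; coding effects are
computed only inside CDS, by rebuilding the reference codon from the
genome (strand-aware, minus-strand alleles complemented) and translating
the mutated codon with the standard table: same residue → synonymous,
new stop → nonsense, otherwise missense (a lost stop also falls in the
missense bin). Consequently per-parent region columns partition the
Total column, and synonymous + missense + nonsense ≤ exon, with equality
only when no exonic SNP is in a UTR. A FASTA/record ref-base mismatch
warns and annotates anyway.

Parent-level "SNP" accounting: one matrix column per (chrom, pos); a
parent's SNP total counts its homozygous-alternate calls, so group
totals sum parent rows and can far exceed the number of distinct sites —
this is how a survey can report ~39k SNPs at ~11k positions.

## Synthetic data

The generator emulates the study design rather than sequence evolution:

* **Genotypes.** Default 9 + 9 parents, 11,085 sites over the 12 rice
  chromosome lengths. Positions are drawn from a two-state window
  process: 3% of 200-kb windows are enriched 15-fold, which reproduces
  \>30-SNP hotspot windows at realistic overall density. Per-site
  alternate-allele frequencies are Beta(1.2, 3.5) (fixed-frequency
  option for calibration checks); parents are i.i.d. homozygous draws.
  Transitions are drawn with probability 1.4/2.4 so the simulated Ts/Tv
  ratio matches the ~1.4 reported for rice GBS surveys. Missingness is
  i.i.d. at 10% by default (GBS produces substantial missing data), with
  at least one observed call kept per site; the pre-missingness calls
  are retained in `meta["true_calls"]` so planted effects act on true
  zygosity — missingness is observational, not biological.
* **Phenotypes.** y = μ + g_f + g_m + s + Σ β·1[het] + b + e with
  Gaussian effects. GCA draws are centred and SCA draws double-centred,
  so the truth ledger satisfies the estimator's constraint convention
  exactly and noiseless recovery is exact to numerical precision. The
  default 12-trait set uses typical japonica trait means with σ scaled
  to the mean (σ_error = 6%, σ_gca = 4%, σ_sca = 2%, σ_block = 2% of the
  mean), putting residual CVs in the realistic 5–15% band.
* **Toy genomes.** Random non-overlapping multi-exon genes on both
  strands with ATG…stop CDS (length divisible by 3) and short UTRs,
  written as FASTA + GFF3 so the real file readers are exercised. Gene
  model simulation uses small toy chromosomes (default 2 × 60 kb;
  the CLI uses 12 × 300 kb) — codon-level annotation does not need
  genome-scale sequence.

What passing tests on these data do **not** show: the generator has no
linkage disequilibrium, no allele-frequency correlation between related
lines, no genotype × environment structure, and Gaussian effects
throughout, so real-data performance of the scan (especially its false
positive behaviour, see the calibration caveat) will differ.

## Numerical and interface choices

* Calls are int8 codes {0 hom-ref, 2 hom-alt, −1 missing}; TSV writes
  missing as ".". Sites sort by natural chromosome order then position.
* VCF reading uses cyvcf2 (biallelic SNP records only; het parental
  calls become missing by default, or drop the site via `drop_het`);
  GFF3 via gffutils; FASTA and codon translation via Biopython; t-tests
  via scipy; BH via statsmodels. The VCF writer is a minimal GT-only
  text emitter.
* Zero-variance equal-mean group comparisons define t = 0, p = 1;
  zero-variance R² is 0. SCA zero-sum and reconstruction identities hold
  to 1e-9 on balanced data and are asserted at that tolerance.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs are bit-reproducible.
* Acceptance-style measurements run at the design scale (9×9×4) with
  200 simulation replicates for recovery/power and 10⁴ locus tests for
  null-rate estimates; these sizes give Monte-Carlo error comfortably
  below the margins being checked.
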