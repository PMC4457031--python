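# Methods

## The genetic model

All mapping stages assume a monogenic, fully penetrant autosomal
recessive disorder segregating in a two-founder F2 intercross: one
founder from each of two divergent lines (called line A and line B
throughout; line B carries the mutation on one chromosome), one F1 × F1
full-sib mating, and a single F2 cohort.  Under this model affected F2s
are exactly those inheriting two copies of the mutant founder
chromosome at the causal position, unaffected:affected counts follow
3:1, and every affected individual is homozygous identical-by-descent
across the chromosomal segment surrounding the locus.

Coordinates are 1-based and closed everywhere in the library; interval
length is `end − start + 1` bp (BED output converts to 0-based
half-open on write).  Genotypes are B-allele dosages in {0, 1, 2} with
−1 as the missing sentinel; allele B is the alphabetically later allele
observed at a marker, a deterministic coding independent of file
format.

## Founder-origin inference

The haplotype reconstruction used in the original style of analysis is
replaced by a small hidden Markov model, which is sufficient in a
two-founder full-sib F2 where founder origin is nearly determined by
the data.  Per F2 individual, the hidden state is the ordered pair of
gamete origins ∈ {A, B}²; transitions per gamete between adjacent
markers use the Haldane map, r = ½(1 − e^(−2d)), with d from the map
(cM) or from physical distance at 1 cM/Mb; emissions take the line's
alt-allele probability at a marker as half the founder's dosage (0.5
when the founder call is missing), mixed with a genotyping-error rate
(default 0.01, deliberately larger than the simulated chip error so
single miscalls do not flip segments).  Posterior decoding assigns:

- an **origin dosage** (count of line-B gametes, 0/1/2) from the
  dosage-class posterior, called when the winning class has posterior
  ≥ 0.95, else unassigned;
- ordered per-gamete labels where the marginals are decisive.  The two
  gametes of an F2 are not individually identifiable from unphased
  dosages (both F1 parents carry one chromosome of each line), so in
  heterozygous-origin stretches only the dosage is identified — it is
  also the only quantity the downstream scan consumes.

The association scan regresses the binary phenotype on origin dosage
per marker (slope t test, two-sided); a Welch two-group variant
(homozygous-A vs homozygous-B origin) is available because the original
grouping convention is not recoverable.  Markers with unassigned
dosage in more than half the scanned individuals, or constant dosage,
are skipped and excluded from the Bonferroni denominator; significance
is declared at p ≤ α/N with α = 0.05 over the N markers actually
tested.

## Fine mapping

`shared_homozygosity_scan` finds maximal runs of consecutive markers at
which every affected individual is homozygous for the same allele.
Missing calls are compatible by default (a strict mode breaks runs
instead).  Up to two consecutive incompatible markers are bridged when
compatible markers flank them: with ~18 affected individuals and a
per-genotype error rate of a few per mille, a marker has a ~4% chance
of being spoiled by a single miscalled genotype, and one spoiled marker
is far more likely an artifact than two recombination events in the
same tiny window; bridged markers carry no resolved haplotype allele
and do not count toward the run's marker total.  Ties among runs are
broken by marker count, then bp span, then lowest coordinate.

The end-to-end pipeline (`map_recessive_locus`) runs the homozygosity
stages on **all position-known markers**, not only the QC'd set: a
family-monomorphic marker is useless for association but still tells
you the affecteds are homozygous-identical there, and dropping such
markers systematically stops the marker hull short of the true
breakpoint.  Among candidate runs it selects the one overlapping the
**descent core** — the longest stretch where every affected is
homozygous line-B by inferred origin — the in-silico analogue of
verifying that the shared haplotype descends from the carrier founder,
and constrains the segment to that core.  This guards against long
shared-by-state runs in regions where the founder lines are weakly
diverged.

`refine_by_carrier_recombinants` trims the interval with unaffected
individuals **known** to carry the mutation.  A marker is excluded when
a carrier's state there is resolvable and incompatible with the locus:
its disease-line chromosome is absent (recombined away) or carries the
normal allele (homozygous-normal genotype with one line-B gamete), or
the carrier is homozygous for the disease haplotype (it would be
affected were the locus there).  Because a real recombinant segment
spans several markers, an exclusion only counts when the same carrier
excludes ≥ 2 markers within a 5-marker window; an isolated exclusion is
treated as a single miscalled genotype.  The refined interval is the
remaining run containing the anchor (or the longest); the default
boundary convention is conservative ("inner": limits on the first
non-excluded markers), with a midpoint option since the true breakpoint
falls between markers.

Carrier certainty matters: the default pipeline uses only obligate
carriers (parents of affected individuals, heterozygous by necessity).
A state-based certification of F2 carriers — genotypes compatible with
one complete disease-haplotype copy across the interval — is available
(`find_carriers(..., include_certified=True)`) but can be fooled where
the interval is weakly informative, so it is opt-in.  When carrier
status is known externally (e.g., after genotyping the candidate
variant), supplying those carriers roughly halves the interval in
simulation while retaining the locus.

## Variant exclusion cascade

Site QC keeps variants with depth in [6, 70] and quality ≥ 20
(inclusive bounds), and removes a variant closer than 5 bp to the
previous seen variant.  The depths are per-site unique-read depths
after deduplication, which is why they sit far below raw sequencing
coverage.  The recessive trio cascade then removes, in order: variants
not homozygous-alt in the affected offspring; variants homozygous-alt
in a parent (an unaffected obligate carrier cannot be homozygous
mutant); Mendelian-inconsistent variants (a homozygous-reference parent
cannot have transmitted the alt allele to a homozygous-alt child); and
variants outside the protein-altering classes.  A missing genotype at
the sample a step evaluates removes the variant at that step — never a
silent pass.  Functional classes are taken from the input annotation
(INFO key `FC`); annotation engines are out of scope.  The surviving
set is screened against a panel of presumed non-carriers: alt frequency
> 0.1 removes, zero retains, (0, 0.1] retains with an "ambiguous" flag.
Every filter records a trace whose counts conserve at each step.

The in-silico PCR-RFLP digest cuts after `cut_offset` bases of each
recognition-site occurrence; bottom-strand occurrences are cut at the
mirrored offset, and a palindromic site (e.g. SmaI's CCCGGG) is one
binding event, never two cuts.  Truncation prediction applies a
(position, deleted, inserted) edit to a CDS and reports the first stop
codon of the edited frame when it shortens the protein relative to the
unedited translation.

## Expression statistics

RPKM is `1e9·C/(N·L)`.  Equal expression between the two libraries is
tested conditionally on the wild-type count: under equal expression the
mutant count given x follows
`p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^{x+y+1})`, a
negative-binomial law with x+1 successes and success probability
N1/(N1+N2).  Pointwise terms are computed in log space (gammaln) and
tails through the negative-binomial CDF/SF, so no count overflows.  The
two-sided p doubles the smaller inclusive tail; a min-likelihood
variant is config-selectable because the exact two-sided convention for
this test is not standardized.  Note the doubled inclusive-tail p is
symmetric under sample swap only up to the observed points' probability
mass; the identity `P(Y>y|x; N1,N2) = P(X≤x|y; N2,N1)` bounds the gap.

DEG calling excludes genes with zero counts in both libraries, treats a
zero in exactly one library as passing the fold-change criterion (its
log2 ratio is infinite), and declares significance at FDR ≤ 0.001
(Benjamini–Hochberg, via statsmodels) **and** |log2(RPKM_wt/RPKM_mut)|
≥ 1, both boundaries inclusive, applied as a simultaneous conjunction.
Direction labels are relative to the mutant library.  The 2^−ΔΔCt qPCR
fold change normalizes the target gene's mean Ct to a reference gene
per group and calibrates to the wild-type group.  Over-representation
of a query set in annotated gene sets uses the upper-tail
hypergeometric p with BH correction across sets.

## Synthetic data: what it emulates, what it does not

`simulate_f2_cross` draws per-line marker allele frequencies from a
Balding–Nichols model (default F_ST 0.3 between the founder lines,
chosen as a realistic divergence for distinct breeds), builds four
founder haplotypes, and performs meioses with crossovers as a Poisson
process under the Haldane map (no interference, 1 cM/Mb).  The causal
mutation rides on a single line-B founder haplotype; the maternal
gametes of both F1s are conditioned to carry it (otherwise the family
could not segregate the disorder — the conditioning mirrors
ascertainment of an affected family).  Chip noise is a uniform dosage
flip (default 0.002) plus independent missingness (default 0.02).
Defaults (75 F2s, 1,000 markers on a 100 Mb chromosome) reproduce the
scale of a single-chromosome slice of a 60K-chip family study; a
simulated study yields a shared IBD segment of ~5 Mb median, matching
what ~10–20 affected meioses resolve.

`simulate_trio_variants` plants one truncating variant that is
homozygous-alt in the affected, heterozygous in both parents, and
absent from the 24-animal panel, among background variants in six
categories (one per exclusion step plus QC fodder); with the default
proportions ~15 background variants survive the Mendelian cascade and
segregate in the panel at realized alt frequency > 0.1 (the draw is
conditioned on that realized property).  `simulate_counts` draws
Poisson counts with rates proportional to expression × length scaled to
the library size; planted genes multiply the mutant rate by 2^±log2fc
without renormalizing, so the mutant library total drifts with the
planted signal exactly as sequencing depth would.
`simulate_ranked_lists` shares a latent score across lists
(`c·base + √(1−c²)·noise`) with a fixed boost for signal genes.

Passing tests on these generators show the algorithms recover planted
truth under the stated statistical model — Poisson counts, independent
chip errors, no phenocopies, full penetrance, a single causal locus.
They do not show robustness to overdispersed RNA counts (no biological
replicates are modeled; a negative-binomial misspecification hook
exists in the generator design space but multi-replicate dispersion
modeling is out of scope), to segregation distortion, to pedigree
errors, or to incomplete penetrance (config-exposed but off by
default).

## Numerical and convention choices

- Chi-square tests (segregation, HWE) are Pearson without continuity
  correction; HWE is computed on all genotyped individuals by default —
  an F2 family deviates from HWE by design, but the 1e-6 removal
  threshold only catches genotyping artifacts.  Removal thresholds are
  strict inequalities (a marker exactly at a threshold is kept).
- Fisher's exact test, hypergeometric tails and BH adjustment go
  through scipy/statsmodels; the test suite checks them against
  exhaustive enumeration oracles on small inputs.
- Top-k in rank consensus uses ceiling of fraction × list length, so
  no floor/ceiling convention could exclude a gene; lists of different
  lengths each contribute their own top fraction.
- The human-variant damaging-score default 0.85 reflects the
  conventional "probably damaging" band of protein-impact predictors;
  conservation default 1.0 ("fully conserved") with a relaxed option.
- Problem sizes in the test suite and acceptance script (25 simulated
  crosses of 75 F2s × 1,000 markers; 20 null + 5 signal count
  simulations of 2,000 genes; enumeration oracles to margins of 30)
  were chosen to estimate each operating characteristic stably while
  keeping a full run in the low tens of seconds.

## Known limitations

- Shared-homozygosity detection is by state, not by descent; in regions
  of weak founder divergence, state-sharing can extend past the true
  IBD boundary.  The descent-core constraint mitigates but cannot fully
  remove this, and ordered gamete origins remain unidentifiable in
  heterozygous stretches.
- The refinement's homozygous-disease exclusion can in principle be
  defeated by a second line-B haplotype that mimics the disease
  haplotype's alleles locally — the same ambiguity that limits any
  state-based homozygosity mapping.
- The association scan treats the binary phenotype with a linear trend
  test; with perfect cosegregation the t statistic saturates and ties
  across a plateau of markers are resolved arbitrarily.
- Multiallelic variants are split or rejected, never jointly modeled;
  indel realignment and annotation are out of scope.
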