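# Methods

## Scope and model

`suppscreen` implements the computational arm of a clonal haploid suppressor
screen: rule-based single-nucleotide variant calling from per-site base
counts, control subtraction, codon-level effect annotation, and cross-strain
triage into pathway categories. There is no probabilistic calling model; the
method's premise is that in a clonal haploid isolate a real mutation sits at
allele frequency ≈ 1, so inclusive count/frequency thresholds plus two
discard rules (multiallelic loci, alleles present in the parental controls)
separate private mutations from noise and ancestry. All coordinates are
1-based inclusive (GFF3/VCF convention); only the standard nuclear codon
table is supported.

## Calling rules and their edge cases

* Thresholds are inclusive on both components (`count ≥ k` and `AF ≥ f`).
  Presets: `pairwise` (5, 0.25) and `batch95` (20, 0.40); the control
  cutoff is AF ≥ 0.1 in any control, compared allele-specifically.
* Allele frequency uses total post-filter site depth (all four bases) as
  the denominator; a zero-depth record has AF 0 for every allele, so
  uncovered sites can never generate calls. A site absent from a control's
  records is treated as control AF 0.
* The multiallelic rule operates locus-wide across every sample of the
  experiment (controls included): two distinct alternate alleles passing
  thresholds anywhere discard the locus. A per-sample scope is available via
  `multiallelic_scope="sample"` for sensitivity analysis.
* Monotonicity: the threshold-candidate set is monotone in the thresholds
  (raising either component only removes candidates). The *final* pass set
  is not strictly monotone in pathological configurations: raising a
  threshold can drop a competing allele below it, un-flag a multiallelic
  locus, and thereby admit the remaining allele. The pass set is provably
  nested across thresholds on every locus that is not multiallelic at the
  looser setting, and the test suite asserts exactly these two properties
  plus empirical nesting of the two presets on simulated screens, where the
  borderline two-allele configuration does not occur.

## Effect annotation

Variants are mapped into codons by ORF coordinate arithmetic (minus-strand
variants are reverse-complemented into the coding frame) and classified by
amino-acid comparison: synonymous; nonsense (alternate codon is a stop);
stop-loss (reference codon is the stop, alternate is not); start-loss
(codon 1 no longer Met); otherwise missense. Any codon containing N is
`unannotatable` rather than guessed. Variants in overlapping ORFs yield one
record per ORF; summaries use the most severe effect
(nonsense > start_loss > stop_loss > missense > synonymous).

Truncation length for a stop-gain is `protein_length − stop_codon_index`,
i.e. the residues strictly C-terminal to the premature stop: a stop at
codon 456 of a 796-residue protein removes the last 340 residues. The
inclusive alternative (counting the stop position itself) appears in some
published allele descriptions; this package standardizes on the exclusive
convention throughout. Protein changes are labelled in screen style
(`Q102STOP`, `H235A`), not HGVS, for direct comparability with allele names.

## Triage

The stringent AF ≥ 0.7 nonsilent filter defines prioritized mutations and
the per-gene recurrence table (counting strains, not variants; ranked by
strains-with-nonsilent-hit, ties lexicographic). The relaxed AF ≥ 0.4
filter feeds pathway assignment in the fixed order Rph1 → Rpd3L →
chromatin silencing → mRNA decay → hyperresistance; the first category with
a gene-set hit wins, all matching variants are kept as evidence, and an
assignment whose evidence is below the strict tier is flagged.
Hyperresistance is a growth phenotype and enters only through an externally
supplied strain list. Mutations outside ORFs never contribute to
assignment.

## The synthetic screen generator

The simulator produces the statistical structure the analysis assumes, not
realistic yeast sequence. Defaults are the screen's study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_suppressor_strains` | 95 | sequenced suppressor isolates |
| `n_control_samples` | 2 | unselected parental controls |
| `background_nonsilent_mean` | 14 | Poisson mean of nonsilent coding mutations per strain |
| `background_silent_mean` | 10 | Poisson mean of synonymous coding mutations per strain (free parameter; not a reported quantity) |
| `ancestral_variant_count` | 50 | variants shared by every sample, controls included |
| `coverage_mean`, `coverage_dispersion` | 200, 10 | negative-binomial depth per emitted cell (overdispersed coverage) |
| `error_rate` | 1e-3 | post-Q30 per-base substitution rate, split equally over the three non-reference bases |
| `af_beta_a`, `af_beta_b` | 49, 1 | Beta(49, 1) true allele fraction (mean 0.98) for clonal variants — residual mapping noise around AF = 1 |
| `multiallelic_noise_rate` | 1e-5 /bp | injected two-allele artifact sites exercising the discard rule |
| `genome_length` | 540 kb | one contig, densely packed with ORFs |

Causal mutations are single-base stop-gains planted in a gene drawn from
configurable category probabilities (defaults: Rph1 0.15, Rpd3L 0.30,
chromatin silencing 0.10, mRNA decay 0.10, other 0.35 — the Rpd3L pathway
dominating, as in the motivating screen). Background mutations are drawn
per coding base and verified nonsilent (or synonymous) against the codon
table at construction, independently of the annotation module that is later
tested against them.

Three deliberate departures from naive realism, all scale corrections:

* **Compressed genome, preserved dilution.** The toy genome is ~0.5 Mb
  instead of 12 Mb. Pathway genes are short (30 codons) against 1500
  100-codon background genes so that the fraction of coding bases in
  pathway genes (~0.5%) approximates genome-scale dilution (~25 genes of
  ~6000); this ratio is what keeps background mutations from spuriously
  hitting pathway gene sets during assignment.
* **Unique truth positions.** Truth-variant positions are drawn without
  replacement genome-wide. At 1/24 of the real genome size, coincidental
  same-site collisions between independent strains would be ~24× more
  frequent than reality and would spuriously trigger the multiallelic
  discard; unique placement restores genome-scale collision statistics.
  The one sanctioned exception: a causal (position, alt) pair may recur
  identically across strains — recurrent identical suppressor mutations are
  real and drive the recurrence analysis.
* **Sparse emission.** Only (site, sample) cells with non-reference
  evidence are emitted, plus every sample at every truth site; absent cells
  mean homozygous reference. A dense matrix would be ~50M cells with no
  information content.

Backcrossing is not modeled as allele-frequency dilution (isolates are
purified clones); it is reflected only in the background mutation count.

What passing tests therefore do **not** show about real data: robustness to
alignment artifacts (indels, repeats, mapping bias beyond the Beta AF
model), quality-score miscalibration, contamination, aneuploidy, or
structural variation. The simulator validates the *rules*, not the upstream
read processing.

## Survival statistics

Relative survival is `100 × strain / control` with the control measured the
same day; a zero control is undefined and raises. The group test is the
classical equal-variance (Student's) two-sample t, two-sided, df =
n₁ + n₂ − 2, wrapping `scipy.stats.ttest_ind` with explicit degenerate
conventions: zero pooled variance gives p = 1 for equal means and p = 0
(t = ±∞) otherwise. Significance tiers are reported as in the source
figure legends: `*` p < 0.05 and `**` p < 0.005 (the printed tier, not the
conventional 0.01). Welch's correction is deliberately not applied — the
named test is Student's.

## Numerical and testing choices

* Determinism: every stochastic component derives from
  `numpy.random.default_rng([seed, stream])` with fixed stream offsets;
  identical config + seed reproduces byte-identical files (asserted).
* The caller is vectorized (pandas/numpy) and is verified exactly against a
  literal loop-based implementation of the three rules on 1000+ random
  loci; the annotator is verified against the simulator's independent
  codon-table constructions on 10⁴ cases with full strand-mirror
  invariance.
* Problem sizes in the test suite: the full default screen (95 strains,
  ~0.5 Mb, 200×, ~9.7M count records) is simulated once per session in
  ~40 s within ~2.5 GB; unit tests use 20–25 kb screens.
* Depth draws are floored at the number of error/alt reads in the rare cell
  where the drawn depth falls below them, which adds a negligible upward
  bias (<1 read) to mean depth; the distributional test allows for it.

## Known limitations

* No indels, multi-nucleotide variants, structural variants, or splice
  effects; single intronless ORFs only; one codon table.
* The caller implements thresholds only — no statistical test per site, no
  p-values; this is faithful to the method it reimplements.
* Pathway assignment resolves gene sets from static GMT files, not a live
  GO service, and cannot reproduce phenotype-based (hyperresistance)
  assignments without an external strain list.
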