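# Methods

## The inference problem

A tetraploid plant (2n = 4x) scored with a codominant marker such as an
SSR can transmit its alleles in two qualitatively different ways:

* **Disomic inheritance** (allopolyploid behaviour): chromosomes pair
  strictly as bivalents within subgenomes, so each locus behaves like a
  diploid locus. Selfing a heterozygote *Aa* gives progeny genotypes in
  the ratio 1 *AA* : 2 *Aa* : 1 *aa*, hence band phenotypes
  1 upper : 2 double : 1 lower.
* **Tetrasomic inheritance** (autopolyploid behaviour): all four
  homologues pair and segregate at random. A two-band parent may be
  simplex (*Aaaa*), duplex (*AAaa*) or triplex (*AAAa*), giving selfed
  band-phenotype ratios 3:1, 1:34:1 and 1:3 respectively.

Because these expected ratios differ sharply, chi-square goodness-of-fit
tests on selfed (S1) progeny counts discriminate the modes. The package
implements the full chain: exact expectation engine → per-locus GOF →
classification → distortion scan → four-band decomposition → synthetic
population generator, and ships the per-locus counts of the two
bermudagrass S1 study populations (228 'Zebra' progenies × 21 loci; 273
A12359 progenies × 12 SSRs) so every analysis runs offline.

## Exact segregation engine

All model-side probabilities are `fractions.Fraction`; every distribution
(gametes, zygotes, phenotypes) sums to exactly 1 with no tolerance.
Floating point enters only in the chi-square statistic and p-values. This
is deliberate: the quantities of interest (1:34:1, 1:14:1, 4/7) are exact
combinatorics, and exact rationals make the oracle tests sharp.

**Tetrasomic gametes.** Under random chromosome segregation a gamete is
an unordered pair drawn from the four homologues, all C(4,2) = 6 labelled
pairs equally likely. A double-reduction component is exposed as a rate
α ∈ [0, 1/6]: with probability α the gamete is instead a doubled copy of
one homologue chosen uniformly. The default, and the only value used in
the headline analyses, is α = 0 — the 1:34:1 duplex ratio holds only
there, and the homozygous-gamete probability increases strictly with α
(tested). The 1/6 ceiling is the maximum under complete equational
segregation.

**Disomic gametes.** Each subgenome locus transmits one of its two
alleles with probability 1/2, independently across loci; a gamete is the
tuple of transmitted alleles.

**Selfing** is the self-convolution of the gamete distribution. Zygotes
are canonicalised as sorted allele multisets in both modes — a disomic
zygote's per-locus structure is always recoverable from the parent model,
and band phenotypes depend only on which alleles are present — so
distribution keys are unique and order-independent.

**Phenotype collapse.** A genotype's band phenotype is its set of
distinct band labels after applying an *alias map* (allele → band,
many-to-one). The alias map is an explicit input, identity by default.
Comigration of alleles from different subgenomes is expressed through it:
with A≡B (upper) and a≡b (lower), selfing the two-locus parent *Aa/Bb*
yields the single-marker ratio 1:14:1, and the seven dual-subgenome
parental configurations (*AA/Bb* … *aa/Bb*) yield 1:3, no segregation,
1:14:1 or 3:1 — with exactly 4 of 7 giving a 3:1-type two-class ratio.

**Band labels and rendering.** Bands are labelled by decreasing size
(upper band first): `A` > `a` at two-band markers, `a` > `b` > `c` > `d`
at multi-band markers. Single-band homozygotes at two-band markers render
doubled (`AA`/`aa`), matching gel-scoring convention; multi-band patterns
render as sorted letter sets (`abc`). Class order in ratio output is
lexicographic under the band-size order, which puts the upper homozygote
first and the lower homozygote last.

## Goodness of fit and classification

`chisq_pvalue(x, df)` is the regularized upper incomplete gamma function
Q(df/2, x/2) (`scipy.special.gammaincc`); tests check it against the
closed forms exp(−x/2) at df = 2 and erfc(√(x/2)) at df = 1 to 1e-10.

`chisq_gof` uses the conventions under which the archived per-locus
statistics recompute exactly:

* missing calls are tallied separately and never enter n;
* expected counts are n·p from the exact phenotype distribution, or an
  explicit expected-count vector (used to reproduce pooled tests computed
  from one-decimal rounded expectations);
* a class with expected 0 is dropped only when it is also observed 0;
  an observation in a zero-expectation class rejects the model outright
  (p = 0, flagged `impossible`);
* df = retained classes − 1; no continuity correction, no
  multiple-testing adjustment by default (thresholds 0.05 and 0.01 are
  both reported by the distortion scan).

A test with fewer than two informative classes raises rather than
returning a meaningless statistic; the classifier treats a
single-support model (e.g. a non-segregating configuration) as a trivial
fit iff all observations fall in its class.

`classify_locus` fits each named hypothesis (1:2:1, 1:34:1, 3:1, 1:3, and
the dual-subgenome disomic 3:1) and returns the common mode of the
fitting models, `ambiguous` when both modes fit — a 3:1 ratio genuinely
is, since tetrasomic *Aaaa* and dual-subgenome *aa/Bb* both produce it —
or `distorted` with the nearest model (largest p-value, ties to listed
order) when none fits.

**Four-band decomposition.** A marker showing four parental bands is
either one tetrasomic locus *ABCD* (19 selfed genotypes, 11 phenotypes)
or two independent disomic loci (9 phenotypes; the pair-homozygote
patterns `ab` and `cd` are impossible). The decomposition scores each of
the 3 ways to split the labels into two pairs by how many observed
progeny carry a pattern with no band from one pair, picks the split with
the fewest such impossible observations (ties raise; a configurable limit
rejects hopeless data), and emits two 3-class count tables. On the
bundled four-band data the split {a,b}|{c,d} wins with 0 impossible
progeny versus 29 and 28 for the alternatives. Note the decomposed
marginal counts (104/125/43 and 14/167/91) are what the joint phenotypes
imply; the separately archived per-locus rows for the same marker were
rescored differently at source and differ by a few progeny.

**Selfed-progeny verification** applies a subset rule per progeny: selfed
iff, at every non-missing marker, every progeny band occurs in the self
parent's pattern (hence no band exclusive to the pollen-contaminant
parent). All-missing rows are indeterminate: flagged and excluded, not
counted either way.

## Synthetic populations

The generator draws progeny genotypes from the exact selfing
distribution, reweighted by genotype-specific zygote viability and
renormalised. Viability selection is the distortion mechanism modelled —
a marker linked to a recessive lethal loses homozygote classes — and it
acts at the zygote level only; gamete-level selection is out of scope.
One consequence worth stating: making the *AA* class fully lethal at a
disomic locus turns 1:2:1 into 0:2:1 (heterozygote excess), not into
3:1 — a 3:1 two-band ratio requires a simplex tetrasomic or
dual-subgenome disomic parent, not homozygote death alone.

Missingness is uniform per cell (default 0; the study's per-locus rates
run ~0–6%). Outcross contamination substitutes, with the configured
probability, a progeny formed from one gamete of each parent; these
zygotes do not pass through the viability weights (which model selfing
depression). Default population sizes 228 and 273 mirror the two study
populations.

Reproducibility: one integer seed; each marker's column is drawn from
`numpy` `default_rng([seed, crc32(marker_id)])`, so identical
configurations are bit-identical and adding markers never perturbs
existing columns.

What the generator does **not** emulate: gel artefacts, size-dependent
allele dropout, scoring error beyond uniform missingness, linkage between
markers, or mixed bivalent/quadrivalent pairing. Passing pipeline tests
therefore demonstrate correct behaviour under clean multinomial sampling
from the stated models, not robustness to genotyping error.

## Numerical and design choices

* Exact rational arithmetic throughout the model side; no tolerance on
  normalization.
* The chi-square p-value is monotone-decreasing in the statistic
  (property-tested); published-value comparisons allow one unit at the
  printed precision because archived tables mix rounding and truncation.
* Simulation problem sizes in the checks: 1000 null loci at n = 200 for
  the type-I scan, 500 replicates at n = 270 per mode for recovery; both
  chosen to make binomial intervals tight while the whole suite runs in
  seconds.
* Tie-breaking is deterministic everywhere (listed model order; sorted
  multiset keys).
* The CLI (`polyseg analyze|simulate|ratios|verify-selfed`) is a thin
  layer over the library; the numbered scripts under `analysis/` are the
  narrative drivers for the bundled datasets.

## Known limitations

* Tetraploids only; no hexaploid or mixed-pairing models.
* The archived tetrasomic (1:34:1) chi-square columns do not recompute
  from their own printed counts under any n convention; they are carried
  in the fixtures for reference but recomputed values are used
  everywhere.
* Double reduction is exposed but none of the bundled analyses exercise
  α > 0; the classic ratios assume α = 0.
* The two-locus decomposition assumes exactly four band labels and
  independent subgenome loci; linked loci would need a different model.
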