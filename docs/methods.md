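# Methods

This note documents the models, conventions and numerical choices behind
`speciescadd`, and what the synthetic study conditions do and do not show
about real data.

## Coordinates and formats

Internal coordinates are 0-based, half-open everywhere; VCF and the
consequence TSV are 1-based on disk and converted at the I/O boundary.
The ancestral genome is consumed as a reference-projected aligned FASTA
(one record per reference contig, equal length), with `-` and `N` both
meaning "ancestral state unknown". Variant class labels travel in the VCF
INFO field `CLS`; allele frequencies in `AF`. Feature matrices are TSV
with a `##column` preamble carrying each column's tags.

## Derived-variant calling

A derived variant is a position where reference and ancestor both have a
known ACGT base and differ; REF is the reference (derived) allele and ALT
stores the ancestral state. Any mismatch at distance 1 from another
mismatch is excluded, and the exclusion is evaluated against the full
pre-filter mismatch set, so whole adjacent clusters are removed. This is
the conservative reading of "not adjacent to another variant site": it
drops multi-nucleotide-event artifacts entirely rather than keeping one
representative. Unknown-ancestor positions yield nothing and do not
trigger the exclusion (adjacency is defined between mismatches only; a
mismatch next to an unknown column is kept).

## Substitution model

Rates are estimated per window (default 100 kb) as

    rate[a→b] = #(ancestral a, reference b≠a) / #(ancestral a)

within each CpG context class. CpG context is evaluated on the ancestral
sequence, strand-symmetrically: a C immediately followed by G, or a G
immediately preceded by C (false at contig edges and next to unknown
bases). Substitution propensity is a property of the ancestral state, so
the ancestral sequence — not the reference — defines the context. The full
4×4 table is kept per context; only the C and G rows of the CpG table are
reachable (A/T bases are never in CpG context), and unreachable or
zero-opportunity rows are zero. Windows with fewer than
`min_window_opportunities` (default 100) opportunities for a base fall
back to the opportunity-weighted global pool, keeping the sampler
well-defined on sparse contigs; windows with zero opportunities have zero
rates, which is irrelevant to sampling since no such site exists there.

The simulator draws positions without replacement with probability
proportional to each eligible site's total rate (eligible: known ancestral
base equal to the reference base and not explicitly excluded — derived
sites are passed in `exclude`), then draws the alternative allele
proportional to rate[a→b] for the site's window and context. Weighted
sampling without replacement uses exponential (Gumbel-key) sampling, fully
deterministic under the seed. Adjacency to derived sites is not enforced
for simulated variants; the adjacency rule applies only to derived-site
ascertainment. Whether the original simulator draws per-window counts
before placing variants is not observable from its outputs; the
position-proportional draw is this package's documented choice. Note that
without-replacement sampling means site inclusion probabilities are only
proportional to rates while the sampling fraction of high-rate sites is
small; at the default ~1% divergence and ≤ 5% sampling fractions the
distortion is negligible for homogeneous rates and modest otherwise.

## Training classes and folds

Class sizes are equalized by uniform downsampling of the larger class
(seeded). Folds (default 11) are dealt round-robin within each class with
a rotating offset, giving fold sizes that differ by at most one and
per-fold class counts that differ by at most one — exact 50/50 balance
whenever the arithmetic allows it (odd fold sizes force a one-variant
imbalance). The highest fold id is the designated held-out test partition.

## Features

- GC%: fraction of G/C among non-N reference bases in the ±75 bp window
  around the variant, clipped at contig ends; all-N windows are missing.
  The window uses the reference sequence (the feature describes context,
  not the substitution).
- Shape deltas: per-descriptor difference `table[alt 5-mer] − table[ref
  5-mer]` for the 5-mer centered on the variant; missing within 2 bases of
  a contig end or when the 5-mer contains N. The lookup table must cover
  all 1024 5-mers.
- Track lookups: per-base score tracks give the covering value or missing;
  interval tracks give 0/1 coverage.
- Consequence one-hots over a closed vocabulary (default: intergenic,
  intron, non_coding_exon, synonymous, missense, stop_gained, UTR); coding
  terms are additionally tagged `coding`. Variants absent from the
  consequence table get an all-zero encoding with transcribed = translated
  = false — untranscribed by default, which also settles how unannotated
  variants enter the "not transcribed" evaluation subset. Hierarchical
  SO-term resolution is out of scope; the pipeline consumes pre-summarized
  consequences.
- Composites: `annot × term` columns carrying the annotation value where
  the consequence one-hot is 1, else 0, with missingness propagated. The
  composite inventory is configuration (defaulting to the cross of
  {intron, intergenic, missense, synonymous} with the conservation-tagged
  columns) because the appropriate list depends on the annotations a user
  actually has.
- Tiers: `all` keeps everything; `no_epi` drops epigenetic and
  species-specific columns; `cons_vep` keeps conservation, sequence, VEP
  and composite columns but drops coding-specific ones unless they are VEP
  one-hots; `seq_only` keeps only conservation and sequence columns. The
  tiers are nested for any matrix whose composites are built from
  tier-surviving parents.
- Missingness: zero-fill plus a `<name>__missing` indicator column. This
  preserves sparsity, which matters because standardization never centers;
  mean imputation would destroy both.

## Classifier

The objective is mean logistic loss + λ‖β‖², intercept unpenalized.
Fitting delegates to a deterministic batch L-BFGS solver whose `C`
parameter is mapped as C = 1/(2nλ), making λ comparable across dataset
sizes; the iteration cap is the solver's outer-iteration limit. Named
presets: `mouse` (λ = 0.1, 100 iterations) and `human` (λ = 1, 10
iterations). Scale factors are population standard deviations computed on
the full training matrix before any fold split, frozen into the model, and
applied to every downstream set; constant columns get factor 1 with a
logged warning. Cross-validation grids over λ ∈ {0.01, 0.1, 1, 10} ×
max_iter ∈ {10, 100} by mean validation ROC-AUC over 10 stratified folds
(the pre-built training partitions when their count matches), ties broken
toward larger λ then smaller max_iter. Exact coefficient equivalence with
any particular external solver is not a goal; the contract is behavioral
(score ranking / AUC level).

## Evaluation

ROC-AUC is the Mann–Whitney statistic (ties count half); subsets with a
missing class report "undefined", never 0. Region subsets derive from the
transcribed/translated/consequence flags carried on variants — a single
source of truth rather than re-querying annotation files. Matched negative
sets filter candidates to AF ≥ 0.9 and sample without replacement so the
three strata {synonymous, non-synonymous (missense ∪ stop_gained), other}
match the positives' counts exactly. Weight-rank comparison restricts to
features with non-zero weight in both models, ranks absolute weights with
average ranks for ties, and reports Spearman's ρ with the common-feature
count; a name map aligns annotations across models (identity by default).

## Synthetic species: what it emulates, and what it does not

`FixtureSpec` defaults are mouse-like: GC fraction 0.42, transition rate
0.006 and transversion rate 0.0015 per site (≈1% reference–ancestor
divergence, transitions 4× transversions), CpG multiplier 10, 2% of the
ancestor unknown in runs of ~50 bases. Evolution runs forward in time:
the generated template is the ancestor and substitutions produce the
reference, so the rate table is the generating distribution in exactly
the direction the estimator measures and recovery is unbiased up to
sampling noise. Adjacent substitutions are thinned to minimum spacing 2
by keeping alternate run members starting at a random offset — a
deterministic choice would systematically discard the G-side of doubly
mutated CpG dinucleotides and bias their realized rate. The thinning
still removes a few percent of substitutions at CpG sites (both members
of a doubly-hit CpG are adjacent), which is the main residual gap between
nominal and realized rates.

Annotation signal is statistical, not mechanistic: informative tracks are
class-conditional Gaussians (simulated class shifted by the effect size,
default 2.0 at noise SD 1.0), scaled up 1.5× in translated regions and
down to 0.6× outside transcripts, and simulated variants are enriched
1.5× for missense among translated sites. Consequence draws match the
region layout (50% transcribed, 30% translated) in expectation. Passing
tests on these fixtures demonstrates that the pipeline's machinery is
correct and that planted signal of known strength is recovered; it says
nothing about how informative real annotations are, about linkage or
mutation-rate structure beyond 100 kb windows and CpG context, or about
realistic epigenomic track geometry.

## Problem sizes

The default test and acceptance runs use 200 kb – 1 Mb genomes, ~20–50 k
variants and ~20–30 features — sizes at which every statistical tolerance
asserted in the tests has several-sigma margin (rates are chosen so each
substitution type has hundreds of expected events per window) while the
whole suite runs in well under a minute of compute per stage. All
generators, samplers and fits are deterministic given their seeds.

## Known limitations

- Single-nucleotide substitutions only: no indels, no multi-nucleotide
  events, no outgroup-based polarization.
- The substitution model is first-order in context (CpG vs non-CpG);
  trinucleotide and broader contexts are out of scope.
- Scores are raw log-odds; no rank-based rescaling or probability
  calibration is provided.
- Consequence vocabularies are closed and flat; real VEP output must be
  summarized to one term per variant upstream.
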