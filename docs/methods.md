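# Methods

This note documents the statistical procedures hybriqc implements, the
choices made where several reasonable conventions exist, and what the
synthetic-data generator does and does not emulate.

## Setting

A breeding program crosses a set of inbred female lines onto one or two
elite male testers and needs to know, for every putative F1 seedling,
whether it is a genuine hybrid or an accidental selfing of the female
(hand emasculation in self-pollinating crops fails silently). A small
panel of quality-control SNPs — here 17 biallelic KASP markers, one or
two per chromosome, pre-screened for allele-frequency neutrality — is
genotyped on parents and progeny. Everything downstream is arithmetic
over the resulting call matrix.

## Call representation

Calls are normalized against the panel to four states: homozygous for
allele 1 (`HOM1`), homozygous for allele 2 (`HOM2`), heterozygous
(`HET`, unordered), and `MISSING`. A call containing an allele the panel
does not define for that marker is a validation error, never a fifth
state. The packaged panel reproduces the published 17-marker cowpea QC
set; one marker's printed end coordinate is shorter than its start in
the distributed source table (an apparent truncation), and the fixture
uses start + 132 bp, the span every neighbouring marker has. Ten
chromosomes carry markers (1, 2 and 8 one each, the others two;
chromosome 3 none).

## Marker statistics

Allele frequencies use gene counting (homozygote = 2 copies,
heterozygote = 1 of each; missing calls excluded from the denominator).
This is the population-genetics standard; the convention matters only at
loci with appreciable heterozygosity. Polymorphism information content
is `PIC_j = 1 − Σ_i p_i²`, bounded by 0.5 for biallelic loci.
`pr_het` is computed over non-missing calls; `pr_missing` over all
calls. Panel screening flags a marker as *biased* when its major allele
frequency strictly exceeds 0.75 and as failing the heterozygosity screen
when `pr_het ≥ 0.04`.

Dataset filtering removes samples first (missingness strictly greater
than the threshold, default 10%), then markers (MnAF strictly below the
threshold), mirroring the usual order of operations — sample removal
changes marker frequencies, not vice versa. The filter is idempotent.
Thresholds stated as "more than X%" are strict inequalities throughout
(a sample at exactly 10% missingness survives; a fingerprint at exactly
55% missingness is still reliable).

Percentages in human-readable summaries are rounded half-up to integers;
machine outputs always carry the unrounded values. (Published summaries
of this kind of analysis occasionally disagree at the integer level —
e.g. 79% vs 80% homozygous parents — which is exactly a rounding-rule
artifact; we therefore never discard the unrounded number.)

## Polymorphism and marker efficiency

For each cross, every marker is scored 1 (parents are opposite
homozygotes — *informative*), 0 (same homozygote) or NA (either parental
call missing). A heterozygous parent also scores NA under the default
policy: at such a locus a hybrid and a selfing can produce the same
genotype, so the locus cannot diagnose hybridity. This is a design
choice, not forced by the definitions; `het_parent_policy="zero"` scores
such loci as non-polymorphic instead.

Per cross: `%polymorphism = 100·Pm/Tm` with `Tm` the non-NA count — not
the full panel size — applying the same "excluding pairs with missing
calls" rule the efficiency statistic states, symmetrically. Per marker:
`efficiency = 100·fm/Tc` over crosses, NA-excluded. When no scores are
NA the two panel means coincide (both are `Σ scores / (crosses ×
markers)`), which the tests exploit as an identity check.

## Hybridity classification

For each putative F1, only loci scored 1 for its parents are used.
Missing F1 calls at informative loci are dropped from numerator and
denominator; `hybridity% = 100·L_het/n_evaluable`. Classification:

* `Pm == 0` → undetermined, no polymorphism;
* evaluable loci `< min_informative` → undetermined, missing data;
* `hybridity% ≥ 20` → true hybrid (the boundary goes to hybrid);
* otherwise → self.

`min_informative` defaults to 1 so that a single clean informative locus
yields a call; classifications from fewer than three loci are weakly
supported and the CLI warns when configured below 3. The 20% threshold
is the conventional rule for this assay; with clean data the two classes
sit at 100% and 0%, so the threshold's exact value only matters under
genotyping error.

An F1 homozygous for the *male* allele at an informative locus counts as
non-heterozygous (towards self) but is flagged: that genotype cannot
arise from selfing and suggests pollen contamination or an outcross.

Cross success is `100·n_true/n_total` with undetermined F1s excluded
from the denominator by default. The parent-vs-F1 heterozygosity
contrast reports per-group min/mean/max and bins per-sample
heterozygosity as exactly 0%, >0–<6%, 6–10%, >10%, with samples above
the missingness filter in a separate filtered-out class. Note that the
heterozygosity binning and the hybridity classification are different
statistics (raw per-sample heterozygosity over all markers vs.
heterozygosity over informative loci only); both are reported.

## Relatedness

Genotypes are encoded as dosage fractions 0 / 0.5 / 1 (missing absent).
Pairwise distance is unscaled Euclidean over loci observed in both
samples; squared distance therefore reads as "number of differing
homozygous loci" (a HOM/HET difference contributes 0.25), bounded by
√17 ≈ 4.12 on the full panel, with 14 homozygous differences giving
√14 ≈ 3.742. Pairwise-complete deletion without rescaling preserves
this reading but makes high-missingness pairs look artificially close —
which is why samples above the missingness filter are excluded before
distance analysis. Pairs sharing no called locus get an undefined
distance and are flagged.

Neighbor-Joining is the classic Saitou–Nei agglomeration on the
distance matrix: join the pair minimizing
`Q(i,j) = (m−2)·d(i,j) − r_i − r_j`, with standard branch-length and
distance-update formulas. Ties in Q are broken towards the
lexicographically smallest index pair so output is reproducible.
Negative branch lengths (possible on non-additive input) are clamped to
zero with the deficit transferred to the sister branch; raw lengths are
kept on each edge. On additive matrices NJ reproduces the generating
tree exactly, which the tests verify on 4- and 5-taxon cases and against
an independent NJ implementation. Cutting the tree into named clusters
is left to the user: any specific cluster count depends on a cut height
no convention fixes.

PCA operates on the dosage matrix with per-marker mean imputation of
missing values, centered but not variance-scaled (markers share a scale
already; scaling would up-weight near-monomorphic markers). Component
signs are fixed by making each loading vector's largest-magnitude entry
positive. Marker contributions are squared loadings normalized per
component (summing to 100% over markers), combined across components by
eigenvalue weighting — the combined column also sums to 100%.

## Synthetic cohorts

The generator draws each female locus homozygous for allele 1 with
probability `p_j`, flips it to heterozygous at the residual rate, copies
male B from male A with a configurable number of opposite-homozygote
differences, and produces each F1 as a true hybrid with probability
`1 − s` (one gamete per parent) or a selfing (two independent female
gametes — so a heterozygous female locus segregates 1:2:1 rather than
cloning the female). Genotyping error (uniform swap among the three
called states) and missingness are applied per call after truth is
recorded.

Defaults define the study-scale scenario: 220 females in four source
groups forming 225 crosses with two males (five females crossed to both,
17 crosses on male B), 1,436 F1s, `s = 0.15`, `p_j = 0.75`, residual
heterozygosity 0.02, missingness 0.03, error 0, identical sister males.
The allele frequency 0.75 makes the expected informative fraction
`2p(1−p) = 0.375` per marker (~6.4 informative markers per cross), the
regime a pre-screened neutral panel operates in; residual heterozygosity
0.02 matches the typical mean heterozygosity of advanced inbred parents;
`s = 0.15` is a realistic emasculation-failure rate for hand crossing.

What the generator does **not** emulate: linkage (gametes are drawn per
locus — irrelevant for single-locus QC statistics), allele-frequency
structure between source groups (all parents share one frequency
vector, so PCA/NJ on synthetic data show sampling structure rather than
pedigree clusters), per-cross clustering of selfing events (real
selfing concentrates in particular crosses — failed emasculation tends
to affect a whole pollination session — so the share of crosses at 100%
success is substantially lower in simulation than in real cohorts at
the same overall selfing rate), and outcrossing by foreign pollen.
Passing tests on synthetic data therefore validate the arithmetic and
the classifier's truth recovery, not the population-genetic realism of
any particular cohort.

## Numerical notes

* All randomness flows through one `numpy` Generator seeded from the
  scenario config; identical seeds reproduce the whole
  generate→analyze path bit-identically.
* Frequency-sum checks use 1e−9; PCA reconstruction and contribution
  identities hold to 1e−9 on the tested sizes; the PIC closed form is
  exact to 1e−12.
* Degenerate inputs are explicit: all-missing markers yield undefined
  (NaN) frequency statistics and are flagged rather than silently
  dropped; a cross with `Tm = 0` is flagged "no informative data"; a
  two-sample NJ input yields the single edge.
* Problem sizes: the bundled study-scale scenario (1,658 samples × 17
  markers, 225 crosses) runs the full pipeline, including the
  ~190-leaf NJ tree and full-rank PCA, in a few seconds on one CPU.
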