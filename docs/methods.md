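# Methods

## The generative model

The simulator (`polyretain.simulate`) realises the duplication history that
the downstream inference is meant to read back out of gene order.

An ancestral genome of `n_genes` single-copy genes is laid out contiguously
on `n_chroms` chromosomes; each ancestral gene is independently tagged
*focal* with probability `focal_fraction` (default 0.3) and the tag is
inherited by all copies, i.e. class membership is a family-level property.

**Polyploidies.** Events are applied oldest-first, each with a multiplicity
(2 = WGD/tetraploidy, 3 = WGT/hexaploidy), a mean age in Ks units, and two
retention probabilities.  An event appends `multiplicity − 1` copies of every
chromosome; each *new* gene copy survives fractionation with
`retention_focal` or `retention_background` according to its class, and lost
copies are deleted from the copied chromosome, so within-copy gene order is
preserved exactly — paleologous blocks are collinear by construction, with
rank gaps where copies were lost.  The pre-existing copy always survives:
gene death is not modelled because the analysis concerns the fate of
duplicate copies, not gene loss per se.

**Single-gene modes.** After all events, each gene independently spawns at
most one extra copy: tandem (inserted at the adjacent rank), proximal
(uniform rank offset in [2, 10]) or dispersed (uniform position on another
chromosome), with per-gene probabilities 0.01/0.01/0.02 by default — small
enough that polyploidy dominates, as it does in the plant genomes this
emulates, but large enough that every branch of the classifier is exercised.

**Erosion.** `inversion_count` random segment inversions (uniform chromosome,
uniform endpoints) are applied last.  An inversion inside a block splits one
chain into a same- and a reverse-orientation fragment; enough inversions push
fragments below the minimum anchor count and genes silently lose their
collinearity evidence — the mechanism behind the classifier's
WGD→dispersed confusion as erosion grows.  How erosion should be
parameterised is an open modelling choice; a count of uniform inversions is
this package's knob.

**Latent Ks.** Every surviving duplicate pair draws
Ks ~ Normal(age of the event that separated the pair, `ks_noise_sd`),
truncated at 0 (default sd 0.05; single-gene pairs use a recent mean of
0.1).  The pair's divergence event is the first event at which the two
lineages took different branches, so the Ks histogram of polyploidy-derived
pairs is multimodal with one mode per event.  The emitted similarity table
maps Ks to percent identity as `100·exp(−k·Ks)` with `k = identity_decay`
(default 0.12, keeping even γ-aged pairs above the 60% family-identity
threshold) plus bounded uniform noise (±0.5), and E-values decay
monotonically with identity (`10^(−identity/3)`); every gene also gets a
rank-first self-hit.  Event attribution inverts the same decay to estimate
pair Ks from identity, which adds ≈0.05 of effective noise at γ age — still
an order of magnitude smaller than the inter-event window widths of the
default history (ages 1.6/0.8/0.2).

**Reference interactome.** A Barabási–Albert preferential-attachment graph
over the focal ancestral genes (mean degree 4 by default) stands in for a
curated interaction database: hub-dominated, sparse, deterministic per seed.

All randomness in a study run flows from one integer seed, fanned out to
per-stage child seeds by a stable FNV-style hash (`polyretain.util.child_seed`)
so stages can be re-run in isolation without disturbing one another.

## Detection conventions

**Anchor chaining.** Chains must be strictly monotone in rank on both
chromosomes (same or reverse orientation) with at most `max_gap = 50`
intervening genes between consecutive anchors on *each* side.  Chain score
is the anchor count; gap totals and, last, the lexicographic anchor-rank
sequence break ties, which makes greedy best-chain-first extraction fully
deterministic and lets an exhaustive-enumeration oracle check it exactly.
`min_anchors` defaults to 5, the conventional synteny-tool floor.  On
self-comparisons, anchors within one rank of the main diagonal are dropped
so tandem arrays cannot pose as blocks.

**Block significance.** The null redraws the observed number of anchors for
the chromosome pair uniformly on its rank grid and recomputes the best
attainable chain score; p is the add-one permutation estimator
`(1 + #{null ≥ observed}) / (1 + n_permutations)`, so p is never 0 and the
test is distribution-free.  1000 permutations resolve the p < 0.05 gate
comfortably; the test suite and calibration loops use 20–200 permutations,
which still resolves the gate (the smallest attainable p at 49 permutations
is 0.02) at a fraction of the cost.

**Event windows.** Blocks are attributed to events by the window containing
the *median* anchor Ks — robust to a minority of misestimated pairs.
Windows are half-open, non-overlapping, and supplied explicitly;
`windows_from_ages` derives midpoint-bounded windows when event ages are
known (as they are for the simulation), but nothing is auto-detected from
histogram peaks, to avoid silent misattribution.

**Enrichment.** Pearson chi-squared at 1 df, no continuity correction, no
multiple-testing adjustment (per-row raw p, matching how such tables are
conventionally printed; both are available as options).  Status is I/D only
when p < alpha (default 0.05) *and* the focal proportion is above/below the
background's.  Two background modes exist: `all_genes` reproduces the
published table layout (focal row vs whole-genome row, overlapping sets) and
is conservative; `non_focal` uses the disjoint complement and is the variant
whose type-I behaviour can be meaningfully calibrated.

**NG86.** Synonymous site fractions count, per codon position, the fraction
of the three possible changes that preserve the amino acid; changes to stop
codons count as nonsynonymous.  Multi-difference codon pairs average over
all minimal mutational pathways with equal weights; pathways through a stop
codon are excluded and the remainder reweighted (if every pathway is
blocked, all are kept with stop-creating steps counted as nonsynonymous —
the loose edge case of the method, resolved as standard practice).
Gapped codon columns are dropped pairwise.  pS or pN ≥ 0.75 is a saturation
error, not a number; Ks = 0 makes ω undefined (a sentinel, not infinity),
and positive selection is flagged only when both distances are defined and
ω > 1.  Only the standard genetic code is supported.

**Robustness.** R = C/(N−Nr) with uniform removal without replacement.
Fraction schemes resolve to `round-half-up(f·N)` clamped into [1, N−1] —
rounding direction is unstated in the field's convention and matters on
small networks, so it is explicit and configurable here; clamping avoids
zero-removal no-ops.  Removal draws come from a single seeded stream
(100 repetitions by default), so profiles are reproducible and two networks
with the same node count are compared on identical removal sets, which makes
the "adding edges never hurts" property exact rather than statistical.

**Percentages.** All reported percentages are `round-half-up(100·c/t, 2)`
via decimal arithmetic, recomputed from the report's own counts.

## What the simulation does and does not establish

The generator reproduces the *order statistics* of polyploid genomes (block
structure, gap distributions from fractionation, Ks peaks, biased class
retention) but not sequences, expression, chromosome fusion/fission, gene
death, or selection dynamics; identity decay is a clean one-parameter map
rather than a rate mixture.  Passing recovery tests therefore shows the
inference chain is correct *given* the model's assumptions — it does not
validate those assumptions against real genomes, where assembly artefacts,
segmental duplications indistinguishable from WGD remnants, and uneven
evolutionary rates all intrude.  The "polyploidy-related" label deliberately
lumps WGD remnants with segmental duplications, and collinearity-based
counts are underestimates wherever erosion has fragmented blocks below the
anchor floor.

**Overdispersion caveat.** The per-gene chi-squared treats genes as
independent trials, but polyploidy manufactures correlated pairs: a retained
duplicate contributes *two* collinear genes that also share their inherited
class tag.  This cluster design effect makes the gene-level test
anticonservative under a class-neutral null — in an idealised cluster model
the empirical type-I error at alpha = 0.05 is roughly 13%/11%/9%/6% at equal
retention 0.2/0.3/0.5/0.8, and the full pipeline measures ≈8% at retention
0.5.  The bias disappears only as retention → 1 (no variance) or → 0 (no
clusters).  Practical reading: enrichment p-values from per-gene 2×2 tables
on polyploid genomes overstate significance by a modest factor; they are
trustworthy as orderings and for the extreme significances typical of
strong retention bias, not as exact tail probabilities.  Testing at the
ancestral-locus level would restore calibration but no longer corresponds
to the per-gene tables this package is built to reproduce.

## Problem sizes

The canonical study uses 1200 ancestral genes on 5 chromosomes through
γ (WGT, Ks 1.6), β (WGD, 0.8), α (WGD, 0.2) with retention 0.9/0.3 and 10
inversions — ≈6000 emitted genes, large enough for stable block statistics
and tight recovery metrics.  Calibration loops use one 0.3-Ks WGD on
400-gene (null) or 2000-gene (power) genomes with 49 permutations per
block; classifier-recovery runs use 2000 genes through one WGT + one WGD.
Ka/Ks fixtures are 60–200 codons; simulated coding pairs evolve under a
purifying acceptance probability of 0.2 for nonsynonymous changes (a
neutral fixture would centre ω on 1 and flag half of all pairs).

## Known limitations

* Event attribution relies on user-supplied Ks windows; overlapping true
  age distributions (ages closer than the combined noise) cannot be
  deconvolved — no mixture modelling is attempted.
* The co-ortholog map (hits within 0.9× of the best bitscore) is a
  deliberate desk-scale surrogate for orthogroup inference; it expands
  one-to-many relationships but has no outgroup awareness.
* Branch-level positive-selection inference (site/branch models, likelihood
  ratio tests) is out of scope; NG86 pairwise ω is the only selection
  statistic.
* The permutation null conditions on anchor *count*, not on anchor spatial
  clustering; heavily clustered non-syntenic anchors (e.g. large tandem
  arrays off the diagonal) could in principle inflate null scores — the
  diagonal exclusion mitigates the dominant case.
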