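# Methods

## Setting and model

The package operates on a jointly genotyped six-sample VCF: two
nearly-isogenic rat strains (WLI, WMI) each sequenced on three platforms
(Illumina short reads, Ion Torrent, 10X Chromium linked reads), called per
sample and joint-genotyped upstream.  The analytical object is the
*site*: six `(GT, GQ, DP, AD)` tuples keyed by strain x platform.  The
goal is a small, high-confidence set of sites where the two strains
genuinely differ, with one strain homozygous reference — everything else
(shared divergence from the reference, platform artifacts, thin evidence)
is removed by a fixed cascade of hard filters.

Two modelling commitments shape the whole package:

* **"Phred quality of a call" means per-sample FORMAT/GQ**, not the
  site-level QUAL.  The cascade repeatedly compares qualities *between
  samples of the same strain* ("disputed by another platform at quality
  30", "unopposed at quality 10"), which only a per-sample quantity
  supports.  This is an interpretation: the upstream description does not
  distinguish the two explicitly.
* **A call is an allele-resolved genotype.**  Two homozygous-alternate
  calls on different ALT alleles of a multiallelic site are *different*
  calls; best-call equality between strains compares the concrete allele
  pair.  A missing call (`./.`) is distinct from homozygous reference and
  equal to nothing.

Per-sample depth is FORMAT/DP, falling back to `sum(AD)` and then 0 when
absent; genotype quality of a non-missing call without GQ is treated as 0
(no confidence).

## The cascade, its order, and edge conventions

Steps run in the fixed order: depth -> equal-best -> (concordance flag) ->
uncertain -> equal-best again -> low-quality dissent -> allele balance ->
cross-platform dispute -> strain-difference -> quality tier ->
homopolymer deletions.  The upstream workflow lists the equal-best
removal twice; we re-apply it literally at position 5.  Because our
per-sample calls are immutable between the two applications, the second
pass is idempotent and removes zero records — it is kept (with its own
trace bucket) so the flowchart is comparable step for step.

Boundary conventions, all chosen to match the stated inequalities
literally: total depth of exactly 10 is kept (`< 10` removes); a single
sample at exactly 300 is kept (`> 300` removes); a dissenting call at
GQ exactly 10 is kept (`< 10` removes); a dispute at GQ exactly 30
removes (`>= 30`); the quality tier requires a supporting call at
GQ >= 30 and treats any conflicting call at GQ >= 10 as opposition.

Other decisions where the description was genuinely open:

* **Cross-platform dispute** is evaluated within *each* strain: any
  platform contradicting its own strain's best call at GQ >= 30 removes
  the site.  Restricting the test to the eventual carrier strain would
  require knowing the carrier before the strain-difference step runs;
  evaluating both strains is order-consistent and strictly conservative.
* **Allele balance** pools FORMAT/AD over all six samples.  "One call
  carries > 90 % of all reads and both strains share >= 25 % of reads" is
  read as: some single allele's pooled AD exceeds 90 % of total pooled AD,
  *and* each strain's pooled AD is >= 25 % of the total.  The alternative
  denominator (raw DP rather than allele-supporting reads) was considered
  and rejected because DP includes uninformative reads that cannot
  attribute support to an allele.  Zero pooled AD never removes here —
  thin evidence is the depth step's concern.
* **Low-quality dissent** requires all six calls non-missing, exactly
  five sharing a genotype, and the dissenter's GQ < 10.  A missing sixth
  call disables the rule (five agreeing calls plus `./.` is handled by
  the remaining steps).
* **Quality tier** treats the opposite strain's homozygous-reference
  calls as *required evidence*, not opposition; otherwise no strain
  difference could ever pass.  Any other conflicting call at GQ >= 10 —
  within the carrier strain or a non-reference call in the opposite
  strain — removes the site.
* **Homopolymer deletions**: the run is evaluated on the *reference*
  (not reads), with a minimum run length of 2 ("two identical
  nucleotides").  A deletion is suspect when every deleted base lies in a
  run of >= 2 within the deleted interval extended by one flanking base
  per side.  The carrier strain must then support that same deletion
  allele on >= 2 platforms at GQ >= 10, otherwise the site is removed.
  Heterozygous carriers are subject to the same rule.
* **Within-strain concordance** ("stored for further analysis") is a
  non-destructive flag exported with the trace; nothing is removed on it.
* The side set of homozygous candidates supported by all three carrier
  platforms at GQ >= 10 but never reaching GQ >= 30 is reported
  separately (`cross_tech_side_set`) and excluded from the finals:
  cross-technology agreement does not substitute for a high-quality call.
* Chromosome names are normalized by stripping an optional `chr` prefix.
  Y-chromosome records pass through the cascade normally; excluding Y is
  a reporting/plotting choice (the density-track `exclude` argument), not
  a filter.

Every record receives exactly one trace (a removal step or "survived"),
so per-step counts + survivors = input size on every run; all step
predicates are per-record, making results independent of input order.

## Classification and summaries

SNPs are single-base substitutions, split into transitions (A<->G, C<->T)
and transversions; length-changing alleles are insertions/deletions;
equal-length multi-base substitutions get an explicit OTHER class rather
than being dropped.  Multiallelic finalists are classified by the carrier
strain's called allele only, so each finalist contributes one class.
Percentages are computed over both strains pooled and rounded half-up to
one decimal (matching how such tables are conventionally printed); the
transition fraction is a percentage of SNPs, not of all variants.

Density tracks bin 1-based positions into half-open fixed-width bins
(`pos // bin_size`; a boundary position belongs to the higher bin) and
conserve counts exactly; optional smoothing is a centered moving average
over 5 bins (the width is a configurable guess — the published figure
says only "smoothed").  Cluster detection slides a `window_bp` window
(default 1 kb) anchored at each variant, reports windows holding >=
`min_count` variants, and merges overlapping qualifying windows into
regions carrying the maximum single-window count.

## Annotation summaries

The ANN INFO field is parsed by the standard pipe-delimited layout
(allele | effect | impact | gene | gene-ID | ...), one record per entry;
malformed entries warn and are skipped.  `&`-compound effects contribute
their first-listed category to tabulations but keep the full compound
string for the high/moderate-impact report.  Effect tabulation counts one
assignment per distinct (variant, primary category) pair — category
totals therefore legitimately exceed the number of variants, which is the
only reading under which the published column totals (2718 + 2430) can
exceed the 4,296 finalists.  How the original analysis collapsed
multi-annotation variants is not verifiable from the raw data, so this
choice is documented rather than proven.  Nearest-gene sets use the
primary annotation's gene per variant; the upstream-of-gene window (5 kb)
is taken from the annotator's classification, not recomputed from
coordinates.  Running the annotator itself is out of scope — the
synthetic fixture writes syntactically valid ANN strings so these stages
are testable offline.

## Validation concordance

The validation design genotypes 4 rats per strain (equal sexes) at
amplicon targets.  An amplified target is confirmed iff >= 3 of 4
carrier-strain rats are homozygous-alternate and 0 of 4 opposite-strain
rats are; unamplified targets leave the denominator.  Missing genotypes
count toward neither criterion (a missing opposite-strain call is not a
hom-alt call); heterozygous carrier-strain calls count against criterion
1 but never trigger criterion 2.  Whether the original "at least three
rats" tolerated missing calls is unstated; the handling here is a
documented choice.  The positive rate is `100 * confirmed / amplified`,
reported to one decimal.

## Synthetic data: what it emulates and what it does not

The generator is first-class, tested code.  It draws a reference with a
target density of homopolymer runs (token process: a run of 2–5 identical
bases with probability tuned to the requested covered fraction, else a
singleton differing from its neighbour), then plants non-overlapping
variants (>= 10 bp apart, so one plant's homopolymer context cannot
perturb another's) in nine classes whose six-call configurations *imply*
their pipeline fate:

| class | construction | expected fate |
|---|---|---|
| true hom/het difference | carrier concordant on 3 platforms, >= 1 call at GQ >= 30, opposite strain 0/0 at GQ >= 12 | survives |
| shared variant | same hom-alt call in all six samples | equal-best |
| homopolymer artifact | one platform (Ion Torrent) calls a het deletion in a run; strain-mates missing | homopolymer step |
| collapsed pseudo-het | het in all six samples at ~2x depth | equal-best |
| low / high depth | total AD+DP below 10 / one sample at 301–599 | depth |
| uncertain | five `./.` calls | uncertain |
| low-quality dissent | five agreeing calls, dissenter GQ 4–9 (its strain's maximum) | low-quality step |

Depths are normal draws around the observed platform coverages (Illumina
43x, Ion Torrent 41x, linked reads 27x; CV 0.15), clamped to [10, 290] so
no class crosses the depth thresholds accidentally; genotype qualities
are uniform draws from role-specific ranges with the class-defining
constraints enforced after the draw.  Each generator call uses a single
seeded `numpy` stream and no global state: identical seeds give
byte-identical FASTA/VCF/TSV outputs.

What passing these tests shows: the cascade implements its stated
decision rules exactly, conserves records, and is order-invariant.  What
it does not show: performance on real data.  The generator plants
idealized configurations — it has no read-level error model, no mapping
ambiguity, no correlated noise between platforms, no borderline-GQ
mixtures, and the published GQ distributions per platform are unknown (the
ranges here are stylized).  The published headline counts (2232/2064
finalists etc.) derive from ~100x real whole-genome data that is not
deposited and are not reproducible at desk scale; the summary-stage
arithmetic on their printed tables is reproduced exactly instead.

## Problem sizes and numerics

The default simulated dataset is a 200 kb reference with 1,020 planted
records (all nine classes), which exercises every cascade branch while
keeping a full test run in seconds; the acceptance script uses the same
size.  All thresholds live in `FilterConfig` with the published values as
defaults and validated invariants (`q_low < q_mid < q_high`, shares in
range).  Rounding of printed percentages is decimal half-up, implemented
with `decimal.Decimal` to avoid binary-float surprises.  Degenerate
inputs are defined, not accidental: empty summary tables report absent
fractions, zero amplified targets report an absent rate, zero pooled AD
never triggers the allele-balance filter, and an all-missing strain has
an absent best call that equals nothing.

## Known limitations

* Structural variants, phasing and genotype refinement are out of scope;
  the pipeline starts at the joint VCF and never revisits reads.
* The GQ-not-QUAL reading and the allele-balance denominator are
  interpretations (documented above); both are exercised by tests against
  their stated readings, not against the original implementation.
* `run-all` executes simulate -> filter -> summarize; annotation and
  validation stages run from their own subcommands since their inputs
  (annotated VCF, genotype matrix) come from external tools.
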