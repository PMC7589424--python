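# Methods

## Problem setting

`spliceamp` analyses splicing of a single, very long transcript that has
been amplified end-to-end (long-range RT-PCR) and sequenced as spliced
long reads. The motivating design is the dystrophin muscle isoform
(Dp427m): 79 exons, ~11.3 kb of coding sequence amplified as one
fragment, reads of mean length ~374 nt after trimming, and a mean
junction coverage around 1638x. At that depth, events at the 1% level
are detectable from junction reads alone, which is the whole point of a
targeted design: a quiescent transcript whose alternative events sit
below 5% in the control state.

Because one amplicon is sequenced, there is no expression-level
normalisation problem; everything reduces to ratios of junction-spanning
read counts.

## Junction extraction

Junctions are read off the skip (`N`) operations of primary spliced
alignments. A read spanning k junctions contributes one count to each.
A junction is only counted for a read when the aligned blocks on both
sides of the gap are at least `anchor` bases long (default 8); this
suppresses spurious one-to-few-base overhangs that aligners occasionally
emit around splice sites. Junctions are keyed by (donor, acceptor) site
positions — the first and last base of the removed region — ordered in
transcript orientation, so on a minus-strand gene the donor coordinate
is numerically larger than the acceptor coordinate. Secondary,
supplementary and unmapped records are skipped and tallied. Counts are
raw read counts: amplicon reads have no meaningful fragment diversity,
so no staggered-read deduplication is applied (there is no de-duplication
switch to turn on; extraction is deliberately simple geometry).

Junctions joining consecutive annotated exons are `annotated`; all
others are `novel`. Novel junctions must reach **5 reads in at least one
treated replicate** to be kept; annotated junctions are always retained.
The filter deliberately gates only novel junctions — the annotated
backbone is needed as the denominator of every usage ratio, and at
design depth it is covered thousands of times anyway.

## Usage metrics

For junction *j* in sample *s*:

- **psi5(j)** = count(j) / Σ count(j′) over junctions sharing j's donor,
- **psi3(j)** = count(j) / Σ count(j′) over junctions sharing j's acceptor.

These intron-centric indices are computed per sample; a zero denominator
yields an undefined (NaN) value, which propagates rather than being
silently replaced by 0.

Event-level usage (the *SJ* value) is derived per event type:

- **Exon skipping (SJ_ES)** — the mean of psi5 and psi3 of the skipping
  junction. The two indices answer slightly different questions (what
  fraction of splicing *out of* the upstream donor, vs *into* the
  downstream acceptor, is the skip); their mean is a single symmetric
  usage. When only one side is informative, the defined index is used
  alone.
- **Alternative splice site (SJ_Altss)** — the psi index at the shared
  *annotated* site: psi5 when the donor is shared, psi3 when the
  acceptor is shared. The index at the novel site is uninformative (it
  is 1 whenever the novel site has a single partner).
- **Pseudoexon insertion (SJ_PI)** — the mean of psi5 of the upstream
  novel junction (at its annotated donor) and psi3 of the downstream
  novel junction (at its annotated acceptor); the two junctions tag the
  same inserted block.

Per-exon inclusion uses the standard two-flank ratio

PSI(e) = (c_up + c_down) / (c_up + c_down + 2·c_skip),

where c_up/c_down count the annotated junctions into and out of exon e
and c_skip counts every junction bridging clear over it (including
multi-exon skips). Terminal exons have one flank and use
c_flank / (c_flank + c_skip). With symmetric flank counts, PSI + SJ_ES
of a clean single skip is exactly 1; asymmetric coverage perturbs this
only through the psi5/psi3 asymmetry.

## Event classification

Every non-canonical junction is classified by the geometry of its two
ends against the gene model:

- annotated donor of exon i → annotated acceptor of exon j, j > i+1:
  skipping of exons i+1..j−1 (single or multi);
- one annotated end and one novel intronic end: alternative 5′/3′ splice
  site, labelled by the exon-relative position of the novel site
  (`E77+1619` = 1619 intronic bases downstream of exon 77's donor,
  `E78-94` = 94 bases upstream of exon 78's acceptor; the nearer
  boundary names the site, ties go to the downstream form);
- one annotated end and one novel *exonic* end: alternative site within
  an exon, labelled `E<i>.<k>` with k the offset from the exon's 5′ end;
- within one intron, a lone pair of novel junctions enclosing an
  internal block: pseudoexon insertion. The intron-1 pseudoexon carries
  the field's name PE1a; others are labelled `<intron>x` (e.g. `34x`).

When an intron contains several novel acceptors or donors, pairing is
ambiguous and the junctions are reported as alternative splice sites
rather than guessed into pseudoexons; this is a deliberate conservative
choice, and the one configuration the emulated study needs (two
alternative donors sharing exon 78's acceptor) is handled correctly by
it. Junctions matching no pattern are logged as unresolved and excluded
from event tables.

## Differential calls

Replicate usage is aggregated as the unweighted mean and sample SD
(ddof 1) per condition; undefined replicate values are dropped with n
adjusted. For each treated condition versus control:

ΔSJ = SJ(treated) − SJ(control),  ΔPSI = PSI(treated) − PSI(control).

Tiers:

- **major**: |ΔSJ| ≥ 0.05 *and* the two mean ± 1 SD intervals are
  disjoint. With only two treated replicates no distributional test is
  defensible; interval disjointness is the honest reading of "not
  overlapping standard deviation". A |ΔSJ| ≥ 0.05 with overlapping
  intervals is tier *none*, not rare — the rare tier is defined by
  effect size, 0.01 ≤ |ΔSJ| < 0.05, with both boundaries inclusive.
- **rare**: 0.01 ≤ |ΔSJ| < 0.05 (no SD gate; these are reported for
  inspection, not called significant).

No multiple-testing correction is applied; the calls table carries the
number of events examined so a reader can judge the search space. ΔPSI
is reported for events already called on ΔSJ (it is not separately
gated), matching how inclusion changes are read off junction-level
calls.

**Regulator roles.** From each condition's major-tier exon calls
(pseudoexon events excluded — their inclusion polarity is opposite to
exon events): all inclusion effects negative → the depleted protein is a
splicing **activator**; all positive → **repressor**; mixed →
**bidirectional**; no calls → none. The inclusion effect is ΔPSI where
defined, else −ΔSJ (equivalent for clean single skips). Effects with
|ΔPSI| ≥ 0.4 are flagged as strong.

## Synthetic data generator

The generator exists so the whole pipeline can be validated against
known truth without any external data. It emulates the study design,
not its biology: event frequencies are *emulation parameters*, clearly
labelled as such in output metadata.

**Gene geometry.** A deterministic 79-exon minus-strand model with
~11.8 kb of exonic sequence; exon 71 is 39 nt and exon 78 is 32 nt (the
two short exons of the real transcript); intron 1 is 25 kb (deep
pseudoexon territory) and intron 77 is 4 kb, so the two alternative
donors at E77+1619 and E78-94 both carry their natural nearest-boundary
labels. Other exon/intron sizes follow a fixed pseudo-irregular table —
irregular enough to catch coordinate bugs, fixed so every test sees the
same coordinates.

**Isoform mixture.** Events (skips, pseudoexons, alternative sites) are
combined independently unless declared mutually exclusive; the mixture
is the full product distribution over event presence/absence, with
inconsistent combinations (two events claiming one intron boundary)
rejected. Exons 37/38 skipping, and exon-78 skipping versus the
intron-77 alternative donors, are mutually exclusive groups in the
preset.

**Read-level simulation.** Reads are drawn from isoforms by weight,
fragment start uniform over the transcript, length from a truncated
normal (mean 374, sd 40, range [100, 600]; only the post-trimming mean
is known, the spread is a modelling choice), truncated at the
transcript end with a logged warning. Alignments are emitted directly
as coordinate-sorted SAM (exon blocks as matches, introns as skips):
the upstream aligner is out of scope, and emitting alignments makes the
pipeline testable without one. A FASTQ writer is provided for optional
integration work. Ground truth junction counts are tallied from the
emitted reads with the same anchor rule the extractor uses, so
extraction must reproduce them *exactly* — any discrepancy is a bug, not
noise. Sequencing error, homopolymer artifacts and PCR bias are not
simulated: junction extraction operates on alignment geometry alone, so
base-level noise is invisible to it, and the real platform's indel
profile mainly degrades alignment quality, which we do not model.

**Fast path.** For statistical tests that need many seeded repetitions,
junction counts are drawn directly: at each annotated intron locus a
multinomial of size `depth` is distributed over isoforms, and each
isoform's draw is credited to the junction(s) it splices at that locus.
A junction spanning several annotated introns (a multi-exon skip) is
credited only at the first, mimicking a read counted once per junction;
both junctions of a pseudoexon are credited together (they sit on the
same transcripts). Under this scheme a weight-1 isoform yields exactly
`depth` counts at every canonical junction, and psi ratios converge to
isoform mixture weights.

**Baseline preset** (the packaged control condition, 4 replicates,
depth 1638): exon-71 skipping 3%, exon-78 skipping 4%, intron-1
pseudoexon (PE1a) 4%, other responsive-exon skips 0.5%, deep-intronic
pseudoexons 34x/63x 0.1%, alternative donors E77+1619 at 0.1% and
E78-94 at 0.2% — a quiescent landscape with everything under 5%.
Knockdowns are expressed as frequency shifts on top of this baseline
(2 replicates each), e.g. a strong activator knockdown as +0.40 on
exon-71 skipping.

What passing tests on these data do **not** show: robustness to
misalignment around splice sites, to PCR or homopolymer artifacts, to
reference/annotation mismatches, or to partial intron retention — none
of which the generator produces. Results on real data depend on the
upstream aligner's splice-site accuracy in ways the synthetic path
cannot probe.

## Numerical choices and degenerate inputs

- Undefined ratios (zero denominators) are NaN throughout and excluded
  from replicate means with n adjusted; a condition with no informative
  replicate yields a skipped, logged call rather than a fabricated zero.
- Thresholds are inclusive where the call definitions state ≥/≤:
  |ΔSJ| = 0.05 is major (SD gate permitting), |ΔSJ| = 0.01 is rare.
- The intronic-label tie (a site equidistant from both exon boundaries)
  resolves to the downstream (`E<i>+k`) form.
- All randomness flows through numpy Generators seeded per condition and
  replicate; identical seeds give byte-identical SAM output.
- Multiple transcripts in an annotation file: the first is used unless a
  transcript id is given (the targeted design has a single isoform).

## Problem sizes used in the checks

The test suite and the acceptance script validate oracle equivalence on
single replicates at depth 1638 (~54,000 reads each, 5 seeds), and the
statistical properties (shift recovery, null false-call rate) on 50
seeded fast-path runs of the full 2-vs-4-replicate screen at depth
1638. These sizes give binomial standard errors a factor ~20 below the
call thresholds, so the pass/fail outcomes are not borderline.

## Known limitations

- SJ_ES/SJ_PI are symmetric means of the two intron-centric indices;
  other aggregation choices (minimum, coverage-weighted mean) are
  defensible and would shift usage values by up to the psi5/psi3
  asymmetry.
- Pseudoexon pairing is conservative (one pair per intron); nested or
  overlapping pseudoexons within one intron are reported as alternative
  sites.
- Intron retention is out of scope: an amplicon design cannot see
  retained introns longer than the read span, and no retention metric is
  computed.
- The SD-overlap gate with n = 2 treated replicates is a crude
  dispersion check, not a test with known error rates; the null
  false-call rate is controlled empirically (see the acceptance checks)
  at the design depth, not analytically.
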