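# Methods

## Model

SLAMseq reads out metabolic labeling as T>C mismatches: a labeled
transcript's 4SU residues reverse-transcribe as C, so for a read with `t`
thymidines (transcript strand) and per-T conversion efficiency `p_e`, the
planted/expected conversion count is Binomial(t, p_e). Everything in the
package follows from treating the reference-T/read-C mismatch as signal
rather than error:

* **Alignment scoring.** Match +10, mismatch -15, reference-T/read-C
  exactly 0. The zero (rather than +10) means conversions neither attract
  nor repel the aligner: a read's score is independent of how many
  conversions it carries as long as they sit on genuine T positions,
  which is what makes mapping rates independent of the conversion rate.
  Direction matters (read-T against reference-C stays -15), and on the
  genomic minus strand the free cell moves to reference-A/read-G because
  conversions are defined on the transcribed strand.
* **Seeding.** 13-mer seed words, with lookup tolerant to reference-T/
  read-C differences. Implementation: two collapsed-alphabet indexes (T=C
  for plus-strand lookups, A=G for minus-strand lookups) retrieve
  candidates, which are then verified so that only the allowed mismatch
  direction survives. Seed hits are clustered by diagonal; clusters with
  a seed count below 30% of the best cluster *over both strands* are
  dropped (thresholding per strand would let spurious single-hit clusters
  on the opposite strand survive whenever that strand has no real hit).
* **Extension.** Each candidate region is first aligned gaplessly along
  its dominant diagonal; the aligned block is the maximum-sum run of
  per-column scores, with ties broken toward the longest block so that
  zero-scoring conversion columns at the read ends are retained. A full
  affine-gap Smith-Waterman (gap open -20, extend -5: any gap costs more
  than any mismatch, preserving the score ordering of the substitution
  scheme) over the candidate window takes over when the gapless alignment
  is poor (< 90% identity or < 60% of the read aligned) and the region is
  well seeded (>= 4 seed hits). Reads with more than 100 reported
  locations are discarded.
* **Filtering.** Keep alignments with >= 95% identity over >= 50% of the
  read bases. Identity counts conversion columns as matches (default,
  configurable): otherwise a 50-bp read with ~12 Ts at high `p_e` could
  exceed the 5% mismatch budget and the conversion-rate-dependent mapping
  loss would return through the back door.
* **Multimapper recovery.** With the 3' interval annotation de-overlapped
  (every member of a same-strand overlap group is dropped, so truth
  assignment stays unambiguous), a read's kept locations decide its fate:
  all inside one interval -> assigned (one location picked with a seeded
  RNG); one interval plus non-interval locations -> assigned to the
  interval (the copies are decoys such as pseudogenes or intronic
  repeats); two distinct intervals -> discarded; none -> discarded.
  Interval overlap requires >= 1 bp on the matching strand.
* **SNP masking.** A position is called a SNP when pileup coverage >= 10
  and a single alternative base reaches >= 0.8 of it (variant fraction;
  alternative bases below Q13 are ignored, coverage counts all aligned
  bases). The 0.8 default targets haploid-derived lines where SNPs are
  fully penetrant; for diploid samples a fraction around 0.2-0.5 is
  appropriate. Masked T positions are removed from **both** the
  conversion numerator k_i and the coverage denominator c_i — leaving
  them in c_i would bias the labeled-fraction estimate downward. Only
  SNVs are considered. The rank-enrichment diagnostic orders intervals by
  T>C read count and applies a two-sided Mann-Whitney U test between
  SNP-flagged and SNP-free intervals; when coverage varies, only the
  upper coverage quartile enters so that calls are not coverage-biased.
* **Estimators.** Read-count based:
  `p_SU = (R_TC / n) / p_TC` with `p_TC = 1 - (1 - p_e)^t`. Here `t` is a
  single experiment-wide constant (default: read length x mean T fraction
  of the terminal windows). Keeping `t` global is deliberate — the
  estimator's documented weakness is exactly that it ignores per-interval
  U-content, which the T-content normalized estimator
  `p_SU = (sum k_i / sum c_i) / p_e` fixes by working per T position.
  `p_e` itself is estimated from a saturating-label sample (p_SU = 1) as
  pooled `sum k / sum c`. Estimates are clamped to [0, 1] with an
  explicit flag rather than silently truncated.
* **Detection planning.** Expected labeled T>C reads
  `E_SU = p_SU * p_TC * n`; detection probability
  `p_DETECT = 1 - B(0; E_SU, S)` with S the empirical per-read detection
  sensitivity. E_SU is not an integer, so the zero-class term is
  evaluated as the analytic continuation `(1 - S)^E_SU` (default). A
  conservative ceil-trials variant and a Poisson approximation
  `1 - exp(-E_SU * S)` are available; the Poisson form tracks the default
  within ~1 point for S <= 0.1 but undershoots as S -> 1, and the ceil
  form overshoots grossly for E_SU < 1 (a single "rounded-up" trial).
  `min_coverage` inverts p_DETECT for n by bisection; the function is
  monotone in every argument.
* **QC.** Per-cycle mismatch rates split into the 12 substitution types
  (reported in transcript orientation, so "T>C" always means the
  labeling signal), with and without the base-quality filter; positional
  conversion profiles over a static terminal 250-bp window in transcript
  orientation (short intervals contribute their 3'-most suffix);
  mappability as exact k-mer uniqueness, score = 1/multiplicity counted
  over both genome strands (a reverse-complement copy is just as
  ambiguous to a both-strand mapper), %-unique per interval binned in 5%
  steps.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| match / mismatch / T>C score | +10 / -15 / 0 | substitution scheme; `conversion_aware=False` restores T>C = -15 |
| gap open / extend | -20 / -5 | unstated upstream; chosen so gaps cost more than mismatches |
| seed length k | 13 | seed word size |
| CMR count fraction | 0.3 | keep clusters with >= 0.3 x best seed count (both strands) |
| max locations | 100 | discard reads mapping to more places |
| min identity / aligned fraction | 0.95 / 0.5 | alignment filters |
| SNP min coverage / variant fraction | 10 / 0.8 | pileup gate (haploid default) |
| min base quality (conversions) | Q27 | conversion-call filter; the SNP pileup uses Q13 |
| conversion threshold | 1 | reads need >= this many conversions to count as T>C reads; 2 suppresses background at a sensitivity cost |
| terminal window | 250 bp | the 3'-most region sequenced/simulated |

## The simulator

The generator emits alternating-strand 3' intervals (length uniform
250-4000 bp by default) separated by random spacers on one synthetic
contig; T content is a per-base probability on the transcribed strand
(fixed, default 0.25, or drawn per interval from a range to emulate the
U-content spread of real 3' UTRs). A configurable fraction of intervals
receives a ~98%-identity copy, placed outside the annotation (decoy,
exercising recovery) or annotated as an interval itself (true ambiguity).
Homozygous SNPs are planted into a *sample* genome at rate 0.1% by
default while the reference stays clean, so SNPs surface as full-
penetrance mismatches. Reads come from the terminal 250 bp in transcript
orientation, starts uniform; each read is labeled with probability p_SU;
labeled reads receive Binomial(t, p_e) conversions at uniformly chosen T
positions (optionally truncated to >= 1, the "perfect simulation");
sequencing errors are uniform substitutions (default 0.1%) and miscalled
bases carry low reported quality (Q10) — as real miscalls tend to — so
the base-quality filter has the same handle it has on real data.
Configurable "bad cycles" (Q10, elevated error rate) exercise the
per-cycle QC. Read names encode origin interval, labeled state and
planted conversion count; truth tables record per-interval read and
labeled-read counts. Everything is deterministic under the seed.

What the simulator does **not** model: paired ends, PCR duplicates,
fragment-length and positional coverage bias, polyA tails/adapters
(reads are emitted pre-trimmed), indel sequencing errors, quality-score
miscalibration. Passing tests therefore demonstrate correctness of the
conversion logic, the recovery rules, masking and the estimators under
the stated generative model — not robustness to library-prep artifacts in
real data.

## Numerical and design choices

* De-overlapping drops entire overlap groups (no survivor): conservative
  and symmetric, keeps simulated truth unambiguous.
* Local trimming prefers the longest block among score ties so terminal
  conversions (score 0) stay aligned; under standard scoring the same
  rule clips terminal conversions (-15 each), which is the mechanism
  behind the conversion-count error of standard scoring in the
  benchmarks.
* The SNP pileup takes coverage from aligned spans and alternative counts
  from mismatch lists; matches are not re-checked against base quality
  (only alt bases are BQ-filtered).
* Ties among equal-scoring locations are ordered by (chrom, pos) for
  determinism; multimapper picks use one seeded generator with reads
  processed in input order.
* Degenerate inputs: n = 0 or sum c = 0 yield flagged undefined
  estimates, never exceptions; rank enrichment with < 2 intervals in
  either group is flagged undefined; intervals shorter than k have
  undefined %-uniqueness.
* N bases score 0 against everything, cannot seed, and never count as
  conversions.

## Benchmark problem sizes

The validation suite runs the full pipeline end to end on synthetic
fixtures sized for a single CPU: the perfect-simulation detection check
uses 500 intervals at 10x window coverage (the reproduction script uses
25x); estimator recovery uses 30 intervals x 6 replicate datasets at 100x
(medians per interval over replicates, so the comparison measures
estimator bias rather than single-replicate sampling noise); SNP masking
uses 350 intervals at 30x with a fully labeled sample; scoring and
multimapper checks use 80-150 intervals. Sensitivity/specificity
outcomes are depth-insensitive well beyond these sizes; the estimator
variance figures shrink with depth as expected.

## Known limitations

* The aligner honors the described contract (seed words, CMRs, scoring,
  location cap) but is not a bit-level reimplementation of any existing
  mapper; banded-extension details and CMR windowing are its own.
* Spliced and paired-end alignment are out of scope (3' end data is
  unspliced and single-ended).
* The variant caller is the thresholding rule only — no strand-bias
  tests, no genotype likelihoods, indels ignored.
* The read-based estimator's global-t idealization is kept intentionally
  (see above); users wanting per-interval t can pass it explicitly.
* Fraction estimates assume `p_e` (or a saturating-label sample) is
  known; mixture-model estimation of new/old RNA proportions is
  deliberately left to downstream tools.
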