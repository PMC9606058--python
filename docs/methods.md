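# Methods

This note documents the models implemented in `museomito`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Problem setting

Formalin-fixed museum specimens yield DNA fragments of a few tens of bases
whose cytosines are partially deaminated; sequencers read deaminated C as
T, preferentially near fragment ends where single-stranded overhangs were
exposed. Reconstructing a ~17 kb circular mitochondrial genome from such
reads, and comparing it against a congener's genome that differs at only a
handful of sites, requires (i) mapping that tolerates damage and the
circular origin, (ii) conservative consensus rules, and (iii) careful
classification of the few differences found. Every component here operates
on a circular reference with 1-based inclusive coordinates on the heavy
strand; BED output converts to 0-based half-open on disk (tested).

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which the rest of the chain is validated.

**Fragment lengths** are truncated lognormal, `ln L ~ N(ln 30.5, 0.30²)`
restricted to [20, 75] bp. The bounds are the post-trimming length filter
(20 bp) and the single-end instrument read length (75 bp). The parameters
were set from the closed-form truncated mean so that the expected read
length is ≈ 33.0 bp with ≈ 0.2 % of fragments at 70 bp or longer, the
regime reported for formalin-fixed fish specimens. The lognormal family is
a modelling choice — empirical museum-library length distributions are
asymmetric and unimodal but follow no named law.

**Damage** follows `p(i) = p_base + (p_max − p_base)·exp(−decay·i)` with
`i` the 0-based distance from the nearer considered end. Single-stranded
libraries apply C→T from both ends (distance to the nearer end);
double-stranded libraries apply C→T with distance from the 5′ end and G→A
with distance from the 3′ end. Uniform sequencing error (default 0.001) is
applied afterwards, drawing uniformly among the three alternative bases.
Defaults `p_max = 0.30`, `p_base = 0.01`, `decay = 0.3` are typical
published deamination magnitudes for degraded wet-collection material; no
numeric damage level is available for the motivating specimen, so damage
recovery tests are self-consistent (simulate → profile → fit) rather than
matched to an external value.

**Scale.** Read count is `round(L·depth / E[fragment length])` with
`depth = 35` over a 17,408 bp circle, ≈ 18,400 reads — the scale of the
real experiment. The planted truth set mirrors the published difference
table: 21 transitions, 5 transversions (placed ≥ 40 bp apart so a short
read sees at most one variant) and one single-base deletion inside an
embedded 14-C homopolymer. Contamination, when requested, is drawn from a
seeded i.i.d. GC-50 % decoy genome and flagged in the truth file.

**Not emulated:** adapter read-through, paired ends, quality-score error
models, PCR-duplicate structure beyond exact duplicates, reference biases
from real repeat architecture. Passing tests therefore demonstrate the
correctness of the inference chain under the stated generative model, not
robustness to every artefact of real libraries.

## Mapper

Ungapped seed-and-extend against the reference extended by its leading
bases, so origin-spanning reads seed normally; coordinates are wrapped
back. Defaults: `k = 12` (balances the 20 bp minimum read length against
the random-hit rate on 17 kb), seeds at the read start, middle and end on
both strands, mismatch penalty 3, mismatch cap `ceil(0.05·length)` (a
reinterpretation of a "maximum fraction of missing alignments 0.05"
aligner setting as a mismatch fraction — an approximation, configurable),
and a uniqueness margin of 5 score units (best minus second-best) standing
in for a Phred-scaled mapping-quality ≥ 25 filter, which cannot be
calibrated for a bespoke aligner. `damage_tolerant` halves the penalty of
C(ref)→T(read) and G(ref)→A(read) mismatches so damaged reads are not
pushed off their true placement. Ties break deterministically by
(position, strand). Gapped alignment is deliberately out of scope: at
~33 bp reads, indels are handled at the consensus stage instead.
Duplicates are flagged per (start, length, strand) — the single-end
analogue of the standard criterion — keeping the best-scoring read, ties
broken by read id.

## Damage profiling

Mismatch frequencies are conditioned on opportunities (occurrences of the
reference base at that read position), the standard convention for
deamination plots. The window is 25 positions per end; each base of a read
shorter than two windows contributes only to its nearer end (ties to 5′),
so nothing is double-counted. Minus-strand alignments are re-oriented into
read coordinates before counting, making "5′ end" always the sequenced
end. The deamination fit is bounded least squares (`scipy.optimize
.least_squares`) of the exponential model to the C→T series; an all-zero
series returns `p_max = p_base = 0` with `decay = NaN` (undefined).

## Consensus

Strict majority with ties → N, minimum depth 3. Damage is handled by depth
plus majority — intact cytosines vastly outnumber deaminated ones at 35× —
rather than damage-aware genotyping; this is a documented limitation, not
an oversight. Terminal recovery maps the reads a second time against the
reference rotated by 200 bp (configurable) and takes calls within 200 bp
of the origin junction from the rotated pass, where those sites are
interior; conflicting non-N calls between passes become N with a logged
warning. Masking covers perfect homopolymers/tandem repeats whose span
reaches the read length (unbridgeable by single reads) plus
manually-specified intervals (merged when overlapping). Homopolymer indel
candidates are voted by reads that carry the full run internally (their
run-base block bounded by non-run bases within the read) — this makes the
vote independent of which flank an ungapped aligner anchored when the
molecule's run length differs from the reference. Reads whose run is split
by an interior mismatch (a deaminated C) are excluded as ambiguous, and
votes are restricted to ±3 of the reference run length (slippage-scale
evidence). A candidate needs ≥ 2 agreeing spanning reads and no read
supporting the reference length, and is always flagged
`manual-confirmation`; candidates are applied only behind an explicit
switch, which also emits a coordinate map.

## Comparison

Differences are reported in the reference's ungapped frame; columns with N
in either sequence are skipped everywhere ("missing", as distinct from a
gap). A maximal gap run counts as one indel event. Transitions are
purine↔purine / pyrimidine↔pyrimidine. Codon annotation is strand- and
phase-aware: reported bases are reference-strand, codons are
coding-orientation — necessary because *ND6*-like genes are light-strand
encoded. Translation uses NCBI table 2 (vertebrate mitochondrial) by
default; the tgg/tga pair in the shipped table is synonymous only under
it, which pins the code choice. Origin-spanning genes are represented as
two features sharing a name, concatenated in coding order.

The headline percent divergence uses the full reference length as
denominator (27/17,408 → 0.16 %; only this convention reproduces the
published rounding), while per-bp substitution rates use compared-site
counts; both are reported and labelled. Display rounding: two decimals for
percentages, four for per-bp rates. Distance matrices use pairwise
deletion (a column counts for a pair only if both rows have A/C/G/T);
pairs with no comparable columns are NaN-flagged. Global alignment of
near-identical genomes is delegated to edlib (edit-distance path), exposed
as `align_pair`; it is not a general-purpose aligner.

The exact boundaries of the high-divergence *ND6*/control-region interval
are not part of the shipped data (they require the GenBank annotation of
NC_057120, an external resource), so region-excluded summaries against the
published per-bp rates are not asserted anywhere; the count structure
(17 substitutions, 0 indels outside the tail) is checked with a synthetic
boundary, and the machinery accepts any interval set.

## Haplotype genealogy

Fitch small parsimony with fully deterministic tie-breaking: the root
takes the lexicographically smallest state of its set, children inherit
the parent state when it is in their set, otherwise their smallest state.
Sites with N or gaps contribute no state (and are skipped in the score);
two haplotypes are merged only if they agree on all sites where both are
defined, the merged sequence preferring definite bases. Zero-change
branches are contracted, identical haplotypes merged with multiplicities
accumulated, and remaining edges weighted by substitution counts between
class sequences; internal haplotypes matching no sampled sequence are kept
with multiplicity 0. Unrooted input trees are rooted at the first tip's
pendant edge; the collapsed graph is root-invariant (tested).

## Pipeline

One master seed fans out to per-stage child seeds by the fixed map
`(seed·1009 + stage·9973) mod 2³¹`, so stages are independently rerunnable
and identical configs give byte-identical outputs. The run report (JSON)
records stage counts: reads simulated, mapped, unique, duplicate-filtered,
consensus called fraction, differences found and recovered against truth.
Config files are flat `key=value` text; unknown keys are rejected by name.

## Problem sizes

Tests and the acceptance script run the full chain at study scale
(17,408 bp, 35×, ≈ 18,400 reads; five seeds for the recovery bound) and
use reduced instances only where an oracle is exponential (6-tip trees for
the exhaustive parsimony check; a 2 kb genome for the brute-force
full-scan mapper oracle). These sizes were chosen so each oracle remains
exact while the end-to-end claims are exercised at the scale the chain is
meant for.

## Known limitations

- No gapped mapping; structural variants and non-homopolymer indels
  surface only indirectly (reads over them drop out or vote at consensus).
- No base-quality modelling anywhere; qualities are placeholders.
- Consensus is haploid by construction (mitochondrial use case);
  heteroplasmy appears only as Ns via the tie rule.
- The repeat masker finds perfect repeats only; diverged repeats long
  enough to misplace reads are not auto-masked.
- Damage fitting assumes the exponential end-decay form; real profiles
  with composite chemistry may fit poorly (the residual is reported).
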