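# Methods

## Library chemistry model

The simulator follows the FTAS-seq workflow stage by stage.

**RNA sampling and reverse transcription.** Molecules are drawn
multinomially from the configured transcript pool. Each molecule is
fragmented by independent per-bond breaks at `degradation_rate`
(per-nucleotide probability; default 0 for cell-line-like presets, giving a
mean fragment length of L/(1+(L−1)p) — approximately 1/p for long
transcripts). Each fragment is reverse transcribed either from a uniform
internal position (random priming) or from its 3' end, with
`random_priming_fraction` (default 0.5) choosing between the two. Priming
at a fragment's 3' end is a simplification of oligo(dT) priming: it lets
degraded fragments act like polyadenylated ends, which slightly overstates
cDNA coverage of internal regions on degraded inputs. A cDNA span can only
template second-strand synthesis if it covers the full outer-primer site.

**Terminator-assisted second-strand synthesis.** Competition between a
dNTP and its OTDDN analogue is modeled as concentration-proportional with
equal incorporation efficiency, because no kinetic constants are available
for the modified nucleotides; the per-incorporation termination probability
in each pyrimidine channel is therefore
`p_term = [terminator] / ([terminator] + [dNTP])` — 0.100 per C and per T
at the default mix (1 µM dATP/dGTP, 0.9 µM dTTP/dCTP, 0.1 µM of each
terminator). Termination may occur on the first base after the primer.
Extension is linear: one nascent strand per template per cycle
(`extension_cycles`, default 15); a single primer cannot amplify
exponentially. The number of pyrimidine incorporations before termination
is geometric; the sampler draws termination positions directly from the
resulting per-template discrete distribution (inverse CDF over the
position-wise hazard), which is exact and fast. Molecules that run off the
template end carry no OTDDN and therefore no reverse priming site; they are
dropped at the PCR stage. This is a modeling consequence of the chemistry
(the adapter enters the molecule only through terminator incorporation).

**Nested PCR, size selection, sequencing.** Surviving molecules are
re-anchored to begin at the nested primer's 5' position (nested
specificity: molecules not covering the inner primer site are dropped).
Copy number follows a Galton–Watson branching process,
X ← X + Binomial(X, `pcr_efficiency`) per cycle (default 0.9 over 20
cycles; the 3–7 reamplification cycles of the bench protocol are folded
into this count). Inserts outside `size_window` (default 50–700 nt,
abstracting the double-bead cleanup) are removed. The sequencer emits
2×150 nt reads: R1 from the nested primer into the OTDDN adapter and
post-adapter flank on short inserts, R2 from the terminated base back
toward the primer into the reverse-complemented P5 flank; bases beyond the
physical molecule are filled with low-quality (Q2) G calls, as a two-color
instrument would report. Substitution errors are i.i.d. at
`substitution_error_rate` (default 10⁻³); error positions carry Q12,
all other real bases Q34; indels are not modeled. When a target `depth` is
set, the sequencer samples that many pairs multinomially proportional to
amplified copy number and records the sampled count as each molecule's
`duplicate_count`, so the truth sidecar is conserved: the duplicate counts
sum exactly to the emitted pairs.

**Seeds.** One master seed; per-replicate and per-stage generators are
derived as `default_rng([seed, replicate, stage])`, so replicates are
independent but individually reproducible, and identical seeds give
byte-identical FASTQ.

## Toy reference

`make_toy_reference` writes a two-chromosome genome (~16 kb): chrA carries
a TMPRSS2-like anchor gene (7 exons; exon 1 is pure 5'UTR and embeds the
real outer extension primer upstream of the real nested primer) and an
ERG-like partner (8 exons), making TMERG-like events intrachromosomal;
chrB carries a GAPDH-like housekeeping gene and PPP3CA-, AMACR-, SIM2-,
TTC18- (minus-strand), FGFR2- and lincRNA-like partners for
interchromosomal, inverted-intron and noncoding junction classes. Exon and
CDS lengths are fixed design constants chosen so that documented junction
classes have the intended codon phase (e.g. anchor exon 3 → PPP3CA-like
exon 2 is in-frame); only the background sequence is random. Both primer
sites are verified unique genome-wide (both strands); the background is
re-drawn deterministically in the astronomically unlikely event of a
collision. Junctions in the bundled presets sit near the primer because the
terminator chemistry yields short fragments (median extension ≈ 20 nt at
p_term = 0.1); breakpoints far from the anchor primer are genuinely hard
for this chemistry at 2×150, and the toy design reflects that constraint
honestly rather than hiding it.

What the generator does **not** emulate: real exon sequence composition
and repeats (background is i.i.d. uniform), multi-isoform annotation,
quality-score profiles of real instruments, indels, optical duplicates,
and chimera formation during PCR. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
performance on real libraries.

## Fusion calling

**Anchor and insert reconstruction.** R1 must begin with the nested primer
(≤ `anchor_max_mismatch` = 1 substitution); everything else is off-target.
Adapter stubs shorter than the trimmer's minimum k-mer (11) can survive
trimming; because both library flanks are known, the caller end-clips any
read tail matching a prefix of the OTDDN adapter (head matching a suffix
of the P5 flank) before analysis — without this, the shared
`AGATCGGAAG` adapter prefix systematically mis-maps as a partner segment.
Mates are overlap-merged into the sequenced insert; R1 bases are preferred
in the overlap.

**Split mapping.** The merged insert is scored as an anchor-transcript
prefix plus a partner suffix (match +1, mismatch −1, gapless segments).
Partner candidates come from exact 15-mer seeds over an annotation-aware
reference set: each gene's spliced transcript, one "intron-retention tail"
per intron (the intron followed by the remaining spliced transcript), and
each intron reverse-complemented (for inversion-type junctions). Splice
junctions are therefore handled by construction, and a partner hit inside
the anchor gene's own introns is classified wild-type read-through, not a
fusion. When the partner segment is too short to contain a full seed, a
dense scan of the insert's terminal `min_overhang` bases (≤ 1 mismatch)
rescues the diagonal. Acceptance requires: both segments ≥ `min_segment`
(10 nt), both junction overhangs ≥ `min_overhang` (10 nt), total mismatches
≤ 12% of the insert, the chimeric score to beat the anchor-only score by
`chim_score_margin` (8 — sequencing-error artifacts re-score a read by
only 2–4 points, a true ≥10 nt partner flank by ≥ ~15), and the fragment
to extend ≥ `min_overhang` bases past the longest anchor prefix explainable
within the wild-type mismatch tolerance (fragments terminating just past a
junction are not trustworthy split evidence). Competing junctions scoring
within `score_separation` (2) of the best flag the read ambiguous;
ambiguous reads are excluded from calls. Ties at equal score prefer an
annotated exon boundary, then the leftmost junction.

**Deduplication and calls.** The anchored design fixes the fragment start,
so the terminator-incorporation coordinate is the sole molecular
identifier (no UMI): alignments identical in (junction, termination
coordinate, strand) collapse to one unique fragment. Junctions within
`junction_merge_window` (3 nt; reported at the modal coordinate) cluster
into calls. Confidence is a transparent evidence tier — *high*: ≥ 5 unique
fragments and ≥ 2 distinct termination sites; *medium*: ≥ 2 fragments;
*low*: otherwise — a deliberate substitute for aligner-internal confidence
models, with thresholds in the configuration and a note in every report
header. Calls must recur (within the merge window) in both technical
replicates; with `require_both_replicates=false` one-sided calls are kept
and flagged. Raising `min_overhang` only filters output — it never
redirects the split search — so the call count is monotone non-increasing
in it.

**Isoform naming.** `<5'code><unit>-<3'code><unit>` with configurable gene
letter codes (T, E, P, A, S, TTC, F, …; unknown genes are an error, not a
guess). Units are arabic exon numbers at exon boundaries (the canonical
transcript's numbering, in transcript orientation) and Roman numerals of
the preceding intron for intronic breakpoints. Forward-orientation intronic
breakpoints always carry a lowercase letter, assigned a, b, … by ascending
distance from the preceding exon within a call set (so a lone retained
intron 3 in the ERG-like gene names as `EIIIa`); inverted-intron
breakpoints are unlettered (`SVI`), with the inversion recorded in the call
record. Exonic-internal breakpoints render as the containing exon's number.

**Reading frame.** A junction is *in-frame* when both breakpoints lie
within (or at the boundary of) annotated CDS and the cumulative CDS length
5' of the junction is congruent mod 3 to the partner's CDS offset at the
first retained base; *out-of-frame* when both sides are coding but the
phases differ; everything else is *unclear* — a UTR-only 5' segment, an
intronic/inverted/noncoding 3' breakpoint, a noncoding partner, a
breakpoint outside the partner's CDS, or annotated partner transcripts
that disagree on phase. A 5' breakpoint past the CDS end (retaining the
stop codon) is also unclear: no fusion protein can be predicted.

**Inverted-intron segments.** The 3' segment of an inversion-type fusion is
modeled as the reverse complement of the intron from its 5' end up to the
breakpoint, and the transcript ends there — a genomic inversion breaks
colinearity beyond the junction, so no downstream exons are appended.

## Problem sizes and study conditions

The fusion-positive preset mixes the five-isoform TMERG-like panel at
abundance 1 each against housekeeping 1000 and wild-type anchor 50 (the
fusion:housekeeping ratio is the assay's measured ~1000-fold; the
wild-type anchor level is a package choice reflecting high TMPRSS2
expression in prostate tissue). The end-to-end positive condition runs
2 replicates × 10⁵ read pairs from 10⁵ sampled cDNA molecules per
replicate; the negative (LNCaP-like) condition is exercised across 20
seeds at 4 000 pairs / 20 000 molecules per replicate — the identical
pipeline at a per-seed scale chosen to keep the 20-seed sweep quick.
Termination-chemistry statistics use ≥ 10⁵ pyrimidine incorporation events
on a 500 nt template. Goodness-of-fit to the geometric termination law is
tested by Kolmogorov–Smirnov after a randomized probability integral
transform, which makes the discrete statistic exact.

## Known limitations

- Single canonical transcript per gene drives naming and reference
  construction; additional transcripts are consulted only by the frame
  classifier's disagreement rule.
- No indel handling inside segments and no read-coordinate gap at the
  junction; the simulator generates none.
- Fragments ending within `min_overhang` of a junction are deliberately
  discarded as evidence; isoforms whose only coverage is such fragments
  (junctions far from the primer) are undetectable — a faithful property
  of the chemistry at short read lengths.
- The termination-coordinate deduplication undercounts when two distinct
  molecules terminate at the same base, so `unique_fragments` is a lower
  bound on sampled molecules.
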