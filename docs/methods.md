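# Methods

## Problem setting

MSR-seq captures tRNA 3′ ends with a capture hairpin oligo (CHO) and
sequences the resulting library paired-end. Because tRNAs are short
(~70–90 nt gene body) and heavily modified, three analysis problems
dominate: (i) reverse transcription is perturbed by modified bases —
producing misincorporations, small indels, and *hard stops* that truncate
cDNAs; (ii) tRNA gene families contain near- or fully identical copies, so
read attribution must account for multimapping; (iii) low-count signals
must be separated from index hopping and cross-contamination, which is
what no-template-control (NTC) libraries calibrate. This package
implements the full path from raw read pairs to per-reference expression,
maturation, modification and anticodon-variant calls, plus a generative
simulator that provides ground truth for every stage.

## Reference model

References are stored as gene bodies without the post-transcriptional CCA.
The mapping reference appends `CCA` to every entry whose tail is not
genomically encoded; `gene_end` is the exclusive end of the gene body
(index of the first tail base), so `gene_end + 3 == len(mapping_sequence)`
holds for all entries. This makes 3′ maturation decidable purely from
alignment coordinates and matched tail bases. For genes that carry a
genomic CCA the construction is a no-op and their tail calls are flagged
non-informative, since presence of CCA there says nothing about
processing. Anticodon coordinates are explicit metadata (a 0-based
half-open span validated against the sequence) rather than inferred from
secondary structure: annotation conventions for anticodon numbering vary,
and making the span explicit removes the ambiguity. Duplicate sequences
under distinct ids are deliberately legal — they are the test surface for
multimapping ties. Gene lengths are restricted to 50–120 nt.

## Simulator

Each read pair is generated as: reference draw ∝ abundance weight → tail
state draw → reverse transcription 3′→5′ over the molecule → optional 5′
extension → CHO adapter appended → R1/R2 emitted from the two construct
ends with iid substitution errors.

- Tail states remove 0/1/2 terminal bases (CCA/CC/C) or the tail plus
  k ≥ 2 gene bases (`TRUNC_k`; plain `TRUNC` draws k uniformly from 2–8,
  emulating heterogeneous 3′ degradation and tRFs).
- At a modified site the RT stops with probability `stop_prob` (the read's
  5′ terminus becomes the next position toward 3′) or, failing that,
  misincorporates with probability `misincorp_prob`; stop and misread are
  mutually exclusive per read per site. Sites are visited 3′→5′, so a
  stop shadows all sites 5′ of it. A stopped RT never reaches the 5′
  extension, so stopped reads carry none.
- The default tail mixture is {CCA 0.65, CC 0.25, C 0.05, TRUNC 0.05},
  within the range reported for real inflorescence libraries (65–70%
  CCA-tailed at the high end, with CC-tailed transcripts next); the
  default 5′-extension probability is 0.1 with lengths 1–12 nt; qualities
  are constant Q30 by default, with a two-state Markov model (Q37/Q12)
  available to exercise quality-scaled penalties.
- NTC libraries emit a contamination read (drawn from a donor profile)
  with probability `contamination_rate`, else an adapter-dimer construct
  that preprocessing rejects as too short — mirroring how real NTCs yield
  a tiny mappable fraction out of many junk reads.
- One master seed; per-library streams are derived by CRC-hashing the
  library name, so adding a library never perturbs another library's
  reads. Identical configs are byte-reproducible.
- The default adapter is a 33-nt surrogate constant; the real CHO sequence
  is protocol-specific and must be supplied in the config when processing
  real data. Barcodes/UMIs are out of scope: the pipeline consumes
  demultiplexed libraries.

What the simulator does *not* emulate: ligation and PCR amplification
biases (real per-gene abundances are strongly method-biased, which is why
only relative comparisons are meaningful), secondary-structure-dependent
RT processivity, quality-correlated error profiles, and chimeric reads.
Passing recovery tests therefore demonstrates correctness of the analysis
logic under the stated generative model, not robustness to every artifact
of real libraries.

## Preprocessing

Merging scans suffix(R1)/prefix(rc(R2)) overlaps of at least
`min_overlap` (default 10) and keeps the qualifying overlap (mismatch
rate ≤ 0.1) with the lowest mismatch rate, ties to the longest;
disagreeing bases resolve to the higher-quality call. Merging is
implemented natively (no external merger binary): the acceptance surface
is this contract, not bit-parity with any particular tool. The adapter is
located as the best full-length window (fewest mismatches, ties toward
the 3′ end, default tolerance 2); the window and everything 3′ of it are
removed, and reads with no window or with < 15 remaining bases are
rejected. Every input pair lands in exactly one of
{processed, rejected_no_merge, rejected_no_adapter, rejected_too_short}.

5′ extensions are trimmed by seeded local alignment (exact 11-mer seeds,
Smith–Waterman with match +1 / mismatch −2 / affine gaps 5,2, minimum
local score 20): only read bases that project 5′ of reference position 0
are removed, so internal fragments and aligned bases are never touched.
Reads without a seeded hit pass through unchanged.

## Alignment

The native aligner is exact dynamic programming: global in the read,
local in the reference (free start/end in the reference only), affine
gaps costing `open + extend·length`, match bonus 0, and mismatch penalty
interpolated by base quality, `MN + (MX−MN)·min(Q,40)/40` with
MN = 2, MX = 5; `N` bases always cost MN. A read is accepted when its
best score reaches `−0.7 − 0.7·L`. Scores are computed on a ×40 integer
scale so the quality interpolation is exact and score ties are
unambiguous — "maps equally well" is defined as an exact score tie, and
the tie set is preserved on every record. The lexicographically smallest
tied reference becomes the primary SAM record (a deterministic stand-in
for a mapper's arbitrary tie choice); NH carries the tie count and ZT the
tie ids. An exact-substring fast path short-circuits the DP when the read
occurs verbatim in a reference (score 0 is then provably optimal and the
tie set is exactly the set of containing references); this keeps 50k-read
runs in seconds. There is no heuristic seeding in the native aligner —
`seed_length` is retained as a config field for parity with external
mapper conventions but full DP is always used, which is what makes exact
oracle equivalence testable. Traceback prefers diagonal moves and breaks
end-position ties toward the smaller reference coordinate, so SAM output
is byte-deterministic.

## Pileups, tails, modifications

`classify_tail` returns NOT_3PRIME when the alignment ends before the
last gene-body base; otherwise the number of tail positions covered by
match operations *with agreeing bases* maps 3/2/1/0 → CCA/CC/C/NONE
(a sequencing error in the tail therefore counts as absence — at the
error rates in scope this biases tail fractions by well under a
percentage point). Reported totals count all mapped reads regardless of
tail state, so CCA-vs-total tables are directly comparable across
references.

Pileups count depth as reads spanning a position (deletions included),
insertions at the reference position following them, and each read's
5′-most aligned position as a read start. Reads contribute to the pileup
of their primary reference only, so profiles never double-count (an
all-ties mode for sensitivity analyses can be layered on by the caller by
re-running attribution with expanded record lists). The stop score at p is
`read_starts(p+1) / depth(p+1)`: a stop *at* p removes coverage at ≤ p
and piles starts at p+1, so one statistic captures both the start pile
and the coverage drop; under the generative model its expectation is the
stop probability itself (reads not reaching p+1 are excluded by the
denominator).

A position is called modified when depth ≥ `min_depth` (20) and
misincorporation rate ≥ τ_mis (0.10) and/or stop score ≥ τ_stop (0.30).
The first 2 and last 5 gene-body positions are masked (tail- and
adapter-adjacent artifacts; the 3′ mask also absorbs the tail itself).
The thresholds are deliberately loose operating points for signatures
that real studies report qualitatively: a 0.1% sequencing error rate
sits two orders of magnitude below τ_mis, while genuine modification
signals in this assay run at tens of percent.

## Attribution and expression calls

Per-reference totals are tie-inclusive (a read "maps to" every reference
in its tie set); unique counts require a singleton tie set; compartment
rollups and tail tallies use primary attribution so they sum to the
mapped-read count. Expression requires unique reads strictly above the
background threshold

    threshold(ref) = max(k_min, multiplier · r_NTC(ref) · N_mappable)

with k_min = 10 and multiplier = 2. `r_NTC` is the reference's pooled NTC
count divided by the NTC *sequencing depth* (input read pairs), i.e. a
per-sequenced-read contamination rate; multiplying by the sample's
mappable count predicts the background the sample accrues from index
hopping alone. Normalising by NTC mappable reads instead would be
degenerate — an NTC with a handful of mapped reads would push thresholds
to the scale of the whole library. k_min = 10 encodes that signals of a
few reads are only meaningful with corroboration (CCA tails,
modification calls), which the rationale string records. A reference
whose total clears the threshold purely through multimapping reads is
`ambiguous_only`: likely a pseudogene or silent duplicate whose apparent
reads belong to an expressed homolog.

## Anticodon variants

For a reference of interest, every read whose alignment covers the
anticodon span with match operations only contributes its observed
3-mer; reads with an indel across the span are excluded and counted. A
candidate variant is *supported* when its read count ≥ k (20) and its
frequency is ≥ f (5)-fold the control-library frequency, with the
control frequency floored at 1/n_control to keep an all-zero control from
dividing out. The comparison is count-plus-enrichment by design — the
biological question ("is this variant above the background seen in a
standard-genetic-code species?") is qualitative — and a one-sided
binomial p-value is attached as auxiliary output only. Tie-ambiguous
reads within an isotype still contribute via their primary reference;
anticodon evidence is locus-agnostic within an isotype.

## Pipeline and determinism

The `run` orchestration processes NTC libraries first, pools them into
one background table, and emits per library: SAM, alignment table,
counts, tail calls, modification calls, preprocess accounting, expression
JSON, plus run-wide background thresholds, anticodon tallies and a run
log (version, seed, parameter echo). Unknown config keys are rejected.
Any stage failure aborts with the stage name in the message. All outputs
are byte-identical across re-runs of the same config; the run log carries
the only timestamp.

## Verification strategy and problem sizes

Every operation with a nontrivial contract is tested against an
independent oracle: the aligner against a plain full-matrix DP
re-implementation (500 random read/reference pairs at up to 15% error,
plus a cigar-implied score recomputation that audits the traceback), the
tail classifier against a brute-force suffix comparator over all 0–5 nt
truncations, merging against an exhaustive overlap scan, and the
simulator against binomial/Poisson expectations at 3σ. End-to-end
recovery runs use 50,000 pairs for tail mixtures (matching the intended
per-library scale of the assay), 6,000 pairs across 20 references for
modification recovery (per-site depth ≈ 300, comfortably above the
min-depth gate), a 20,000-pair sample with a 50,000-pair NTC for the
expression panel, and 4,000-pair libraries for anticodon mixtures —
sizes at which binomial noise is far inside the stated tolerances while
a full run stays in tens of seconds on one CPU.

## Known limitations

- The aligner is exhaustive over references; it is designed for curated
  tRNA reference sets (tens to hundreds of sequences), not genome-scale
  indices.
- Bit-parity with any specific external short-read mapper is not claimed;
  the native scoring contract (quality-scaled penalties, linear score
  threshold, exact ties) is the specification, and no external-mapper
  mode is bundled.
- Abundances are raw counts; no cross-library normalisation or
  differential expression is attempted, since tRNA-seq abundances carry
  strong protocol biases and only relative comparisons are meaningful.
- Aminoacylation (charging) state is out of scope; the pipeline analyses
  untreated libraries only.
- The NTC background model treats contamination as uniform per sequenced
  read; it does not model reference-specific carryover.
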