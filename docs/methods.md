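# Methods

This note documents the models, conventions and numerical choices behind
`triad`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and edit conventions

All positions are 0-based; intervals are half-open `[start, end)`;
insertion points are inter-base indices. A transposition site is the
index `s` of the first base of the 5-bp window the transposase
duplicates. The deletion/insertion windows implemented in
`triad.mechanism` follow directly from the cassette chemistry: the −3 bp
deletion removes `[s+1, s+4)`; −6 bp removes `[s−2, s+4)` (orientation A)
or `[s+1, s+7)` (orientation B); −9 bp removes `[s−2, s+7)`; insertions
place the randomized triplets at `s+5` (A) or `s` (B). A site is valid
when both the 5-bp duplication window and the edit window lie inside the
available sequence (gene plus optional vector flanks); with flanks, edit
windows must additionally intersect the gene. Blunt-end ligation and
transposon insertion are direction-agnostic, so both mirror-image
outcomes are enumerated with equal weight where they differ (−6 bp and
insertions); `orientations="A"` restricts to the single-orientation
model.

## Canonicalisation and ambiguity

Neighbouring events in repetitive context can produce byte-identical
mutant sequences. Every edit is reduced to its leftmost placement
(VCF-style left alignment; insertions shift with payload rotation), and
the *ambiguity interval* records the full contiguous set of equivalent
start positions. Left alignment is a deterministic stand-in for the
arbitrary assignment any caller must make; all per-position statistics
attribute a unique variant to its canonical (leftmost) position, while
read counting divides each read's weight equally across its ambiguity
interval so positional totals are conserved exactly (checked to 1e−9).

## Protein consequences

Net length changes not divisible by 3 are frameshifts. In-frame changes
are diffed against the wild-type protein by longest common prefix, then
longest common suffix (prefix maximised first — the tie-break matching
left alignment). The differing middle defines the deleted/inserted
residues: middles of shape (k, 0)/(0, k) are clean InDels; (k+1, 1)/(1,
k+1) carry one flanking substitution, the signature of a cross-codon
event; a stop codon in the mutant middle is a truncation; identical
proteins are silent (possible only in triplet-substitution mode). On a
codon-aligned ORF exactly two of three single-triplet deletion windows
cross a codon boundary — a purely positional fact the test suite checks
by exhaustive enumeration.

Theoretical protein diversity of the +9 bp library is estimated as 21×
the +6 bp value (20 amino acids + stop per extra randomized triplet)
rather than enumerated; the same rule chains from +3 bp when the +6 bp
space is itself above the enumeration cap (default 5 × 10⁶ variants,
a desk-scale memory bound).

## Synthetic-data generator

`readsim` emulates the features of a deep-sequenced InDel library that
the caller and profiler must survive, with defaults chosen to match the
regime such experiments report:

- **Site preference** — an optional 5×4 weight matrix applied to each
  site's duplicated 5-mer on both strands (transposon direction is
  unknown). Member abundance is log-normal(0, σ = 1.0 by default)
  multiplied by the normalized site weight: a preferred site receives
  more independent transposition events and therefore more reads. This
  coupling is what makes read-count-weighted PWM recovery possible at
  all; with membership-only bias, sampling most sites without
  replacement would flatten any finite preference.
- **Abundance skew** — log-normal σ = 1.0 at depth ~20–50 puts most
  variants in the 10–99 reads-per-variant bin, the regime reported for
  real deletion libraries.
- **Frameshift contamination** — a per-member Bernoulli rate (default
  0.04, the observed −3 bp library rate; >0.2 is realistic for the
  others) replaces the member with a ±1/±2 bp edit at the same site.
- **Reads** — full-fragment "merged" reads (130 bp default) or 2×75 bp
  pairs whose exact ≥20 bp overlap a naive merger reconstructs;
  substitution errors i.i.d. at the configured rate (default 10⁻³),
  constant Q30 qualities. Sequencer InDel errors, quality profiles, PCR
  duplicates and adapter artefacts are *not* modelled, so passing
  round-trip tests demonstrates correctness of the calling logic under
  substitution noise, not robustness to every real-world artefact.

## Caller

Reads are globally aligned to the reference with affine gaps (match +5,
mismatch −4, gap open 15, gap extend 0.5; a length-L gap costs
open + L·extend). The gap penalties are the standard ones for this
analysis; match/mismatch are EDNAFULL-like defaults and configurable.
End gaps on the read are free (semi-global) because reads are internal
fragments of the sequenced insert. The alignment engine is Biopython's
`PairwiseAligner` (C implementation); the test suite carries an
independent pure-Python Gotoh dynamic program and checks score equality
on hundreds of random instances. Isolated mismatches are ignored as
sequencing errors; exactly one run of three contiguous mismatches with
no gap is reported as a triplet substitution; reads with more than one
separated edit are classed `complex` and excluded from positional
tables.

## Bias profile

The transposition PWM adds, for each unique −3 bp deletion with
canonical window `[p, p+3)`, the 5-mer `seq[p−1, p+4)` and its reverse
complement at half the variant's depth-normalized weight. The consensus
calls per position the most specific IUPAC class among A/C/G/T, R, Y, S,
W reaching proportion ≥ 0.75, else N. The threshold is deliberately
high so that genuinely weak preferences produce degenerate or N calls.
Note the arithmetic this implies: under read-count weighting an odds-k
preference yields an expected class proportion of k/(k+1), so a 2:1
preference (0.67) can never reach the 0.75 threshold in expectation —
closed-loop recovery is therefore demonstrated at a 6:1 effect with
abundance σ = 0.3, and an unbiased library is shown to give `NNNNN`.
When a deletion's ambiguity interval spans several positions, only the
canonical leftmost window enters the matrix.

## Fitness and kinetics

Fitness bins partition the wild-type-relative activity ratio r at 0.1,
1/1.5 and 1.5; boundary values 0.1 and 1.5 fall in the milder class
(mildly deleterious and neutral respectively) — the published wording is
open-interval ambiguous, so the convention is fixed here. Censored
(below-detection) measurements are floored at 0.01, the typical printed
detection limit; geometric means include them at the floor by default,
with an exclusion mode provided. The specificity ratio is defined as
rel_AE / rel_PTE (promiscuous gain over native retention), which
reproduces the >100 strong-trade-off diagonal; the term is used in the
field without an explicit formula, so the definition is stated here.

Michaelis–Menten parameters come from `scipy.optimize.curve_fit`
(bounded, initialized at V_max = max v₀ and K_M = S at half-max);
standard errors from the parameter covariance. K_M is flagged
non-identifiable when its relative SE exceeds 50 % (e.g. saturating-only
designs). Parameter recovery holds to <1 % on noiseless curves and
within 10 % at 5 % multiplicative noise when rates are measured in
triplicate at 8 concentrations spanning 0.2–4 K_M — single measurements
at 5 % noise can miss K_M by >20 %, which is why replication is part of
the stated recovery condition. Melt curves are smoothed with a 5-point
moving average and differentiated centrally; Tm is the derivative
maximum, flagged unreliable when it sits at the grid boundary or lacks
prominence over the baseline derivative (flat or linearly ramping
traces).

## Problem sizes and determinism

Every stochastic step consumes an explicit seed; identical seeds give
byte-identical FASTQ/TSV outputs. The standard demonstration sizes are
a 999-bp synthetic ORF (restriction-site-free by rejection sampling,
retry cap 1000), 500-variant libraries at mean depth 30 for round-trip
checks (~15 000 reads), 600-variant libraries at depth 10 for bias
recovery, and a 60-bp toy gene for exhaustive brute-force comparisons —
sizes chosen so the full analysis remains a desk-scale computation.

## Known limitations

- Transposition biochemistry (MuA kinetics, selection bottlenecks) is
  not modelled; site bias and sampling stand in for it.
- The flank model excludes edits wholly inside a flank but does not
  model vector re-circularisation beyond that.
- `dna_unique`/`protein_unique` above the enumeration cap fall back to
  documented estimates (naive upper bound, 21× chaining) with warnings.
- The caller ignores base qualities and classifies mixed
  InDel-plus-substitution reads by their gap edit alone; mismatches
  outside the edit are attributed to sequencing error.
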