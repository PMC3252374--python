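# Methods

## Overview

`alucensus` takes a census of exact transcription-factor binding k-mers in
repeat elements. Its model of the problem has three layers:

1. a **binder set** — the k-mers a factor binds, determined from replicate
   protein-binding-microarray (PBM) scores against a random-control null;
2. a **site map** — every exact occurrence of every binder k-mer in a
   genome, assigned to annotated repeat copies;
3. **summaries** — per-k-mer frequencies, per-element multiplicities,
   per-family prevalence, consensus-position histograms, and
   promoter/accessibility statistics.

The package is exercised end to end on synthetic genomes whose ground
truth is known exactly, so every stage has a frozen oracle.

## Binder calling

A probe's score is the unweighted arithmetic mean over all replicate spots
of all grids (the reference array design prints each probe 4 times on each
of 4 grids; any replicate layout is accepted, and missing spots are
ignored). The binder threshold is

    threshold = mean(controls) + m * sd(controls),   m = 2 by default,

where the mean and the sample SD (n−1 denominator) are taken over the
mean scores of the random negative-control probes. The sample SD is used
because it is the conventional unbiased-variance estimator; at the control
counts involved (≥ 100) the distinction from the population SD is
negligible. A probe is a binder iff its mean score is **strictly** greater
than the threshold.

Two p-values are available per probe: the default empirical value against
the control score distribution with an add-one correction,
p = (#controls ≥ s + 1)/(n + 1), which can never be exactly zero and
equals 1/(n+1) for a score above every control; and a parametric
upper-tail value under Normal(control mean, control SD). The empirical
form is the default because it makes no distributional assumption about
control scores.

Position weight matrices are per-position base frequencies of the bound
sequence set, with no pseudocount by default (an optional pseudocount is
supported); information content per position is 2 + Σ_b f log₂ f bits with
0·log 0 = 0. Bound sets of different lengths (13- and 14-mers) are given
separate matrices — no alignment or padding is attempted, since a
single-position register shift would smear the matrix.

## Genome scanning

The scanner reports every exact occurrence of every query k-mer,
overlapping occurrences included. All patterns of one length are held in
a hash map keyed by window sequence, so the genome is traversed once per
distinct pattern length regardless of pattern count. In the default
`both`-strands mode the map also keys each pattern's reverse complement;
a reverse-complement palindrome yields a single, plus-strand hit
(canonical orientation) rather than a double count. Lowercase
(soft-masked) genome bases match after uppercasing; `N` never matches,
because only A/C/G/T patterns are admitted. Both-strands is the default
because binder sets typically contain near-reverse-complement pairs and a
direct-repeat site is readable from either strand; `plus_only` is kept as
a sensitivity-analysis flag. Correctness, not the traversal strategy, is
the contract: the test suite checks multiset equality against a naive
O(n·m) sliding-window oracle on 100+ random instances in both modes,
plus a reverse-complement-invariance property.

## Repeat assignment and consensus coordinates

Genomic coordinates are 0-based half-open throughout; 1-based inclusive
conversions happen only at the RepeatMasker `.out` boundary, where
minus-strand ("C") rows carry their consensus columns in the
`(left) end begin` layout. Subfamilies classify into families by prefix
(AluY*/AluS*/AluJ*) plus the exact monomer names FLAM_A, FLAM_C, FRAM and
FAM; everything else is `other_named` and keeps its subfamily name for
non-Alu reporting. SVA elements, although they contain Alu-derived
sequence, are deliberately left in `other_named` and reported among
non-Alu families.

A hit is *in* a repeat only when its interval is fully contained in the
repeat interval. Containment (rather than ≥ 1-nt overlap) avoids
double-counting a k-mer that straddles an element edge and makes
per-element multiplicity well defined; hits that overlap without
containment are flagged `partial` and counted as outside in all census
tables. When nested or overlapping annotation places a hit inside several
features, the owner is the feature with the smallest start (then smallest
end) and the hit is flagged ambiguous — a deterministic rule chosen so
multiplicity counts are reproducible. The consensus-relative position of a
contained hit is `consensus_begin + (hit.start − repeat.start)` on the
plus strand and `consensus_begin + (repeat.end − hit.end)` on the minus
strand, 1-based, so positional histograms from both strands align on the
same consensus axis.

Promoter and accessibility analysis intentionally uses the different
≥ 1-nt overlap rule, and counts *elements* (repeat copies with ≥ 1
contained binder site), not individual k-mer hits: a promoter window is
the W = 5000 bases strictly upstream of the TSS, strand-aware, half-open,
clipped at contig bounds and flagged when clipped. The enrichment cutoff
is ceil(mean + k·SD) of per-gene element counts (k = 2, sample SD;
degenerate SD = 0 falls back to ceil(mean)); the ceiling reproduces an
integer cutoff from fractional summary statistics.

## Percent rendering

Every percentage cell is round-half-up(100·a/b, 2) computed in decimal
arithmetic, so table cells are exactly recomputable from their own integer
columns and never depend on binary-float rounding at .005 boundaries.
Division by zero is guarded: a k-mer with no genome occurrences gets an
empty percent cell. Machine TSV outputs carry bare integers; thousands
separators belong only to pretty renderings.

## Synthetic data

The generator emulates the statistical structure the census assumes:

* **Consensus set** — `n_consensus` iid sequences over A/C/G/T at
  `gc_content` (default 0.41, human-like), default length 300 nt, named
  `AluY_syn1`, `AluS_syn1`, `AluJ_syn1`, … so the prefix classification
  maps them onto family classes.
* **Genome** — an iid background (no higher-order composition model; the
  analysis is composition-agnostic at exact-match level) of
  `genome_length` bases (default 200 kb) into which `n_copies_per_consensus`
  (default 50) copies per consensus are planted, shuffled, separated by
  multinomially distributed gaps and therefore never overlapping, each on
  a random strand.
* **Divergence** — each copy receives iid substitutions at its family's
  rate; the default ladder 0.02 / 0.10 / 0.25 represents young,
  intermediate and old families. A 13-mer survives a copy intact with
  probability (1 − r)^13, which is what produces the monotone young > old
  percent-with-site ordering in the family census.
* **Truncation** — with probability `truncation_prob` (default 0.1) a copy
  is 5'-truncated, keeping at least `min_copy_fraction` (default 0.5) of
  the consensus; consensus offsets are recorded RepeatMasker-style
  (1-based inclusive). Truncation is 5'-only, mirroring the left-monomer
  structure of real dimeric Alu elements.
* **PBM scores** — every spot score is Normal(μ, `pbm_sd`) with μ =
  `pbm_binder_mean` (0.75) for designated binder probes and
  `pbm_control_mean` (0.452) otherwise; `pbm_sd` (0.08) is spot-level
  noise. These defaults place control mean + 2·SD at 0.612 on the spot
  scale — the published cutoff of the reference array — and, after
  16-replicate averaging, an operative threshold near 0.49 on mean scores,
  far below the binder mean, so designated binders are recovered at the
  normal-tail rate.
* **Fixture bundle** — genome FASTA, consensus FASTA, RepeatMasker-style
  `.out` + BED6 annotation, TSS BED, accessible-region BED, PBM TSV, and
  a ground-truth plants TSV. Probe/binder selection in the bundle is
  stratified per family (top-N/`n_consensus` k-mers of each family's own
  consensus): because the synthetic consensus sequences are mutually
  unrelated, a global frequency top-N would be monopolized by the least
  diverged family, whereas real repeat subfamilies share ancestry and
  overlap in k-mer content.

All randomness derives from one integer seed through per-component
substreams (`default_rng([seed, component])`), so a fixed configuration
reproduces byte-identical bundles.

What the generator does **not** emulate: real Alu sequence structure
(A-tails, CpG decay, the left/right-arm homology), insertion-site
preferences, nested or overlapping annotation, GC isochores, and
alternative TSSs. Passing tests therefore demonstrate correctness of the
census machinery under the stated statistical assumptions, not biological
fidelity of any particular number.

## Problem sizes

The default study conditions — 200-kb genome, 3 families × 50 copies of a
300-nt consensus, 100 probe + 100 control PBM, 5-kb promoter windows over
20 genes — are desk-scale choices that keep every property checkable
exactly while preserving the shape of the full-genome analysis; the
scanner and interval machinery are linear in genome size and support much
larger inputs unchanged. Calibration tests use 5000 control-distributed
probes so the false-binder rate is estimated with ~0.2% binomial SE.

## Known limitations

* Exact matching only — no mismatch-tolerant search; a diverged site is
  either intact or invisible.
* One TSS per gene; the TSS table owns that choice.
* BED6 repeat input carries no consensus offsets, so copies read from BED
  are assumed full-length from position 1.
* The published total of 3802 unique array sequences is not enforced in
  library assembly: the printed per-category counts sum to 3883 and the
  deduplication rule that yields exactly 3802 is not recoverable, so the
  library reports both raw and unique sequence counts instead of forcing
  either.
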