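# Methods

## Coordinate system

All genomic intervals are 0-based half-open (BED convention); reports and
the CLI print 1-based inclusive strings (`chr7:109876329-111966581`), and
`region_size_mb` measures such a string in Mb at one-decimal rounding.
Restriction fragments are produced by an exact-string scan for the
recognition site (leftmost-first; IUPAC ambiguity codes unsupported; sites
never match across N); cut coordinates are `site_start + cut_offset` with
top-strand offsets HindIII A^AGCTT = 1, BglII A^GATCT = 1, NlaIII CATG^ = 4,
DpnII ^GATC = 0 (overridable in config). Chromosome ends close the terminal
fragments. Fragments whose span intersects the region window are flagged
in-region — boundary fragments clipped by the window are counted, and the
choice is recorded in output metadata.

Second-enzyme subfragments tile each parent fragment; the first and last
pieces are END (they abut a first-enzyme cut, or a chromosome end), pieces
bounded by two second-enzyme cuts are INTERNAL. Only END pieces carry
ligation-junction information, so reads wholly inside an INTERNAL
subfragment are removed.

## Probe design

For each in-region fragment end the candidate window starts at the
first-enzyme cut and extends inward, bounded by the nearest second-enzyme
site (the END subfragment). With ≥62 bp available, the length in 62–90 bp
whose nearest-neighbor Tm is closest to the target is chosen (ties to the
shorter length); with less, the probe is trimmed to the available length
down to `min_probe_len` (default 30 bp), below which the end is
uncapturable. Right-hand ends are designed on the reverse complement so
"close to the cut" is symmetric; output coordinates are always
forward-strand. Uniqueness requires every `seed_len`-mer of the probe
(default: the full probe) to occur exactly once in the genome counting both
strands; a non-unique candidate may slide inward up to `slide_max` bp
(default 10) before the end is declared uncapturable. Candidates whose Tm
deviates from the target by more than `tm_window` (default 5 °C) are
rejected, which bounds the Tm spread of a design by `2 × tm_window`.

Tm uses the unified nearest-neighbor thermodynamic parameters (via
Biopython's `Tm_NN`) at fixed hybridization conditions: 50 mM monovalent
salt, 250 nM per strand, entropy salt correction. The Tm target defaults to
the median Tm of the leftmost full-length (62-mer) candidates over all
admissible ends, so a design self-centres; there is no universal target
temperature for capture arrays. `replicate_probes` is integer division of
array capacity by probe count (800 probes on a 2.1 M-feature array →
2,625 spots each).

## Read-pair filtering

Reads are trimmed at the first occurrence of the recognition site (ligation
restores the full site at the junction, so sequence past its 3′ end belongs
to the partner fragment), then quality-trimmed: maximal runs of bases with
phred < 10 are stripped from both ends and reads retaining < 12 bases are
discarded. Fragment assignment uses the full aligned span: spans touching
more than one fragment are MULTI_FRAGMENT, spans wholly inside an INTERNAL
subfragment are INTERNAL_SUBFRAGMENT.

Pair classification applies a fixed precedence: UNMAPPED > NON_UNIQUE
(either mapq < 20) > MULTI_FRAGMENT > INTERNAL_SUBFRAGMENT > IDENTICAL_ENDS
(both mates at one position/strand) > SELF_LIGATION (one fragment) >
NON_DIGESTION > VALID. "Uniquely mapped" is operationalized as a mapq
threshold because aligners encode multi-mapping there. A NON_DIGESTION call
requires adjacent fragments with the two inner read ends within
`junction_tol` (default 5 bp) of the shared cut in convergent orientation;
plain adjacent pairs stay VALID, since neighbouring fragments genuinely
interact in 3C data and only the convergent-at-the-cut geometry indicates
an uncut or re-ligated site. Exact-coordinate duplicates of an
already-seen pair (same spans and strands on both mates) are flagged
IDENTICAL_ENDS, so that class doubles as duplicate removal; the first
occurrence keeps its own class and tallies always partition the input.
Duplicates are removed before any capture-region restriction; both
orderings give the same in-region counts because the signature is
coordinate-based.

## Contact matrices and normalization

A matrix entry is a canonically ordered fragment pair `(i < j)` with its
valid-pair count; self entries are excluded (they are SELF_LIGATION
upstream), trans entries are stored but excluded from in-region summaries
and distance statistics. Capture normalization divides `n_ij` by
`S_i + S_j`; marginals exclude self-ligation/uncut counts by default, with
an opt-in to include them for capture-efficiency correction analyses. The
binned variant divides bin counts by bin marginal sums analogously (bin
marginals, not aggregated fragment marginals — the natural reading once
reads are re-binned). Bin origin is coordinate 0 of each chromosome, as in
genome-wide binning tools, not the region start. Mean reads per
interaction is rounded half-up (557,763/4,057 → 137; 1,929,245/8,989 →
215, which truncation would miss). Spearman comparison of two binned maps
uses the union of occupied bin pairs with absent entries as 0 and returns
exactly 1.0 for identical inputs (the floating rank-correlation of a
vector with itself is otherwise 1 − ε).

The Mann–Whitney U statistic is computed with midrank ties; the two-sided
p-value is by exhaustive enumeration of group assignments when
`C(n+m, n) ≤ 2×10⁵` (valid under ties) and by the tie-corrected normal
approximation otherwise — exact enumeration beyond that is combinatorially
infeasible.

## The simulator: what it emulates, and what it does not

`simulate_genome` builds random chromosomes (GC 0.45) and implants
first-enzyme sites at ~Exponential(3 kb) spacings and second-enzyme sites
at ~Exponential(450 bp), matching the near-exponential fragment-length
distribution of a 6-/4-cutter digest. Accidental occurrences of either
site are scrubbed from the random background first, so the implant log is
exactly the digest result — this makes cut-recovery tests exact and the
constructive trimming oracle sound. An optional duplicated segment
exercises the probe-uniqueness screen.

Contacts are drawn from `P(i,j) ∝ (1+d)^(−α)` with α = 1 by default, block
multipliers for planted domains, and pair multipliers for planted loops.
Default planted loops span ~30–60 kb (10–20 fragments) — the
enhancer–promoter scale of the assay's positive-control loci (LCR–promoter
contacts). At the default 50× multiplier a loop at that span outweighs
every adjacent-fragment background pair, so loops are recoverable in the
top percentile of normalized entries; loops planted at several hundred kb
would have weights comparable to the adjacent-pair background and would
not separate at realistic depths.

Read emission constructs junction reads outward from the ligated
first-enzyme cut: the mate's informative part is the fragment-end segment
plus the restored recognition site, followed by random site-free filler,
so restriction-site trimming reproduces the fragment-end prefix exactly
(the recorded per-read expectation). The aligned span covers only the
fragment-end segment, not the few restored-site bases that cross the cut —
a deliberate simplification that keeps full-span fragment assignment
unambiguous. The outer read end varies randomly (12 bp up to the read
length, 101 bp as in a 101-cycle paired-end protocol), which is what makes
exact-coordinate duplicates rare; a small residue of accidental coordinate
collisions (≲1% at 10⁵ pairs on a 110-fragment map) is counted as
IDENTICAL_ENDS, exactly as a real pipeline would count them.
Contamination classes are drawn by one categorical draw per pair (mutually
exclusive, matching the classifier): self-ligations read outward from both
cuts of one fragment; non-digestion pairs sit convergently at a shared
cut; duplicates copy a previously emitted valid pair; internal reads fall
wholly inside an INTERNAL subfragment; multi-mappers get mapq 0. Base
qualities decay linearly from phred 35 with noise and an occasional
low-quality 3′ tail, so quality trimming has realistic work.

Not emulated: polymer-physics contact models, sequencing substitution
errors, PCR amplification bias, hybridization thermodynamics of capture,
and mappability structure beyond the planted duplication. Passing tests
therefore demonstrate the correctness of the bookkeeping and the
recoverability of planted structure under the stated noise model — not
robustness to every artefact of a real library.

## Decay-exponent estimation

Cis entries are pooled into log-spaced distance bins; since each pair is
drawn independently with probability ∝ `(1+d)^(−α)`, the mean observed
count per *possible* fragment pair in a bin is proportional to
`(1+d̄)^(−α)`, and the slope of `log(mean count)` against `log(1+d)` over
populated bins (≥20 possible pairs, ≥10 reads) estimates −α by ordinary
least squares. Planted loop and in-domain pairs are excluded from both
numerator and denominator via a mask, keeping the power-law fit clean.

## Problem sizes

The test suite and the acceptance script use a 300 kb single-chromosome
genome (~110 fragments, ~3 kb median resolution) with 10⁴ pairs for
classifier-recovery checks and 10⁵ pairs for end-to-end structure
recovery; these sizes give binomial standard errors small enough for 3σ
recovery bounds and sub-percent loop ranking while a full run stays under
a minute per simulation.

## Known limitations

* Probe uniqueness is exact-match k-mer uniqueness, not mappability or
  alignment-based (no mismatch tolerance); repeat families subtler than
  exact duplication are not modeled.
* The NON_DIGESTION test requires convergent orientation; a re-ligation
  read pair mapped with unusual orientation (e.g. after structural
  variation) would be kept as VALID.
* Binned normalization uses bin marginals; aggregating fragment-level
  marginals into bins is a defensible alternative and would differ for
  fragments straddling bin boundaries.
* The exact Mann–Whitney path enumerates combinations and is only engaged
  for small samples; p-values for large tied samples rely on the normal
  approximation.
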