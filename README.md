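# t2c — Targeted Chromatin Capture analysis

Targeted Chromatin Capture (T2C) is a chromosome-conformation-capture (3C)
derivative: a crosslinked genome is digested with a 6-cutter (HindIII or
BglII), ligated in dilute conditions so that spatially proximal restriction
fragments join, shortened with a frequent 4-cutter (NlaIII or DpnII), and
hybridized to capture oligonucleotides tiling the fragment ends of a region
of interest. Paired-end sequencing of the captured library yields a
many-to-all chromatin interaction map at **single restriction-fragment
resolution** (median 2–4 kb) for a multi-megabase locus, at a fraction of
the sequencing effort of genome-wide Hi-C.

This package implements the computational side of the assay for researchers
analysing such libraries (or designing capture experiments):

* **digestion** — in-silico single/double digest; the `FragmentMap` /
  `SubfragmentMap` coordinate system (fragment *ends* abut a first-enzyme
  cut and carry ligation-junction information; *internal* second-enzyme
  subfragments are uninformative).
* **probes** — capture-oligo design at fragment ends: 62–90 nt, as close as
  possible to the cut, not crossing the second-enzyme site (trimmed when
  the end is short), unique in the genome, melting temperatures clustered
  around a common target (nearest-neighbor model).
* **readproc** — restriction-site trimming, quality trimming, span-based
  fragment assignment and the pair-filter cascade (self-ligation,
  non-digestion/re-ligation, identical ends/duplicates, internal
  subfragments, multi-fragment spans, non-unique mappings).
* **contacts** — sparse fragment×fragment contact matrices, 40 kb binning,
  capture-efficiency normalization, per-library accounting, Spearman
  comparison of binned maps.
* **factors** — ChIP-seq peak intersection, factor-filtered interaction
  maps, interaction-count and cis-distance statistics with the
  Mann–Whitney U test.
* **simulate** — synthetic genomes, ground-truth contact models and
  contaminated read pairs, so every stage is testable without external data.

## The statistics at the core

With `n_ij` valid read pairs joining fragments *i* and *j*, an
**interaction** is any unordered pair with `n_ij ≥ 1`. The per-fragment
marginal is `S_i = Σ_j n_ij` (optionally plus self-ligation/uncut reads),
and the capture-normalized score of an interaction is

```
score(i, j) = n_ij / (S_i + S_j)    ∈ (0, 0.5]
```

which corrects for per-fragment capture bias; the bound 0.5 is attained
only when two fragments interact exclusively with each other. Library
accounting reports `round(pairs / interactions)` reads per interaction.
Binned maps assign each read end to `floor(pos / bin_size)` on a fixed
40 kb tiling and are compared by Spearman's rank correlation over the
union of occupied bin pairs.

The simulator draws fragment pairs with probability
`P(i,j) ∝ (1 + d_ij)^(−α) × block × loop` (`d_ij` = midpoint distance),
plants domain blocks and loops, and contaminates reads at stated rates;
`estimate_decay_exponent` recovers α from an observed matrix.

## Worked example

`python examples/03_contact_map.py` simulates a 300 kb locus (~110 HindIII
fragments), plants a 3× domain block and two 50× loops at
enhancer–promoter span, pushes 50,000 contaminated read pairs through the
filter cascade and prints:

```
interactions: 4259  reads: 37143
max normalized score: 0.2785 (bound 0.5)
planted loop (10,25): top 0.77% of normalized entries
planted loop (60,75): top 0.28% of normalized entries
read counts of the top 20% of interactions: 875 down to 7
recovered decay exponent: 1.00 (true 1.0)
40 kb binned map, self Spearman rho = 1.0
```

37,143 of 50,000 pairs survive filtering and form 4,259 distinct
interactions; both planted loops rank inside the top 1% of normalized
entries, and the distance-decay exponent used to generate the data is
recovered exactly. The other examples cover probe design
(`01_digest_and_design.py`), classifier recovery (`02_classify_pairs.py`)
and ChIP-seq intersection with condition comparison
(`04_factor_intersection.py`).

A `t2c` console command exposes the same stages as subcommands
(`digest`, `design`, `classify`, `compare`, `intersect`, `plot`, `run`);
`t2c run --config config.yaml` executes the whole pipeline and writes a
manifest with per-stage checksums and the library summary.

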