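"""Contact matrices at restriction-fragment and binned resolution.

An *interaction* is a distinct unordered fragment pair supported by at least
one valid read pair; the matrix stores read counts per interaction.  The
capture-efficiency normalization divides each interaction's count by the sum
of the total read counts (marginals) of its two fragments, which bounds every
score by 0.5.  Binned matrices re-aggregate read ends on a fixed genome
tiling (40 kb by default) for comparison with external maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .digestion import FragmentMap, median_resolution

__all__ = [
    "ContactMatrix",
    "BinnedMatrix",
    "NormalizedMatrix",
    "SummaryTable",
    "build_contact_matrix",
    "fragment_marginals",
    "normalize_capture",
    "capture_efficiency",
    "bin_matrix",
    "compare_binned_maps",
    "summarize",
    "interaction_read_quantiles",
    "render_map",
]

IN_REGION = "IN_REGION"
REGION_VS_GENOME = "REGION_VS_GENOME"
GENOME = "GENOME"


class ContactMatrix:
    """Sparse symmetric fragment x fragment read-pair counts (i < j)."""

    def __init__(self, entries: Mapping[tuple[int, int], int], fragmap: FragmentMap, scope: str = GENOME):
        self.entries: dict[tuple[int, int], int] = dict(entries)
        self.fragmap = fragmap
        self.scope = scope
        for (i, j), n in self.entries.items():
            if i >= j:
                raise ValueError(f"entry ({i},{j}) not canonically ordered i<j")
            if n < 1:
                raise ValueError(f"entry ({i},{j}) has count {n} < 1")

    def get(self, i: int, j: int) -> int:
        if i == j:
            return 0
        key = (i, j) if i < j else (j, i)
        return self.entries.get(key, 0)

    @property
    def n_interactions(self) -> int:
        return len(self.entries)

    @property
    def total_pairs(self) -> int:
        return sum(self.entries.values())

    def cis_entries(self) -> dict[tuple[int, int], int]:
        out = {}
        for (i, j), n in self.entries.items():
            if self.fragmap[i].chrom == self.fragmap[j].chrom:
                out[(i, j)] = n
        return out

    def to_tsv(self, path, normalized: Optional["NormalizedMatrix"] = None) -> None:
        with open(path, "w") as fh:
            header = "frag_i\tfrag_j\tcount" + ("\tnormalized" if normalized else "")
            fh.write(header + "\n")
            for (i, j), n in sorted(self.entries.items()):
                line = f"{i}\t{j}\t{n}"
                if normalized:
                    line += f"\t{normalized.entries[(i, j)]:.6g}"
                fh.write(line + "\n")

    @classmethod
    def from_tsv(cls, path, fragmap: FragmentMap, scope: str = GENOME) -> "ContactMatrix":
        entries = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                p = line.split("\t")
                entries[(int(p[0]), int(p[1]))] = int(p[2])
        return cls(entries, fragmap, scope)


@dataclass
class NormalizedMatrix:
    """Capture-normalized scores n_ij / (S_i + S_j), each in (0, 0.5]."""

    entries: dict[tuple[int, int], float]

    def get(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        return self.entries.get(key, 0.0)


BinKey = tuple[str, int]  # (chrom, bin index)


class BinnedMatrix:
    """Sparse symmetric binned contact counts on a fixed genome tiling."""

    def __init__(self, entries: Mapping[tuple[BinKey, BinKey], int], bin_size: int):
        self.entries: dict[tuple[BinKey, BinKey], int] = dict(entries)
        self.bin_size = bin_size

    def get(self, a: BinKey, b: BinKey) -> int:
        key = (a, b) if a <= b else (b, a)
        return self.entries.get(key, 0)

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def marginals(self) -> dict[BinKey, int]:
        marg: dict[BinKey, int] = {}
        for (a, b), n in self.entries.items():
            marg[a] = marg.get(a, 0) + n
            if b != a:
                marg[b] = marg.get(b, 0) + n
        return marg

    def normalize(self) -> dict[tuple[BinKey, BinKey], float]:
        """Capture normalization at bin resolution: n_ab / (S_a + S_b)."""
        marg = self.marginals()
        return {
            (a, b): n / (marg[a] + marg[b]) for (a, b), n in self.entries.items()
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom1\tbin_start1\tchrom2\tbin_start2\tcount\n")
            for ((c1, b1), (c2, b2)), n in sorted(self.entries.items()):
                fh.write(f"{c1}\t{b1 * self.bin_size}\t{c2}\t{b2 * self.bin_size}\t{n}\n")

    @classmethod
    def from_tsv(cls, path, bin_size: int) -> "BinnedMatrix":
        entries: dict[tuple[BinKey, BinKey], int] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                c1, s1, c2, s2, n = line.rstrip("\n").split("\t")
                a, b = (c1, int(s1) // bin_size), (c2, int(s2) // bin_size)
                key = (a, b) if a <= b else (b, a)
                entries[key] = entries.get(key, 0) + int(n)
        return cls(entries, bin_size)


def _pair_scope_ok(fragmap: FragmentMap, i: int, j: int, scope: str) -> bool:
    ri, rj = fragmap[i].in_region, fragmap[j].in_region
    if scope == IN_REGION:
        return ri and rj
    if scope == REGION_VS_GENOME:
        return ri or rj
    return True


def build_contact_matrix(valid_pairs, fragmap: FragmentMap, scope: str = GENOME) -> ContactMatrix:
    """Aggregate canonical VALID pairs into fragment-pair read counts.

    ``valid_pairs`` may be PairRecords (with integer frag1/frag2) or plain
    (i, j) tuples.  Self pairs (i == j) never occur in valid input and are
    rejected; trans entries are retained when the scope permits.
    """
    entries: dict[tuple[int, int], int] = {}
    n_frag = len(fragmap)
    for rec in valid_pairs:
        i, j = (rec.frag1, rec.frag2) if hasattr(rec, "frag1") else rec
        if not (isinstance(i, int) and isinstance(j, int)):
            raise ValueError(f"pair with non-fragment assignment ({i}, {j})")
        if not (0 <= i < n_frag and 0 <= j < n_frag):
            raise ValueError(f"pair references unknown fragment ({i}, {j})")
        if i == j:
            raise ValueError("self pair in valid input (should be SELF_LIGATION)")
        if i > j:
            i, j = j, i
        if _pair_scope_ok(fragmap, i, j, scope):
            entries[(i, j)] = entries.get((i, j), 0) + 1
    return ContactMatrix(entries, fragmap, scope)


def fragment_marginals(
    matrix: ContactMatrix,
    self_uncut_counts: Mapping[int, int] | None = None,
) -> dict[int, int]:
    """Per-fragment total read counts S_i = sum_j n_ij.

    When per-fragment self-ligation/non-digestion tallies are supplied they
    are added, matching the capture-efficiency accounting that counts *all*
    reads of a fragment: its interactions, its self-ligation and its
    non-cleaved material.
    """
    marg: dict[int, int] = {}
    for (i, j), n in matrix.entries.items():
        marg[i] = marg.get(i, 0) + n
        marg[j] = marg.get(j, 0) + n
    if self_uncut_counts:
        for i, n in self_uncut_counts.items():
            marg[i] = marg.get(i, 0) + n
    return marg


def normalize_capture(
    matrix: ContactMatrix,
    self_uncut_counts: Mapping[int, int] | None = None,
) -> NormalizedMatrix:
    """Divide each interaction count by the sum of its fragments' marginals."""
    marg = fragment_marginals(matrix, self_uncut_counts)
    out = {}
    for (i, j), n in matrix.entries.items():
        denom = marg[i] + marg[j]
        assert denom > 0, "zero marginal for a stored entry"
        out[(i, j)] = n / denom
    return NormalizedMatrix(out)


def capture_efficiency(pairs, probe_fragment_ids: set[int], fragmap: FragmentMap) -> float:
    """Fraction of mapped pairs with >=1 end on a probe-represented fragment.

    ``pairs`` are mapped pairs as PairRecords or (i, j) fragment tuples; ends
    without a fragment assignment count as off-probe.
    """
    total = hits = 0
    for rec in pairs:
        i, j = (rec.frag1, rec.frag2) if hasattr(rec, "frag1") else rec
        total += 1
        if (isinstance(i, int) and i in probe_fragment_ids) or (
            isinstance(j, int) and j in probe_fragment_ids
        ):
            hits += 1
    if total == 0:
        raise ValueError("zero mapped pairs")
    return hits / total


def bin_matrix(valid_pairs, bin_size: int = 40_000) -> BinnedMatrix:
    """Bin read ends on a fixed tiling, bin = floor(pos / bin_size).

    Bin origin is coordinate 0 of each chromosome.  The total binned count
    equals the number of retained pairs.  Accepts PairRecords (binned by the
    5' aligned position of each end) or ((chrom, pos), (chrom, pos)) tuples.
    """
    entries: dict[tuple[BinKey, BinKey], int] = {}
    for rec in valid_pairs:
        if hasattr(rec, "end1"):
            locs = ((rec.end1.chrom, rec.end1.pos), (rec.end2.chrom, rec.end2.pos))
        else:
            locs = rec
        a = (locs[0][0], locs[0][1] // bin_size)
        b = (locs[1][0], locs[1][1] // bin_size)
        key = (a, b) if a <= b else (b, a)
        entries[key] = entries.get(key, 0) + 1
    return BinnedMatrix(entries, bin_size)


def compare_binned_maps(
    a: BinnedMatrix,
    b: BinnedMatrix,
    region: Optional[tuple[str, int, int]] = None,
) -> tuple[float, float]:
    """Spearman rank correlation between two binned maps.

    The union of occupied bin pairs is compared, absent entries as 0;
    ``region`` (chrom, start, end in bp) restricts both maps to bin pairs
    whose bins both lie in the window.  Returns (rho, two-sided p).
    """
    if a.bin_size != b.bin_size:
        raise ValueError("bin sizes differ")

    def keep(key) -> bool:
        if region is None:
            return True
        chrom, start, end = region
        lo, hi = start // a.bin_size, (end - 1) // a.bin_size
        return all(c == chrom and lo <= idx <= hi for c, idx in key)

    keys = sorted({k for k in a.entries if keep(k)} | {k for k in b.entries if keep(k)})
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} shared bin pairs; need >=3")
    va = [a.entries.get(k, 0) for k in keys]
    vb = [b.entries.get(k, 0) for k in keys]
    rho, p = stats.spearmanr(va, vb)
    if va == vb:
        rho = 1.0  # self-comparison is exact, not subject to rounding
    return float(rho), float(p)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SummaryTable:
    """Per-experiment accounting in the style of a library summary table."""

    raw_pairs: int
    mapped_pairs: int
    region_vs_genome_pairs: int
    unique_filtered_pairs: int
    unique_filtered_region_vs_genome: int
    in_region_pairs: int
    interactions_in_region: int
    mean_reads_per_interaction: int
    median_resolution_kbp: float

    def __post_init__(self):
        cascade = [
            self.raw_pairs,
            self.mapped_pairs,
            self.region_vs_genome_pairs,
        ]
        if any(a < b for a, b in zip(cascade, cascade[1:])):
            raise ValueError("filter cascade counts must be non-increasing")
        if self.unique_filtered_pairs > self.mapped_pairs:
            raise ValueError("filtered pairs exceed mapped pairs")
        if not (
            self.in_region_pairs
            <= self.unique_filtered_region_vs_genome
            <= self.unique_filtered_pairs
        ):
            raise ValueError("region counts must nest within genome-wide counts")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, value in self.__dict__.items():
                fh.write(f"{name}\t{value}\n")


def mean_reads_per_interaction(pairs: int, interactions: int) -> int:
    """Average reads per interaction, rounded half-up to an integer."""
    if interactions <= 0:
        raise ValueError("zero interactions")
    return _round_half_up(pairs / interactions)


def summarize(
    tallies: Mapping,
    matrix: ContactMatrix,
    fragmap: FragmentMap,
    raw_pairs: int,
    mapped_pairs: int,
    region_vs_genome_pairs: int,
    unique_filtered_pairs: int,
    unique_filtered_region_vs_genome: int,
) -> SummaryTable:
    """Assemble the experiment summary from tallies and the in-region matrix.

    The in-region matrix must be built with scope IN_REGION; cis entries only
    enter the interaction count (trans contacts are kept in the matrix store
    but excluded from in-region summaries).
    """
    cis = matrix.cis_entries()
    in_region_pairs = sum(cis.values())
    n_inter = len(cis)
    return SummaryTable(
        raw_pairs=raw_pairs,
        mapped_pairs=mapped_pairs,
        region_vs_genome_pairs=region_vs_genome_pairs,
        unique_filtered_pairs=unique_filtered_pairs,
        unique_filtered_region_vs_genome=unique_filtered_region_vs_genome,
        in_region_pairs=in_region_pairs,
        interactions_in_region=n_inter,
        mean_reads_per_interaction=mean_reads_per_interaction(in_region_pairs, n_inter),
        median_resolution_kbp=round(median_resolution(fragmap) / 1000, 1),
    )


def interaction_read_quantiles(matrix: ContactMatrix, top_fraction: float) -> tuple[int, int]:
    """Extreme read counts of the top ``top_fraction`` of interactions.

    Interactions are ranked by read count descending; returns (highest,
    lowest) count inside the band.  ``top_fraction`` in (0, 1].
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("fraction outside (0, 1]")
    counts = sorted(matrix.entries.values(), reverse=True)
    if not counts:
        raise ValueError("empty matrix")
    k = max(1, int(math.floor(top_fraction * len(counts) + 1e-9)))
    return counts[0], counts[k - 1]


def render_map(
    matrix,
    fragmap: FragmentMap | None = None,
    tracks: Sequence[tuple[str, Sequence[tuple[int, int]]]] = (),
    path=None,
    log_scale: bool = True,
    vmin: float | None = None,
    vmax: float | None = None,
    title: str = "",
):
    """Render a square heatmap of an in-region contact matrix.

    ``tracks`` are (label, list of (start, end) bp intervals) drawn beneath
    the map (probe positions, restriction sites, ChIP-seq peaks).  Pass
    ``vmin``/``vmax`` to share one color normalization across maps.  Returns
    the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    entries = matrix.entries
    if not entries:
        raise ValueError("matrix non-empty required for rendering")
    ids = sorted({i for k in entries for i in k})
    pos = {f: n for n, f in enumerate(ids)}
    dense = np.zeros((len(ids), len(ids)))
    for (i, j), n in entries.items():
        dense[pos[i], pos[j]] = dense[pos[j], pos[i]] = n

    n_tracks = len(tracks)
    fig, axes = plt.subplots(
        1 + n_tracks, 1, figsize=(7, 7 + 0.4 * n_tracks),
        gridspec_kw={"height_ratios": [14] + [1] * n_tracks},
        squeeze=False,
    )
    ax = axes[0][0]
    norm = None
    if log_scale:
        positive = dense[dense > 0]
        norm = LogNorm(vmin=vmin or positive.min(), vmax=vmax or positive.max())
    im = ax.imshow(
        np.where(dense > 0, dense, np.nan),
        cmap="jet", norm=norm, vmin=None if norm else vmin, vmax=None if norm else vmax,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, shrink=0.7)
    ax.set_title(title)
    for k, (label, intervals) in enumerate(tracks):
        tax = axes[1 + k][0]
        for s, e in intervals:
            tax.axvspan(s, e, color="black")
        tax.set_yticks([])
        tax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
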