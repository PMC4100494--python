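"""ChIP-seq peak intersection with interaction maps and factor statistics.

Fragments carrying a binding-site peak of a chromatin protein (e.g. Ldb1,
Ctcf) are flagged; interaction matrices can be filtered to entries where one
(ANY) or both (BOTH) fragments are bound; per-bound-fragment partner counts
and cis interaction-distance statistics are compared between conditions with
the Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from statistics import mean, median
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _st

from .contacts import ContactMatrix
from .digestion import FragmentMap

__all__ = [
    "Peak",
    "PeakSet",
    "FactorAnnotation",
    "read_peaks",
    "annotate_fragments",
    "filter_interactions_by_factor",
    "interaction_count_per_bound_fragment",
    "interaction_distance_stats",
    "mann_whitney_u",
    "ANY",
    "BOTH",
]

ANY = "ANY"
BOTH = "BOTH"


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based half-open
    end: int
    height: float = 0.0


@dataclass
class PeakSet:
    factor: str
    peaks: list[Peak]

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self):
        return len(self.peaks)


def read_peaks(path, factor: str, height_col: int = 4) -> PeakSet:
    """Read peaks from BED/narrowPeak; ``height_col`` is the 0-based column
    holding peak height (4 = BED score, 6 = narrowPeak signalValue)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            height = float(p[height_col]) if len(p) > height_col else 0.0
            peaks.append(Peak(p[0], int(p[1]), int(p[2]), height))
    return PeakSet(factor, peaks)


@dataclass
class FactorAnnotation:
    factor: str
    bound_fragments: set[int]

    def is_bound(self, fragment_id: int) -> bool:
        return fragment_id in self.bound_fragments

    def to_tsv(self, path, fragmap: FragmentMap) -> None:
        with open(path, "w") as fh:
            fh.write("fragment_id\tfactor\tbound\n")
            for frag in fragmap:
                fh.write(f"{frag.id}\t{self.factor}\t{int(frag.id in self.bound_fragments)}\n")


def annotate_fragments(
    fragmap: FragmentMap,
    peaks: PeakSet,
    min_height: float = 20.0,
) -> FactorAnnotation:
    """Flag fragments overlapped (>=1 bp, half-open) by a peak of sufficient
    height.  Peaks on chromosomes absent from the fragment map are an error
    (genome-build mismatch)."""
    bound: set[int] = set()
    for peak in peaks:
        if peak.chrom not in fragmap.chroms:
            raise KeyError(
                f"peak chromosome {peak.chrom!r} not in fragment map "
                f"(chroms {fragmap.chroms}); genome builds must match"
            )
        if peak.height < min_height or peak.end <= peak.start:
            continue
        for frag in fragmap.overlapping(peak.chrom, peak.start, peak.end):
            bound.add(frag.id)
    return FactorAnnotation(peaks.factor, bound)


def filter_interactions_by_factor(
    matrix: ContactMatrix,
    annotation: FactorAnnotation,
    mode: str = ANY,
) -> ContactMatrix:
    """Keep entries where one (ANY) or both (BOTH) fragments are bound."""
    if mode not in (ANY, BOTH):
        raise ValueError(f"mode must be ANY or BOTH, got {mode!r}")
    bound = annotation.bound_fragments
    if mode == ANY:
        entries = {k: n for k, n in matrix.entries.items() if k[0] in bound or k[1] in bound}
    else:
        entries = {k: n for k, n in matrix.entries.items() if k[0] in bound and k[1] in bound}
    return ContactMatrix(entries, matrix.fragmap, matrix.scope)


def interaction_count_per_bound_fragment(
    subset: ContactMatrix,
    annotation: FactorAnnotation,
) -> dict[int, int]:
    """Distinct interaction partners per bound fragment (unbound excluded)."""
    partners: dict[int, set[int]] = {}
    for i, j in subset.entries:
        if annotation.is_bound(i):
            partners.setdefault(i, set()).add(j)
        if annotation.is_bound(j):
            partners.setdefault(j, set()).add(i)
    return {f: len(p) for f, p in partners.items()}


def interaction_distance_stats(subset: ContactMatrix) -> tuple[float, float]:
    """Mean and median linear distance (bp) between cis interaction partners.

    Distance is taken between fragment midpoints; trans entries are excluded.
    """
    fragmap = subset.fragmap
    dists = [
        abs(fragmap[i].midpoint - fragmap[j].midpoint)
        for i, j in subset.cis_entries()
    ]
    if not dists:
        raise ValueError("no cis entries")
    return float(mean(dists)), float(median(dists))


def _u_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """Mann-Whitney U for sample a, midrank ties."""
    ranks = _st.rankdata(list(a) + list(b))
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


_MAX_EXACT = 200_000  # enumeration budget: C(n+m, n) combinations


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    max_exact: int = _MAX_EXACT,
) -> tuple[float, float]:
    """Mann-Whitney U (for sample_a) and two-sided p-value.

    Small problems (C(n+m,n) <= ``max_exact``) are solved by exhaustive
    enumeration of group assignments, valid under ties; larger ones use the
    normal approximation with tie correction.  U_a + U_b = n*m always holds.
    """
    a, b = list(map(float, sample_a)), list(map(float, sample_b))
    if not a or not b:
        raise ValueError("empty sample")
    n, m = len(a), len(b)
    u = _u_statistic(a, b)

    if math.comb(n + m, n) <= max_exact:
        pooled = a + b
        center = n * m / 2
        obs_dev = abs(u - center)
        hits = total = 0
        for idx in combinations(range(n + m), n):
            chosen = set(idx)
            ua = _u_statistic(
                [pooled[i] for i in idx],
                [pooled[i] for i in range(n + m) if i not in chosen],
            )
            total += 1
            if abs(ua - center) >= obs_dev - 1e-9:
                hits += 1
        return u, hits / total

    _, p = _st.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(p)
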