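"""In-silico restriction digestion and the fragment coordinate system.

A Targeted Chromatin Capture experiment is anchored on a double digest: a
6-cutter (e.g. HindIII, BglII) defines the interaction fragments, and a
frequent 4-cutter (e.g. NlaIII, DpnII) shortens ligation products so that only
fragment *ends* carry junction information.  This module models reference
sequences and enzymes, performs single and double digestion, and exposes the
resulting :class:`FragmentMap` / :class:`SubfragmentMap` that every downstream
stage (probe design, read classification, contact matrices) uses as its
coordinate system.

Coordinates are 0-based half-open (BED convention) throughout the API;
rendering helpers print 1-based inclusive strings for reports.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ReferenceGenome",
    "RestrictionEnzyme",
    "Fragment",
    "FragmentMap",
    "Subfragment",
    "SubfragmentMap",
    "KNOWN_ENZYMES",
    "get_enzyme",
    "find_sites",
    "digest",
    "double_digest",
    "median_resolution",
    "parse_region",
    "format_region",
    "region_size_mb",
    "revcomp",
]

_GENOME_ALPHABET = set("ACGTN")
_SITE_ALPHABET = set("ACGT")

END = "END"
INTERNAL = "INTERNAL"


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as name, recognition site and cut offset.

    ``cut_offset`` is the distance in bp from the 5' start of the recognition
    site to the cut position on the top strand (HindIII A^AGCTT has offset 1).
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if not site or not set(site) <= _SITE_ALPHABET:
            raise ValueError(
                f"recognition site {self.site!r} must be non-empty A/C/G/T "
                "(IUPAC ambiguity codes and N are unsupported)"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(site)}]"
            )
        if not self.is_palindromic:
            warnings.warn(
                f"recognition site of {self.name} is not palindromic; "
                "cut positions are computed on the top strand only",
                stacklevel=2,
            )

    @property
    def is_palindromic(self) -> bool:
        return self.site == revcomp(self.site)


#: Enzymes used by the assay, with top-strand cut offsets.
KNOWN_ENZYMES: dict[str, tuple[str, int]] = {
    "HindIII": ("AAGCTT", 1),  # A^AGCTT
    "BglII": ("AGATCT", 1),    # A^GATCT
    "NlaIII": ("CATG", 4),     # CATG^
    "DpnII": ("GATC", 0),      # ^GATC
}


def get_enzyme(name: str, site: str | None = None, cut_offset: int | None = None) -> RestrictionEnzyme:
    """Look up a built-in enzyme by name, or build one from explicit fields."""
    if site is not None:
        if cut_offset is None:
            raise ValueError("cut_offset required when site is given")
        return RestrictionEnzyme(name, site, cut_offset)
    try:
        s, off = KNOWN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; known: {sorted(KNOWN_ENZYMES)}"
        ) from None
    return RestrictionEnzyme(name, s, off)


class ReferenceGenome:
    """Uppercase DNA sequences keyed by name, with length bookkeeping."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("empty genome")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            if not set(seq) <= _GENOME_ALPHABET:
                bad = sorted(set(seq) - _GENOME_ALPHABET)
                raise ValueError(f"sequence {name!r} contains non-ACGTN characters {bad}")
            self.sequences[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class Fragment:
    """One first-enzyme restriction fragment (0-based half-open)."""

    id: int
    chrom: str
    start: int
    end: int
    in_region: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def parse_region(region: str | tuple) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive, as printed in reports)
    into a 0-based half-open (chrom, start, end) tuple.

    Tuples are passed through unchanged (assumed already half-open).
    """
    if isinstance(region, tuple):
        chrom, start, end = region
        return str(chrom), int(start), int(end)
    chrom, _, span = region.replace(",", "").replace(" ", "").partition(":")
    if not span or "-" not in span:
        raise ValueError(f"cannot parse region {region!r}; expected chrom:start-end")
    lo, _, hi = span.partition("-")
    start1, end1 = int(lo), int(hi)
    if start1 < 1 or end1 < start1:
        raise ValueError(f"bad region bounds in {region!r}")
    return chrom, start1 - 1, end1


def format_region(chrom: str, start: int, end: int) -> str:
    """Render a half-open interval as the 1-based inclusive display string."""
    return f"{chrom}:{start + 1}-{end}"


def region_size_mb(region: str | tuple, decimals: int = 1) -> float:
    """Size of a region in Mb, rounded to ``decimals`` (report convention)."""
    _, start, end = parse_region(region)
    return round((end - start) / 1e6, decimals)


class FragmentMap:
    """Ordered first-enzyme fragments tiling each reference sequence."""

    def __init__(
        self,
        fragments: Sequence[Fragment],
        enzyme: RestrictionEnzyme,
        region_of_interest: Sequence[tuple[str, int, int]] = (),
    ):
        self.fragments = list(fragments)
        self.enzyme = enzyme
        self.region_of_interest = [tuple(r) for r in region_of_interest]
        self._index: dict[str, tuple[list[int], list[Fragment]]] = {}
        for frag in self.fragments:
            starts, frags = self._index.setdefault(frag.chrom, ([], []))
            starts.append(frag.start)
            frags.append(frag)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __getitem__(self, frag_id: int) -> Fragment:
        return self.fragments[frag_id]

    @property
    def chroms(self) -> list[str]:
        return list(self._index)

    def fragment_at(self, chrom: str, pos: int) -> Fragment:
        """The unique fragment containing genomic position ``pos``."""
        try:
            starts, frags = self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None
        i = bisect_right(starts, pos) - 1
        if i < 0 or not frags[i].start <= pos < frags[i].end:
            raise ValueError(f"position {chrom}:{pos} outside the genome tiling")
        return frags[i]

    def overlapping(self, chrom: str, start: int, end: int) -> list[Fragment]:
        """All fragments intersecting half-open [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        starts, frags = self._index.get(chrom, ([], []))
        i = max(bisect_right(starts, start) - 1, 0)
        out = []
        while i < len(frags) and frags[i].start < end:
            if frags[i].end > start:
                out.append(frags[i])
            i += 1
        return out

    @property
    def in_region_fragments(self) -> list[Fragment]:
        return [f for f in self.fragments if f.in_region]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t{int(f.in_region)}\n")

    @classmethod
    def from_bed(cls, path, enzyme: RestrictionEnzyme) -> "FragmentMap":
        frags = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, start, end, fid = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                in_region = bool(int(parts[4])) if len(parts) > 4 else False
                frags.append(Fragment(fid, chrom, start, end, in_region))
        return cls(frags, enzyme)


@dataclass
class Subfragment:
    """A second-enzyme subfragment of a first-enzyme fragment."""

    parent_id: int
    chrom: str
    start: int
    end: int
    label: str  # END or INTERNAL

    @property
    def length(self) -> int:
        return self.end - self.start


class SubfragmentMap:
    """Second-enzyme subfragments, grouped by parent fragment.

    END subfragments abut a first-enzyme cut (or a chromosome end) and carry
    ligation-junction information; INTERNAL subfragments lie strictly between
    two second-enzyme cuts and are uninformative — reads wholly inside them
    are removed by the classifier.
    """

    def __init__(self, by_parent: Mapping[int, Sequence[Subfragment]], enzyme2: RestrictionEnzyme):
        self.by_parent: dict[int, list[Subfragment]] = {
            pid: list(subs) for pid, subs in by_parent.items()
        }
        self.enzyme2 = enzyme2

    def __getitem__(self, parent_id: int) -> list[Subfragment]:
        return self.by_parent[parent_id]

    def __len__(self) -> int:
        return len(self.by_parent)

    def subfragment_at(self, parent_id: int, pos: int) -> Subfragment:
        for sub in self.by_parent[parent_id]:
            if sub.start <= pos < sub.end:
                return sub
        raise ValueError(f"position {pos} outside parent fragment {parent_id}")

    def end_subfragments(self, parent_id: int) -> list[Subfragment]:
        return [s for s in self.by_parent[parent_id] if s.label == END]

    def internal_subfragments(self, parent_id: int) -> list[Subfragment]:
        return [s for s in self.by_parent[parent_id] if s.label == INTERNAL]


def find_sites(seq: str, site: str) -> list[int]:
    """Start positions of every exact occurrence of ``site`` in ``seq``.

    Leftmost-first scan; overlapping occurrences are all reported.  Sites
    never match across N (exact string match only).
    """
    if "N" in site:
        raise ValueError("recognition site containing N is unsupported")
    positions = []
    i = seq.find(site)
    while i != -1:
        positions.append(i)
        i = seq.find(site, i + 1)
    return positions


def digest(
    genome: ReferenceGenome,
    enzyme: RestrictionEnzyme,
    region: str | tuple | Sequence | None = None,
) -> FragmentMap:
    """Digest the genome with ``enzyme``, producing the fragment tiling.

    Cut coordinates are ``site_start + cut_offset`` for every occurrence of
    the recognition site; chromosome ends close the terminal fragments.
    Fragments whose span intersects any ``region`` interval are flagged
    ``in_region`` (boundary fragments clipped by the window are counted).
    """
    regions: list[tuple[str, int, int]] = []
    if region is not None:
        if isinstance(region, (str, tuple)):
            region = [region]
        regions = [parse_region(r) for r in region]

    fragments: list[Fragment] = []
    fid = 0
    for chrom, seq in genome.sequences.items():
        cuts = [s + enzyme.cut_offset for s in find_sites(seq, enzyme.site)]
        # cuts at offset 0 of position 0 or at the very end produce no boundary
        cuts = [c for c in cuts if 0 < c < len(seq)]
        bounds = [0] + sorted(set(cuts)) + [len(seq)]
        for start, end in zip(bounds, bounds[1:]):
            in_region = any(
                rc == chrom and start < rend and end > rstart
                for rc, rstart, rend in regions
            )
            fragments.append(Fragment(fid, chrom, start, end, in_region))
            fid += 1
    return FragmentMap(fragments, enzyme, regions)


def double_digest(
    fragmap: FragmentMap,
    enzyme2: RestrictionEnzyme,
    genome: ReferenceGenome,
) -> SubfragmentMap:
    """Cut every first-enzyme fragment with the second enzyme.

    Subfragments tile their parent.  The first and last pieces are END; any
    piece bounded by two second-enzyme cuts is INTERNAL.  A parent with <2
    internal cuts yields only END subfragments.
    """
    if enzyme2.site == fragmap.enzyme.site:
        warnings.warn(
            "second enzyme has the same recognition site as the first; "
            "every subfragment will be END",
            stacklevel=2,
        )
    by_parent: dict[int, list[Subfragment]] = {}
    for frag in fragmap:
        seq = genome[frag.chrom][frag.start : frag.end]
        cuts = [
            frag.start + s + enzyme2.cut_offset
            for s in find_sites(seq, enzyme2.site)
        ]
        cuts = sorted({c for c in cuts if frag.start < c < frag.end})
        bounds = [frag.start] + cuts + [frag.end]
        subs = []
        n_pieces = len(bounds) - 1
        for k, (s, e) in enumerate(zip(bounds, bounds[1:])):
            label = END if (k == 0 or k == n_pieces - 1) else INTERNAL
            subs.append(Subfragment(frag.id, frag.chrom, s, e, label))
        by_parent[frag.id] = subs
    return SubfragmentMap(by_parent, enzyme2)


def median_resolution(fragmap: FragmentMap, in_region_only: bool = True) -> float:
    """Median fragment length (bp) — the map's effective resolution.

    With an even count, the mean of the two middle lengths is returned.
    """
    frags = fragmap.in_region_fragments if in_region_only else list(fragmap)
    if not frags:
        raise ValueError("no fragments in region")
    return float(median(f.length for f in frags))
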