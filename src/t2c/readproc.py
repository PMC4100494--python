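"""Read-pair processing: trimming, fragment assignment, pair classification.

Proximity-ligation read pairs carry several uninformative signal classes that
must be removed before contact counting: self-ligations (both ends on one
fragment), non-digestion/re-ligation events (adjacent fragments, convergent
reads at the shared cut), identical-end pairs / PCR duplicates, reads inside
internal second-enzyme subfragments, multi-fragment spans, and non-uniquely
mapped reads.  This module implements restriction-site and quality trimming,
span-based fragment assignment, and a fixed-precedence classifier, plus a
stream driver producing canonically ordered valid pairs and a class tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from .digestion import FragmentMap, SubfragmentMap, INTERNAL

__all__ = [
    "ReadEnd",
    "PairRecord",
    "PairClass",
    "FilterParams",
    "DISCARD",
    "trim_at_restriction_site",
    "quality_trim",
    "assign_fragment",
    "classify_pair",
    "process_pairs",
    "pairs_from_sam",
    "pairs_from_tsv",
    "write_valid_pairs",
    "write_tally",
    "MULTI_FRAGMENT",
    "INTERNAL_SUBFRAGMENT",
    "UNASSIGNED",
]

DISCARD = "DISCARD"

# assign_fragment sentinels (non-integer results)
MULTI_FRAGMENT = "MULTI_FRAGMENT"
INTERNAL_SUBFRAGMENT = "INTERNAL_SUBFRAGMENT"
UNASSIGNED = "UNASSIGNED"


class PairClass(Enum):
    """Exhaustive, mutually exclusive read-pair classes.

    Precedence (highest wins): UNMAPPED > NON_UNIQUE > MULTI_FRAGMENT >
    INTERNAL_SUBFRAGMENT > IDENTICAL_ENDS > SELF_LIGATION > NON_DIGESTION >
    VALID.
    """

    VALID = "VALID"
    SELF_LIGATION = "SELF_LIGATION"
    NON_DIGESTION = "NON_DIGESTION"
    IDENTICAL_ENDS = "IDENTICAL_ENDS"
    NON_UNIQUE = "NON_UNIQUE"
    MULTI_FRAGMENT = "MULTI_FRAGMENT"
    INTERNAL_SUBFRAGMENT = "INTERNAL_SUBFRAGMENT"
    UNMAPPED = "UNMAPPED"


@dataclass
class ReadEnd:
    read_id: str
    mate: int  # 1 or 2
    seq: str = ""
    qualities: Sequence[int] = ()
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 0-based leftmost aligned position
    strand: str = "+"
    mapq: int = 0
    span: Optional[tuple[int, int]] = None  # aligned half-open interval

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None and self.span is not None


@dataclass
class PairRecord:
    read_id: str
    end1: ReadEnd
    end2: ReadEnd
    frag1: object = UNASSIGNED  # fragment id, or an assignment sentinel
    frag2: object = UNASSIGNED
    pair_class: Optional[PairClass] = None


@dataclass
class FilterParams:
    q_min: int = 10
    min_len: int = 12
    mapq_min: int = 20
    junction_tol: int = 5  # bp window around the shared cut for re-ligation calls


def trim_at_restriction_site(read: ReadEnd, site: str) -> ReadEnd:
    """Trim a read at the first occurrence of the recognition site.

    Ligation junctions restore the full recognition site, so sequence after
    the 3' end of the first site belongs to the ligation partner and is
    removed; the trimmed read then contains and ends with a single site.
    Reads without the site are returned unchanged.
    """
    if not site:
        raise ValueError("empty recognition site")
    i = read.seq.find(site)
    if i == -1:
        return read
    keep = i + len(site)
    if keep >= len(read.seq):
        return read
    return replace(read, seq=read.seq[:keep], qualities=list(read.qualities)[:keep])


def quality_trim(read: ReadEnd, q_min: int = 10, min_len: int = 12):
    """Strip low-quality runs from both ends; DISCARD if too little remains.

    Maximal runs of bases with phred quality < ``q_min`` are removed from
    each end; a read retaining fewer than ``min_len`` bases is discarded.
    Idempotent.
    """
    quals = list(read.qualities)
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < q_min:
        lo += 1
    while hi > lo and quals[hi - 1] < q_min:
        hi -= 1
    if hi - lo < min_len:
        return DISCARD
    if lo == 0 and hi == len(quals):
        return read
    return replace(read, seq=read.seq[lo:hi], qualities=quals[lo:hi])


def assign_fragment(end: ReadEnd, fragmap: FragmentMap, subfragmap: SubfragmentMap | None = None):
    """Assign an aligned read end to a first-enzyme fragment.

    The full aligned span is used: a span intersecting more than one fragment
    is MULTI_FRAGMENT; a span wholly inside an INTERNAL second-enzyme
    subfragment is INTERNAL_SUBFRAGMENT; otherwise the containing fragment's
    id is returned.
    """
    if not end.is_mapped:
        return UNASSIGNED
    start, stop = end.span
    frags = fragmap.overlapping(end.chrom, start, stop)
    if not frags:
        raise ValueError(f"aligned span {end.chrom}:{start}-{stop} outside the genome")
    if len(frags) > 1:
        return MULTI_FRAGMENT
    frag = frags[0]
    if subfragmap is not None:
        for sub in subfragmap.internal_subfragments(frag.id):
            if sub.start <= start and stop <= sub.end:
                return INTERNAL_SUBFRAGMENT
    return frag.id


def classify_pair(
    rec: PairRecord,
    fragmap: FragmentMap,
    params: FilterParams | None = None,
) -> PairClass:
    """Classify one read pair under the fixed precedence order.

    Assumes ``rec.frag1``/``rec.frag2`` were set by :func:`assign_fragment`.
    A NON_DIGESTION call requires adjacent fragments on one chromosome with
    the two inner read ends within ``junction_tol`` bp of the shared cut in
    convergent orientation — plain adjacent pairs remain VALID, since
    neighbouring fragments genuinely interact in 3C data.
    """
    params = params or FilterParams()
    e1, e2 = rec.end1, rec.end2
    if not (e1.is_mapped and e2.is_mapped):
        return PairClass.UNMAPPED
    if min(e1.mapq, e2.mapq) < params.mapq_min:
        return PairClass.NON_UNIQUE
    if MULTI_FRAGMENT in (rec.frag1, rec.frag2):
        return PairClass.MULTI_FRAGMENT
    if INTERNAL_SUBFRAGMENT in (rec.frag1, rec.frag2):
        return PairClass.INTERNAL_SUBFRAGMENT
    if (e1.chrom, e1.pos, e1.strand) == (e2.chrom, e2.pos, e2.strand):
        return PairClass.IDENTICAL_ENDS
    if rec.frag1 == rec.frag2:
        return PairClass.SELF_LIGATION
    f1, f2 = fragmap[rec.frag1], fragmap[rec.frag2]
    if f1.chrom == f2.chrom and abs(f1.id - f2.id) == 1:
        lower, upper = (f1, f2) if f1.id < f2.id else (f2, f1)
        cut = lower.end  # shared first-enzyme cut
        end_lower = e1 if rec.frag1 == lower.id else e2
        end_upper = e2 if end_lower is e1 else e1
        if (
            end_lower.strand == "+"
            and end_upper.strand == "-"
            and abs(end_lower.span[1] - cut) <= params.junction_tol
            and abs(end_upper.span[0] - cut) <= params.junction_tol
        ):
            return PairClass.NON_DIGESTION
    return PairClass.VALID


def _canonical(rec: PairRecord) -> PairRecord:
    """Order mates so that frag1 <= frag2 (ties by coordinate)."""
    f1, f2 = rec.frag1, rec.frag2
    if isinstance(f1, int) and isinstance(f2, int) and f1 > f2:
        return replace(rec, end1=rec.end2, end2=rec.end1, frag1=f2, frag2=f1)
    return rec


def _signature(rec: PairRecord):
    # full aligned spans, not just 5' positions: with a double digest the
    # junction-side coordinate is pinned at the cut, so spans are what
    # distinguishes distinct molecules
    a = (rec.end1.chrom, rec.end1.span, rec.end1.strand)
    b = (rec.end2.chrom, rec.end2.span, rec.end2.strand)
    return (a, b) if a <= b else (b, a)


def process_pairs(
    pairs: Iterable[PairRecord],
    fragmap: FragmentMap,
    subfragmap: SubfragmentMap | None = None,
    params: FilterParams | None = None,
) -> tuple[list[PairRecord], dict[PairClass, int]]:
    """Classify a stream of pairs; return canonical VALID pairs and a tally.

    Exact-coordinate duplicates of an already-seen mapped pair are flagged
    IDENTICAL_ENDS (the first occurrence keeps its own class), so this class
    doubles as duplicate removal; class tallies always sum to the input pair
    count.
    """
    params = params or FilterParams()
    tally: dict[PairClass, int] = {c: 0 for c in PairClass}
    valid: list[PairRecord] = []
    seen: set = set()
    for rec in pairs:
        rec.frag1 = assign_fragment(rec.end1, fragmap, subfragmap)
        rec.frag2 = assign_fragment(rec.end2, fragmap, subfragmap)
        if rec.end1.is_mapped and rec.end2.is_mapped:
            sig = _signature(rec)
            if sig in seen:
                rec.pair_class = PairClass.IDENTICAL_ENDS
                tally[PairClass.IDENTICAL_ENDS] += 1
                continue
            seen.add(sig)
        rec.pair_class = classify_pair(rec, fragmap, params)
        tally[rec.pair_class] += 1
        if rec.pair_class is PairClass.VALID:
            valid.append(_canonical(rec))
    return valid, tally


# ---------------------------------------------------------------------------
# I/O plumbing


def pairs_from_sam(path) -> Iterator[PairRecord]:
    """Read mate pairs from a (name-sorted or unsorted) SAM/BAM file.

    Mates are joined on read name; unmapped mates yield ReadEnds with no
    coordinates so the classifier counts them as UNMAPPED.
    """
    pending: dict[str, ReadEnd] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            end = ReadEnd(
                read_id=aln.query_name,
                mate=2 if aln.is_read2 else 1,
                seq=aln.query_sequence or "",
                qualities=list(aln.query_qualities or ()),
                chrom=None if aln.is_unmapped else aln.reference_name,
                pos=None if aln.is_unmapped else aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
                span=None if aln.is_unmapped else (aln.reference_start, aln.reference_end),
            )
            other = pending.pop(aln.query_name, None)
            if other is None:
                pending[aln.query_name] = end
            else:
                e1, e2 = (other, end) if other.mate == 1 else (end, other)
                yield PairRecord(aln.query_name, e1, e2)
    for leftover in pending.values():
        yield PairRecord(
            leftover.read_id,
            leftover if leftover.mate == 1 else ReadEnd(leftover.read_id, 1),
            leftover if leftover.mate == 2 else ReadEnd(leftover.read_id, 2),
        )


_TSV_COLUMNS = [
    "read_id",
    "chrom1", "start1", "end1", "strand1", "mapq1",
    "chrom2", "start2", "end2", "strand2", "mapq2",
]


def pairs_from_tsv(path) -> Iterator[PairRecord]:
    """Read aligned pairs from the simulator's tabular format.

    Columns: read_id, then chrom/start/end/strand/mapq per mate; '.' as
    chrom marks an unmapped mate.
    """
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            ends = []
            for mate, k in ((1, 1), (2, 6)):
                chrom = p[k]
                if chrom == ".":
                    ends.append(ReadEnd(p[0], mate))
                else:
                    s, e = int(p[k + 1]), int(p[k + 2])
                    ends.append(
                        ReadEnd(p[0], mate, chrom=chrom, pos=s, strand=p[k + 3],
                                mapq=int(p[k + 4]), span=(s, e))
                    )
            yield PairRecord(p[0], ends[0], ends[1])


def write_pairs_tsv(pairs: Iterable[PairRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for rec in pairs:
            row = [rec.read_id]
            for end in (rec.end1, rec.end2):
                if end.is_mapped:
                    row += [end.chrom, str(end.span[0]), str(end.span[1]), end.strand, str(end.mapq)]
                else:
                    row += [".", "-1", "-1", ".", "0"]
            fh.write("\t".join(row) + "\n")


def write_valid_pairs(valid: Iterable[PairRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom1\tpos1\tstrand1\tfrag1\tchrom2\tpos2\tstrand2\tfrag2\n")
        for rec in valid:
            fh.write(
                f"{rec.read_id}\t{rec.end1.chrom}\t{rec.end1.pos}\t{rec.end1.strand}\t{rec.frag1}\t"
                f"{rec.end2.chrom}\t{rec.end2.pos}\t{rec.end2.strand}\t{rec.frag2}\n"
            )


def write_tally(tally: dict[PairClass, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_class\tcount\n")
        for cls in PairClass:
            fh.write(f"{cls.value}\t{tally.get(cls, 0)}\n")
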