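"""Capture-probe design at first-enzyme fragment ends.

Oligonucleotides (62–90 nt by default) are placed as close as possible to the
first-enzyme cut of each in-region fragment end, must not cross the nearest
second-enzyme site (probes that would are trimmed, down to a minimum length),
must be unique in the genome, and are length-tuned so their melting
temperatures cluster around a common target.  Ends that cannot satisfy the
rules are reported as uncapturable with a reason — that is data, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Optional

from Bio.SeqUtils import MeltingTemp as _mt

from .digestion import (
    END,
    FragmentMap,
    ReferenceGenome,
    SubfragmentMap,
    revcomp,
)

__all__ = [
    "Probe",
    "ProbeSet",
    "DesignParams",
    "melting_temperature",
    "is_unique",
    "design_probes",
    "replicate_probes",
]

LEFT = "LEFT"
RIGHT = "RIGHT"

# Hybridization conditions used for all Tm calculations (mM monovalent salt,
# nM strand concentrations). Fixed so designs are deterministic.
_TM_CONDITIONS = dict(Na=50, K=0, Tris=0, Mg=0, dNTPs=0, dnac1=250, dnac2=250)


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor melting temperature (°C) of a DNA oligo.

    Uses the unified nearest-neighbor thermodynamic parameters with a
    monovalent-salt entropy correction at the module's fixed hybridization
    conditions.  Deterministic; strand-symmetric (a sequence and its reverse
    complement form the same duplex).
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt")
    if "N" in seq or not set(seq) <= set("ACGT"):
        raise ValueError("sequence must be unambiguous A/C/G/T")
    return float(_mt.Tm_NN(seq, **_TM_CONDITIONS))


def _count_occurrences(genome: ReferenceGenome, kmer: str) -> int:
    """Occurrences of ``kmer`` in the genome, both strands.

    A palindromic k-mer's forward and reverse-complement hits are the same
    physical occurrence and are counted once.
    """
    total = 0
    rc = revcomp(kmer)
    for seq in genome.sequences.values():
        i = seq.find(kmer)
        while i != -1:
            total += 1
            i = seq.find(kmer, i + 1)
        if rc != kmer:
            i = seq.find(rc)
            while i != -1:
                total += 1
                i = seq.find(rc, i + 1)
    return total


def is_unique(seq: str, genome: ReferenceGenome, seed_len: int | None = None) -> bool:
    """True iff every ``seed_len``-mer of ``seq`` occurs exactly once in the
    genome, counting both strands.

    ``seed_len`` defaults to ``len(seq)`` (full-length exact uniqueness).
    The k-mers of the reverse complement are the reverse complements of the
    k-mers of ``seq``, so checking ``seq``'s k-mers covers both orientations.
    """
    seq = seq.upper()
    if seed_len is None:
        seed_len = len(seq)
    if seed_len > len(seq):
        raise ValueError("seed_len exceeds sequence length")
    for i in range(len(seq) - seed_len + 1):
        if _count_occurrences(genome, seq[i : i + seed_len]) != 1:
            return False
    return True


@dataclass
class Probe:
    probe_id: str
    fragment_id: int
    end: str  # LEFT or RIGHT
    chrom: str
    start: int  # forward-strand coordinates, 0-based half-open
    stop: int
    sequence: str  # oriented reading away from the first-enzyme cut
    tm: float
    unique: bool = True
    trimmed: bool = False

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class DesignParams:
    min_len: int = 62
    max_len: int = 90
    min_probe_len: int = 30  # floor for probes trimmed at a second-enzyme site
    tm_target: Optional[float] = None  # None: median Tm of leftmost full-length candidates
    tm_window: float = 5.0
    seed_len: Optional[int] = None  # None: full probe length
    slide_max: int = 10  # bp of inward slide allowed before declaring non-unique


@dataclass
class UncapturableEnd:
    fragment_id: int
    end: str
    reason: str  # "too-short" | "non-unique" | "tm-out-of-window"


@dataclass
class ProbeSet:
    probes: list[Probe]
    params: DesignParams
    uncapturable: list[UncapturableEnd] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def fragment_ids(self) -> set[int]:
        """Fragments represented by at least one probe."""
        return {p.fragment_id for p in self.probes}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("probe_id\tfragment_id\tend\tchrom\tstart\tstop\tsequence\ttm\ttrimmed\n")
            for p in self.probes:
                fh.write(
                    f"{p.probe_id}\t{p.fragment_id}\t{p.end}\t{p.chrom}\t{p.start}\t"
                    f"{p.stop}\t{p.sequence}\t{p.tm:.2f}\t{int(p.trimmed)}\n"
                )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.probes:
                strand = "+" if p.end == LEFT else "-"
                fh.write(f"{p.chrom}\t{p.start}\t{p.stop}\t{p.probe_id}\t{p.tm:.1f}\t{strand}\n")


def _candidate_seq(genome: ReferenceGenome, chrom: str, start: int, stop: int, end: str) -> str:
    seq = genome[chrom][start:stop]
    # RIGHT-end probes read on the reverse complement so that both ends are
    # anchored at their cut and extend inward symmetrically.
    return seq if end == LEFT else revcomp(seq)


def _end_windows(fragmap: FragmentMap, subfragmap: SubfragmentMap):
    """Yield (fragment, end, cut_pos, available_bp) for each in-region end.

    ``available_bp`` is the span from the first-enzyme cut to the nearest
    second-enzyme site — the extent of the END subfragment at that end.
    """
    for frag in fragmap.in_region_fragments:
        subs = subfragmap[frag.id]
        left_sub = subs[0]
        right_sub = subs[-1]
        yield frag, LEFT, frag.start, left_sub.length
        if len(subs) > 1:
            yield frag, RIGHT, frag.end, right_sub.length


def design_probes(
    genome: ReferenceGenome,
    fragmap: FragmentMap,
    subfragmap: SubfragmentMap,
    params: DesignParams | None = None,
) -> ProbeSet:
    """Design one capture oligo per in-region fragment end.

    For each end the candidate window starts at the first-enzyme cut and
    extends inward, bounded by the nearest second-enzyme site:

    * >= ``min_len`` bp available: among lengths ``min_len..min(max_len,
      available)`` pick the length whose Tm is closest to ``tm_target``;
    * < ``min_len`` bp available: the probe is trimmed to the available
      length if that is >= ``min_probe_len``, else the end is uncapturable
      ("too-short");
    * a non-unique candidate may slide inward up to ``slide_max`` bp before
      the end is declared uncapturable ("non-unique");
    * a candidate whose Tm deviates from ``tm_target`` by more than
      ``tm_window`` is rejected ("tm-out-of-window"), so the Tm spread of the
      returned set is at most ``2 * tm_window``.

    When ``tm_target`` is None it defaults to the median Tm of the leftmost
    full-length (``min_len``-mer) candidates over all admissible ends, so the
    set self-centres its melting temperatures.
    """
    params = params or DesignParams()
    windows = list(_end_windows(fragmap, subfragmap))

    tm_target = params.tm_target
    if tm_target is None:
        anchor_tms = []
        for frag, end, cut, avail in windows:
            if avail >= params.min_len:
                if end == LEFT:
                    s, e = cut, cut + params.min_len
                else:
                    s, e = cut - params.min_len, cut
                seq = _candidate_seq(genome, frag.chrom, s, e, end)
                if "N" not in seq:
                    anchor_tms.append(melting_temperature(seq))
        if not anchor_tms:
            raise ValueError("no full-length candidate windows; cannot infer tm_target")
        tm_target = float(median(anchor_tms))
    params = DesignParams(**{**params.__dict__, "tm_target": tm_target})

    probes: list[Probe] = []
    uncapturable: list[UncapturableEnd] = []
    for frag, end, cut, avail in windows:
        probe = _design_one_end(genome, frag, end, cut, avail, params)
        if isinstance(probe, Probe):
            probes.append(probe)
        else:
            uncapturable.append(UncapturableEnd(frag.id, end, probe))
    return ProbeSet(probes, params, uncapturable)


def _interval(cut: int, length: int, offset: int, end: str) -> tuple[int, int]:
    """Forward-strand interval of a candidate slid ``offset`` bp inward."""
    if end == LEFT:
        return cut + offset, cut + offset + length
    return cut - offset - length, cut - offset


def _design_one_end(genome, frag, end, cut, avail, params: DesignParams):
    """Design a probe for one fragment end; returns a Probe or a reason str."""
    trimmed = False
    if avail >= params.min_len:
        lengths = range(params.min_len, min(params.max_len, avail) + 1)
    elif avail >= params.min_probe_len:
        lengths = [avail]  # trimmed at the second-enzyme site
        trimmed = True
    else:
        return "too-short"

    # Rank candidate lengths by |Tm - target|, deterministic tie-break on
    # shorter length.
    scored = []
    for L in lengths:
        s, e = _interval(cut, L, 0, end)
        seq = _candidate_seq(genome, frag.chrom, s, e, end)
        if "N" in seq:
            continue
        scored.append((abs(melting_temperature(seq) - params.tm_target), L, s, e, seq))
    if not scored:
        return "too-short"
    scored.sort(key=lambda t: (t[0], t[1]))
    dev, L, s, e, seq = scored[0]
    # melting temperatures must cluster within the window around the target,
    # which bounds the Tm spread of the whole set by 2*tm_window
    if dev > params.tm_window:
        return "tm-out-of-window"

    # Uniqueness gate with bounded inward slide (relaxing "as close as
    # possible to the cut" by at most slide_max bp).
    for offset in range(params.slide_max + 1):
        s, e = _interval(cut, L, offset, end)
        if s < frag.start or e > frag.end:
            break
        seq = _candidate_seq(genome, frag.chrom, s, e, end)
        if "N" in seq or abs(melting_temperature(seq) - params.tm_target) > params.tm_window:
            continue
        if is_unique(seq, genome, params.seed_len):
            return Probe(
                probe_id=f"frag{frag.id}_{end[0]}",
                fragment_id=frag.id,
                end=end,
                chrom=frag.chrom,
                start=s,
                stop=e,
                sequence=seq,
                tm=melting_temperature(seq),
                unique=True,
                trimmed=trimmed,
            )
    return "non-unique"


def replicate_probes(probeset: ProbeSet | int, array_capacity: int) -> int:
    """Spots per probe when replicating a set equally up to array capacity.

    Accepts a ProbeSet or a plain probe count; returns
    ``floor(capacity / count)`` (e.g. 800 probes on a 2.1M-feature array are
    each spotted 2,625 times).
    """
    count = probeset if isinstance(probeset, int) else len(probeset)
    if count <= 0:
        raise ValueError("zero probes")
    if array_capacity < count:
        raise ValueError("array capacity smaller than probe count")
    return array_capacity // count
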