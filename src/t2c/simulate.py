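"""Synthetic T2C data: genomes, ground-truth contacts, contaminated reads.

The generator makes every pipeline stage testable without external data:

* :func:`simulate_genome` builds random chromosomes with first- and
  second-enzyme sites implanted at exponential spacings (accidental site
  occurrences are scrubbed first, so the implant log *is* the digest truth);
* :func:`sample_contacts` draws fragment pairs from a distance-decay model
  ``P(i,j) ∝ (1+d_ij)^(-α)`` with planted domain blocks and loops;
* :func:`emit_reads` turns true pairs into aligned pair records and FASTQ
  reads, contaminated with self-ligation, non-digestion, duplicates,
  internal-subfragment reads and non-unique mappings at stated rates, with a
  per-pair truth table.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .digestion import (
    END,
    Fragment,
    FragmentMap,
    ReferenceGenome,
    RestrictionEnzyme,
    SubfragmentMap,
    digest,
    double_digest,
    find_sites,
    get_enzyme,
    revcomp,
)
from .readproc import PairClass, PairRecord, ReadEnd

__all__ = [
    "ContactModel",
    "ContaminationProfile",
    "TruthRecord",
    "SimulatedGenome",
    "EmittedReads",
    "simulate_genome",
    "sample_contacts",
    "emit_reads",
    "estimate_decay_exponent",
    "write_fastq",
]


@dataclass
class ContactModel:
    """Distance-decay contact probabilities with planted structure.

    ``P(i,j) ∝ (1+d_ij)^(-decay_exponent) × block × loop`` for cis pairs,
    d in bp between fragment midpoints; a ``trans_fraction`` of pairs is
    drawn uniformly across chromosomes (when there are at least two).
    """

    decay_exponent: float = 1.0
    domains: Sequence[tuple[int, int, float]] = ()  # (start_frag, end_frag, multiplier)
    loops: Sequence[tuple[int, int, float]] = ()    # (frag_i, frag_j, multiplier)
    trans_fraction: float = 0.0

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be positive")
        if any(m <= 0 for *_, m in list(self.domains) + list(self.loops)):
            raise ValueError("multipliers must be positive")
        if not 0 <= self.trans_fraction < 1:
            raise ValueError("trans_fraction in [0, 1)")


@dataclass
class ContaminationProfile:
    """Per-pair contamination rates and the read/quality model.

    Classes are drawn by a single categorical draw per pair, mutually
    exclusive, matching the classifier's exclusivity; the remainder is VALID.
    """

    p_self_ligation: float = 0.05
    p_non_digestion: float = 0.05
    p_duplicate: float = 0.05
    p_internal_subfragment: float = 0.03
    p_multimap: float = 0.05
    read_length: int = 101  # HiSeq 101-cycle protocol
    mean_quality: int = 35
    quality_decay: float = 0.10  # phred drop per base toward the 3' end
    p_lowq_tail: float = 0.3     # chance of a short low-quality 3' tail

    def __post_init__(self):
        ps = [self.p_self_ligation, self.p_non_digestion, self.p_duplicate,
              self.p_internal_subfragment, self.p_multimap]
        if any(not 0 <= p <= 1 for p in ps) or sum(ps) > 1:
            raise ValueError("class probabilities must lie in [0,1] and sum <= 1")


@dataclass
class TruthRecord:
    pair_id: str
    true_class: PairClass
    frag_i: int
    frag_j: int
    duplicate_of: Optional[str] = None


@dataclass
class SimulatedGenome:
    """A synthetic reference plus the implant log the tests check against."""

    genome: ReferenceGenome
    cut_positions: dict[str, dict[str, list[int]]]  # enzyme name -> chrom -> cuts
    duplicated_segment: Optional[tuple[str, int, int, str, int]] = None
    # (chrom, start, end, dest_chrom, dest_start) of the planted duplication


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _scrub_sites(arr: np.ndarray, sites: Sequence[str], rng: np.random.Generator,
                 protected: Sequence[tuple[int, int]] = ()) -> None:
    """Destroy accidental occurrences of the recognition sites in place.

    Bases inside ``protected`` intervals (deliberate implants) are left
    untouched.  Iterates until no stray occurrence remains.
    """
    prot = np.zeros(len(arr), dtype=bool)
    for s, e in protected:
        prot[s:e] = True
    for _ in range(50):
        seq = arr.tobytes().decode()
        dirty = False
        for site in sites:
            keep = {(s, s + len(site)) for s in protected_starts(protected, len(site))}
            for pos in find_sites(seq, site):
                if (pos, pos + len(site)) in keep:
                    continue
                # flip one unprotected base inside the occurrence
                for off in range(len(site)):
                    if not prot[pos + off]:
                        choices = [b for b in b"ACGT" if b != arr[pos + off][0]]
                        arr[pos + off] = bytes([rng.choice(choices)])
                        dirty = True
                        break
                else:  # fully protected stray occurrence: leave it
                    continue
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental recognition sites")


def protected_starts(protected: Sequence[tuple[int, int]], site_len: int) -> list[int]:
    return [s for s, e in protected if e - s == site_len]


def _implant_positions(rng: np.random.Generator, length: int, mean_spacing: float,
                       site_len: int, forbidden: list[tuple[int, int]]) -> list[int]:
    """Site start positions at ~Exponential(mean_spacing) gaps, skipping
    collisions with already-occupied intervals."""
    positions = []
    pos = float(rng.exponential(mean_spacing))
    while pos + site_len < length - 1:
        start = int(pos)
        if all(start + site_len <= fs or start >= fe for fs, fe in forbidden):
            positions.append(start)
            forbidden.append((start, start + site_len))
        pos += max(rng.exponential(mean_spacing), site_len + 2)
    return positions


def simulate_genome(
    n_chrom: int = 1,
    length: int = 300_000,
    gc: float = 0.45,
    enzyme1: RestrictionEnzyme | str = "HindIII",
    enzyme2: RestrictionEnzyme | str = "NlaIII",
    target_frag_len: int = 3_000,
    target_subfrag_len: int = 450,
    seed: int | np.random.Generator = 0,
    plant_duplicate: bool = False,
    read_length: int = 75,
) -> SimulatedGenome:
    """Build a random genome with implanted restriction sites.

    First-enzyme sites are implanted at ~Exponential(``target_frag_len``)
    spacings (matching the observed near-exponential fragment-length
    distribution of a 6-cutter) and second-enzyme sites at
    ~Exponential(``target_subfrag_len``) spacings within fragments.  The
    random background is scrubbed of accidental occurrences of both sites,
    so the implant log equals the digest result exactly.  Optionally a
    duplicated segment is planted for probe-uniqueness tests.
    """
    if target_frag_len <= 2 * read_length:
        raise ValueError("target fragment length must exceed twice the read length")
    if isinstance(enzyme1, str):
        enzyme1 = get_enzyme(enzyme1)
    if isinstance(enzyme2, str):
        enzyme2 = get_enzyme(enzyme2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sequences: dict[str, str] = {}
    cut_positions: dict[str, dict[str, list[int]]] = {enzyme1.name: {}, enzyme2.name: {}}
    duplicated = None
    for c in range(n_chrom):
        chrom = f"chrS{c + 1}"
        arr = _random_bases(rng, length, gc)
        occupied: list[tuple[int, int]] = []
        pos1 = _implant_positions(rng, length, target_frag_len, len(enzyme1.site), occupied)
        pos2 = _implant_positions(rng, length, target_subfrag_len, len(enzyme2.site), occupied)
        _scrub_sites(arr, [enzyme1.site, enzyme2.site], rng, protected=occupied)
        site1 = np.frombuffer(enzyme1.site.encode(), dtype="S1")
        site2 = np.frombuffer(enzyme2.site.encode(), dtype="S1")
        for p in pos1:
            arr[p : p + len(site1)] = site1
        for p in pos2:
            arr[p : p + len(site2)] = site2
        _scrub_sites(
            arr, [enzyme1.site, enzyme2.site], rng,
            protected=[(p, p + len(enzyme1.site)) for p in pos1]
            + [(p, p + len(enzyme2.site)) for p in pos2],
        )
        seq = arr.tobytes().decode()
        sequences[chrom] = seq
        cut_positions[enzyme1.name][chrom] = sorted(p + enzyme1.cut_offset for p in pos1)
        cut_positions[enzyme2.name][chrom] = sorted(p + enzyme2.cut_offset for p in pos2)

    if plant_duplicate:
        # copy a site-free segment from the first chromosome onto itself
        chrom = next(iter(sequences))
        seq = sequences[chrom]
        seg_len = 200
        src = length // 3
        dst = 2 * length // 3
        all_sites = sorted(
            s for site in (enzyme1.site, enzyme2.site) for s in find_sites(seq, site)
        )

        def site_free(start):
            return all(not (start - len(enzyme1.site) < s < start + seg_len) for s in all_sites)

        while not site_free(src):
            src += 50
        while not site_free(dst) or abs(dst - src) < seg_len:
            dst += 50
        segment = seq[src : src + seg_len]
        sequences[chrom] = seq[:dst] + segment + seq[dst + seg_len :]
        duplicated = (chrom, src, src + seg_len, chrom, dst)

    return SimulatedGenome(ReferenceGenome(sequences), cut_positions, duplicated)


# ---------------------------------------------------------------------------
# Contact sampling


def _cis_pair_arrays(fragmap: FragmentMap, model: ContactModel):
    """Index arrays, distances and model weights for all cis pairs i<j."""
    ids, mids, chroms = [], [], []
    for f in fragmap:
        ids.append(f.id)
        mids.append(f.midpoint)
        chroms.append(f.chrom)
    ids = np.asarray(ids)
    mids = np.asarray(mids)
    chroms = np.asarray(chroms)

    ii, jj, dd = [], [], []
    for chrom in dict.fromkeys(chroms.tolist()):
        mask = chroms == chrom
        cid = ids[mask]
        cmid = mids[mask]
        a, b = np.triu_indices(len(cid), k=1)
        ii.append(cid[a])
        jj.append(cid[b])
        dd.append(np.abs(cmid[a] - cmid[b]))
    i_arr = np.concatenate(ii)
    j_arr = np.concatenate(jj)
    d_arr = np.concatenate(dd)

    w = (1.0 + d_arr) ** (-model.decay_exponent)
    for fs, fe, mult in model.domains:
        inside = (i_arr >= fs) & (i_arr <= fe) & (j_arr >= fs) & (j_arr <= fe)
        w[inside] *= mult
    if model.loops:
        loop_mult = {(min(i, j), max(i, j)): m for i, j, m in model.loops}
        for k, (i, j) in enumerate(zip(i_arr, j_arr)):
            m = loop_mult.get((int(i), int(j)))
            if m is not None:
                w[k] *= m
    return i_arr, j_arr, d_arr, w


def sample_contacts(
    fragmap: FragmentMap,
    model: ContactModel,
    n_pairs: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[int, int]]:
    """Draw ``n_pairs`` true fragment pairs from the contact model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i_arr, j_arr, _, w = _cis_pair_arrays(fragmap, model)
    if w.sum() <= 0:
        raise ValueError("contact model not normalizable over this fragment map")

    chrom_of = {f.id: f.chrom for f in fragmap}
    chrom_names = sorted(set(chrom_of.values()))
    n_trans = 0
    if model.trans_fraction > 0 and len(chrom_names) > 1:
        n_trans = int(rng.binomial(n_pairs, model.trans_fraction))

    idx = rng.choice(len(w), size=n_pairs - n_trans, p=w / w.sum())
    pairs = [(int(i_arr[k]), int(j_arr[k])) for k in idx]

    by_chrom: dict[str, list[int]] = {}
    for fid, chrom in chrom_of.items():
        by_chrom.setdefault(chrom, []).append(fid)
    for _ in range(n_trans):
        c1, c2 = rng.choice(len(chrom_names), size=2, replace=False)
        i = int(rng.choice(by_chrom[chrom_names[c1]]))
        j = int(rng.choice(by_chrom[chrom_names[c2]]))
        pairs.append((min(i, j), max(i, j)))
    return pairs


def estimate_decay_exponent(
    matrix,
    fragmap: FragmentMap,
    exclude: Iterable[tuple[int, int]] = (),
    n_bins: int = 12,
) -> float:
    """Recover the distance-decay exponent α from an observed contact matrix.

    Cis entries are pooled into log-spaced distance bins; the mean count per
    *possible* fragment pair in each bin follows ``(1+d)^(-α)``, so the
    negative slope of log(mean count) against log(1+d) estimates α.  Pairs in
    ``exclude`` (planted loops, in-domain pairs) are dropped from both the
    observed counts and the possible-pair denominators.
    """
    excl = {(min(i, j), max(i, j)) for i, j in exclude}
    mids = {f.id: f.midpoint for f in fragmap}
    chrom = {f.id: f.chrom for f in fragmap}

    obs: dict[tuple[int, int], int] = {
        k: n for k, n in matrix.entries.items()
        if chrom[k[0]] == chrom[k[1]] and k not in excl
    }
    # all possible cis pairs over fragments that appear in the matrix scope
    ids_by_chrom: dict[str, list[int]] = {}
    scoped = (
        fragmap.in_region_fragments
        if getattr(matrix, "scope", None) == "IN_REGION"
        else list(fragmap)
    )
    for f in scoped:
        ids_by_chrom.setdefault(f.chrom, []).append(f.id)
    poss_d, poss_key = [], []
    for fids in ids_by_chrom.values():
        arr = np.asarray(fids)
        a, b = np.triu_indices(len(arr), k=1)
        for i, j in zip(arr[a], arr[b]):
            key = (int(i), int(j))
            if key in excl:
                continue
            poss_d.append(abs(mids[key[0]] - mids[key[1]]))
            poss_key.append(key)
    poss_d = np.asarray(poss_d)
    obs_counts = np.asarray([obs.get(k, 0) for k in poss_key], dtype=float)

    d_pos = poss_d[poss_d > 0]
    edges = np.geomspace(max(d_pos.min(), 1.0), d_pos.max() + 1, n_bins + 1)
    which = np.digitize(poss_d, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        n_possible = int(sel.sum())
        total = obs_counts[sel].sum()
        if n_possible >= 20 and total >= 10:
            xs.append(math.log(1.0 + float(poss_d[sel].mean())))
            ys.append(math.log(total / n_possible))
    if len(xs) < 3:
        raise ValueError("too few populated distance bins to fit a decay exponent")
    slope = np.polyfit(xs, ys, 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# Read emission


@dataclass
class FastqRead:
    read_id: str
    mate: int
    seq: str
    qualities: list[int]


@dataclass
class EmittedReads:
    pairs: list[PairRecord]           # aligned pair records (aligner bypass)
    reads1: list[FastqRead]
    reads2: list[FastqRead]
    truth: list[TruthRecord]
    expected_trimmed: dict[tuple[str, int], str]  # (read_id, mate) -> sequence

    def truth_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pair_id\ttrue_class\tfrag_i\tfrag_j\tduplicate_of\n")
            for t in self.truth:
                dup = t.duplicate_of or "."
                fh.write(f"{t.pair_id}\t{t.true_class.value}\t{t.frag_i}\t{t.frag_j}\t{dup}\n")


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}/{r.mate}\n{r.seq}\n+\n{qual}\n")


class _Emitter:
    def __init__(self, genome: ReferenceGenome, fragmap: FragmentMap,
                 subfragmap: SubfragmentMap, profile: ContaminationProfile,
                 rng: np.random.Generator):
        self.genome = genome
        self.fragmap = fragmap
        self.subfragmap = subfragmap
        self.profile = profile
        self.rng = rng
        self.site = fragmap.enzyme.site
        self.offset = fragmap.enzyme.cut_offset
        self.remainder_r = self.site[self.offset:]          # completes an R-end junction
        self.remainder_l = revcomp(self.site[: self.offset])  # completes an L-end junction
        self.last_id = {f.chrom: 0 for f in fragmap}
        for f in fragmap:
            self.last_id[f.chrom] = max(self.last_id[f.chrom], f.id)
        self.first_id = {}
        for f in fragmap:
            self.first_id.setdefault(f.chrom, f.id)
        self.internal_candidates = [
            fid for fid in range(len(fragmap))
            if any(s.length >= 20 for s in subfragmap.internal_subfragments(fid))
        ]

    # -- mate builders ------------------------------------------------------
    def _span_len(self, end_len: int, remainder: str) -> int:
        """Random aligned length: junction position is fixed at the cut, but
        the outer read end varies (as quality trimming makes it in real
        data), which is what makes exact-coordinate duplicates rare."""
        cap = max(1, min(self.profile.read_length - len(remainder), end_len))
        lo = min(12, cap)
        return int(self.rng.integers(lo, cap + 1))

    def mate_r(self, frag: Fragment, read_id: str, mate: int):
        """Mate on the RIGHT end of ``frag``, reading + strand into the cut."""
        subs = self.subfragmap[frag.id]
        L = self._span_len(subs[-1].length, self.remainder_r)
        span = (frag.end - L, frag.end)
        is_cut = frag.id != self.last_id[frag.chrom]
        segment = self.genome[frag.chrom][span[0]: span[1]]
        seq_core = segment + (self.remainder_r if is_cut else "")
        return self._finish(read_id, mate, frag.chrom, span, "+", seq_core, is_cut)

    def mate_l(self, frag: Fragment, read_id: str, mate: int):
        """Mate on the LEFT end of ``frag``, reading - strand into the cut."""
        subs = self.subfragmap[frag.id]
        L = self._span_len(subs[0].length, self.remainder_l)
        span = (frag.start, frag.start + L)
        is_cut = frag.id != self.first_id[frag.chrom]
        segment = revcomp(self.genome[frag.chrom][span[0]: span[1]])
        seq_core = segment + (self.remainder_l if is_cut else "")
        return self._finish(read_id, mate, frag.chrom, span, "-", seq_core, is_cut)

    def mate_internal(self, frag: Fragment, read_id: str, mate: int):
        sub = max(self.subfragmap.internal_subfragments(frag.id), key=lambda s: s.length)
        L = min(self.profile.read_length, sub.length)
        start = sub.start + int(self.rng.integers(0, sub.length - L + 1))
        span = (start, start + L)
        seq_core = self.genome[frag.chrom][span[0]: span[1]]
        return self._finish(read_id, mate, frag.chrom, span, "+", seq_core, ends_with_site=False)

    def _finish(self, read_id, mate, chrom, span, strand, seq_core, ends_with_site):
        rl = self.profile.read_length
        filler_n = rl - len(seq_core)
        if filler_n > 0:
            raw = seq_core + self._filler(seq_core, filler_n, ends_with_site)
        else:
            raw = seq_core[:rl]
        expected = seq_core[:rl] if ends_with_site else raw
        quals = self._qualities(rl)
        end = ReadEnd(read_id, mate, seq=raw, qualities=quals, chrom=chrom,
                      pos=span[0], strand=strand, mapq=60, span=span)
        return end, expected

    def _filler(self, core: str, n: int, core_ends_with_site: bool) -> str:
        """Random bases after the informative part of a read.

        When the core does not end with the restored recognition site the
        trimming oracle expects the read to pass through untrimmed, so the
        filler must not create an accidental site across the junction.
        """
        site = self.site
        for _ in range(100):
            filler = "".join(self.rng.choice(list("ACGT"), size=n))
            if core_ends_with_site:
                return filler
            if site not in core[-(len(site) - 1):] + filler:
                return filler
        raise RuntimeError("could not draw site-free filler")

    def _qualities(self, n: int) -> list[int]:
        base = self.profile.mean_quality - self.profile.quality_decay * np.arange(n)
        noise = self.rng.normal(0, 2, size=n)
        q = np.clip(np.rint(base + noise), 2, 41).astype(int)
        if self.rng.random() < self.profile.p_lowq_tail:
            tail = int(self.rng.integers(1, 6))
            q[-tail:] = self.rng.integers(2, 9, size=tail)
        return q.tolist()


def emit_reads(
    true_pairs: Sequence[tuple[int, int]],
    genome: ReferenceGenome | SimulatedGenome,
    fragmap: FragmentMap,
    subfragmap: SubfragmentMap,
    profile: ContaminationProfile | None = None,
    seed: int | np.random.Generator = 0,
) -> EmittedReads:
    """Emit contaminated read pairs for the given true fragment pairs.

    Each true pair is re-labeled by one categorical contamination draw; the
    VALID remainder produces junction reads whose mates read outward from the
    ligated first-enzyme cut (so restriction-site trimming reproduces the
    fragment-end prefix exactly — recorded in ``expected_trimmed``).  Aligned
    spans cover only the fragment-end segment, not the restored site overhang
    that crosses the cut.
    """
    if isinstance(genome, SimulatedGenome):
        genome = genome.genome
    profile = profile or ContaminationProfile()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    em = _Emitter(genome, fragmap, subfragmap, profile, rng)

    thresholds = np.cumsum([
        profile.p_self_ligation,
        profile.p_non_digestion,
        profile.p_duplicate,
        profile.p_internal_subfragment,
        profile.p_multimap,
    ])
    labels = [
        PairClass.SELF_LIGATION,
        PairClass.NON_DIGESTION,
        PairClass.IDENTICAL_ENDS,
        PairClass.INTERNAL_SUBFRAGMENT,
        PairClass.NON_UNIQUE,
    ]

    pairs: list[PairRecord] = []
    truth: list[TruthRecord] = []
    expected: dict[tuple[str, int], str] = {}
    valid_history: list[tuple[str, PairRecord]] = []
    valid_truth: dict[str, tuple[int, int]] = {}
    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []

    n_frag = len(fragmap)
    for k, (i, j) in enumerate(true_pairs):
        rid = f"sim{k:07d}"
        draw = rng.random()
        cls = PairClass.VALID
        for t, lab in zip(thresholds, labels):
            if draw < t:
                cls = lab
                break

        if cls is PairClass.IDENTICAL_ENDS and not valid_history:
            cls = PairClass.VALID  # nothing to duplicate yet
        if cls is PairClass.INTERNAL_SUBFRAGMENT and not em.internal_candidates:
            cls = PairClass.VALID  # map has no usable internal subfragment

        dup_of = None
        if cls is PairClass.VALID or cls is PairClass.NON_UNIQUE:
            fi, fj = fragmap[min(i, j)], fragmap[max(i, j)]
            adjacent = fi.chrom == fj.chrom and fj.id - fi.id == 1
            if adjacent:
                (e1, x1), (e2, x2) = em.mate_l(fi, rid, 1), em.mate_r(fj, rid, 2)
            else:
                (e1, x1), (e2, x2) = em.mate_r(fi, rid, 1), em.mate_l(fj, rid, 2)
            if cls is PairClass.NON_UNIQUE:
                victim = 1 if rng.random() < 0.5 else 2
                if victim == 1:
                    e1 = replace(e1, mapq=0)
                else:
                    e2 = replace(e2, mapq=0)
            rec = PairRecord(rid, e1, e2)
            ti, tj = fi.id, fj.id
        elif cls is PairClass.SELF_LIGATION:
            f = fragmap[i]
            (e1, x1), (e2, x2) = em.mate_r(f, rid, 1), em.mate_l(f, rid, 2)
            rec = PairRecord(rid, e1, e2)
            ti = tj = f.id
        elif cls is PairClass.NON_DIGESTION:
            f = fragmap[i]
            if f.id == em.last_id[f.chrom]:
                f = fragmap[f.id - 1]
            g = fragmap[f.id + 1]
            (e1, x1), (e2, x2) = em.mate_r(f, rid, 1), em.mate_l(g, rid, 2)
            rec = PairRecord(rid, e1, e2)
            ti, tj = f.id, g.id
        elif cls is PairClass.INTERNAL_SUBFRAGMENT:
            f = fragmap[em.internal_candidates[int(rng.integers(len(em.internal_candidates)))]]
            other = fragmap[j if j != f.id else i]
            (e1, x1) = em.mate_internal(f, rid, 1)
            (e2, x2) = (em.mate_l if other.id > f.id else em.mate_r)(other, rid, 2)
            rec = PairRecord(rid, e1, e2)
            ti, tj = f.id, other.id
        else:  # duplicate of a previously emitted valid pair
            src_id, src = valid_history[int(rng.integers(len(valid_history)))]
            e1 = replace(src.end1, read_id=rid)
            e2 = replace(src.end2, read_id=rid)
            x1, x2 = expected[(src_id, 1)], expected[(src_id, 2)]
            rec = PairRecord(rid, e1, e2)
            dup_of = src_id
            ti, tj = valid_truth[src_id]

        pairs.append(rec)
        truth.append(TruthRecord(rid, cls, ti, tj, dup_of))
        expected[(rid, 1)] = x1
        expected[(rid, 2)] = x2
        reads1.append(FastqRead(rid, 1, rec.end1.seq, list(rec.end1.qualities)))
        reads2.append(FastqRead(rid, 2, rec.end2.seq, list(rec.end2.qualities)))
        if cls is PairClass.VALID:
            valid_history.append((rid, rec))
            valid_truth[rid] = (ti, tj)

    return EmittedReads(pairs, reads1, reads2, truth, expected)
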