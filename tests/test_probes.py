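"""Capture-probe design: Tm model, uniqueness screen, design rules."""

import math
import random

import pytest

from t2c.digestion import ReferenceGenome, digest, double_digest, get_enzyme, revcomp
from t2c.probes import (
    DesignParams,
    design_probes,
    is_unique,
    melting_temperature,
    replicate_probes,
)
from t2c.simulate import simulate_genome

# ---------------------------------------------------------------------------
# Independent nearest-neighbor oracle: unified dimer parameters
# (dH kcal/mol, dS cal/mol/K), terminal initiation terms, and the
# monovalent-salt entropy correction 0.368*(N-1)*ln[Na+].

_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def _tm_oracle(seq, na_molar=0.05, dnac1=250e-9, dnac2=250e-9):
    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh, ds = dh + 2.3, ds + 4.1
        else:
            dh, ds = dh + 0.1, ds - 2.8
    for i in range(len(seq) - 1):
        dimer = seq[i : i + 2]
        h, s = _NN[dimer] if dimer in _NN else _NN[revcomp(dimer)]
        dh, ds = dh + h, ds + s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    k = dnac1 - dnac2 / 2
    return 1000 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestMeltingTemperature:
    def test_matches_independent_nn_oracle(self):
        rng = random.Random(42)
        for _ in range(60):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 90)))
            assert melting_temperature(seq) == pytest.approx(_tm_oracle(seq), abs=0.5)

    def test_reverse_complement_symmetry(self):
        rng = random.Random(1)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(30))
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(revcomp(seq)), abs=1e-9
            )

    def test_gc_monotonicity(self):
        assert melting_temperature("GC" * 15) > melting_temperature("AT" * 15)

    def test_rejects_n_and_short(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACGTN")
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")


class TestUniqueness:
    def _count_bruteforce(self, genome, kmer):
        total = 0
        for seq in genome.sequences.values():
            for strand_seq in (kmer, revcomp(kmer)):
                if strand_seq == kmer or kmer != revcomp(kmer):
                    start = 0
                    while True:
                        i = seq.find(strand_seq, start)
                        if i == -1:
                            break
                        total += 1
                        start = i + 1
                if kmer == revcomp(kmer):
                    break
        return total

    def test_random_probe_unique(self):
        rng = random.Random(7)
        seq = "".join(rng.choice("ACGT") for _ in range(5000))
        g = ReferenceGenome({"c": seq})
        probe = seq[1000:1062]
        assert self._count_bruteforce(g, probe) == 1
        assert is_unique(probe, g)

    def test_planted_duplication_breaks_uniqueness(self):
        rng = random.Random(8)
        core = "".join(rng.choice("ACGT") for _ in range(3000))
        dup = core[500:700]
        g = ReferenceGenome({"c": core + dup})
        probe = core[520:590]
        assert self._count_bruteforce(g, probe) >= 2
        assert not is_unique(probe, g)

    def test_palindrome_counts_single_occurrence(self):
        pal = "GGGAATTCCC"
        assert pal == revcomp(pal)
        g = ReferenceGenome({"c": "ACTGACTGAC" + pal + "TTCTTCTTCT"})
        assert is_unique(pal, g)

    def test_seed_windows_all_checked(self):
        # a 10-mer seed repeated elsewhere fails even if the full probe is unique
        rng = random.Random(9)
        core = "".join(rng.choice("ACGT") for _ in range(2000))
        seed = core[100:110]
        g = ReferenceGenome({"c": core + "CCCCC" + seed})
        assert not is_unique(core[95:160], g, seed_len=10)


@pytest.fixture(scope="module")
def designed():
    sim = simulate_genome(length=120_000, target_frag_len=3_000, seed=5)
    genome = sim.genome
    chrom = next(iter(genome.sequences))
    fragmap = digest(genome, get_enzyme("HindIII"), [(chrom, 0, genome.lengths[chrom])])
    subfragmap = double_digest(fragmap, get_enzyme("NlaIII"), genome)
    params = DesignParams(seed_len=30)
    return genome, fragmap, subfragmap, design_probes(genome, fragmap, subfragmap, params)


class TestDesign:
    def test_probe_geometry(self, designed):
        genome, fragmap, subfragmap, ps = designed
        assert len(ps) > 0
        for p in ps.probes:
            frag = fragmap[p.fragment_id]
            assert frag.start <= p.start < p.stop <= frag.end
            if not p.trimmed:
                assert 62 <= p.length <= 90
            else:
                assert p.length >= ps.params.min_probe_len
            # abuts the cut (within the bounded slide)
            if p.end == "LEFT":
                assert p.start - frag.start <= ps.params.slide_max
            else:
                assert frag.end - p.stop <= ps.params.slide_max

    def test_probe_does_not_cross_second_site(self, designed):
        genome, fragmap, subfragmap, ps = designed
        for p in ps.probes:
            subs = subfragmap[p.fragment_id]
            boundary = subs[0].end if p.end == "LEFT" else subs[-1].start
            if p.end == "LEFT":
                assert p.stop <= boundary or len(subs) == 1
            else:
                assert p.start >= boundary or len(subs) == 1

    def test_tm_choice_is_optimal_over_lengths(self, designed):
        """Exhaustive length-scan oracle: chosen length minimizes |Tm-target|."""
        genome, fragmap, subfragmap, ps = designed
        target = ps.params.tm_target
        for p in [q for q in ps.probes if not p_is_slid(q, fragmap)][:20]:
            if p.trimmed:
                continue
            frag = fragmap[p.fragment_id]
            subs = subfragmap[p.fragment_id]
            avail = subs[0].length if p.end == "LEFT" else subs[-1].length
            best = None
            for L in range(62, min(90, avail) + 1):
                if p.end == "LEFT":
                    seq = genome[p.chrom][frag.start : frag.start + L]
                else:
                    seq = revcomp(genome[p.chrom][frag.end - L : frag.end])
                dev = abs(melting_temperature(seq) - target)
                if best is None or dev < best:
                    best = dev
            assert abs(p.tm - target) == pytest.approx(best, abs=1e-9)

    def test_trimming_at_short_end(self):
        # fragment end with 45 bp to the second site -> trimmed probe
        rng = random.Random(3)
        flank = lambda n: "".join(rng.choice("ACT") for _ in range(n))  # site-free
        seq = flank(200) + "AAGCTT" + "G" * 36 + "CATG" + flank(200)
        g = ReferenceGenome({"c": seq})
        fm = digest(g, get_enzyme("HindIII"), [("c", 0, len(seq))])
        sm = double_digest(fm, get_enzyme("NlaIII"), g)
        ps = design_probes(g, fm, sm, DesignParams(min_probe_len=30, tm_window=50.0))
        trimmed = [p for p in ps.probes if p.fragment_id == 1 and p.end == "LEFT"]
        assert trimmed and trimmed[0].trimmed and trimmed[0].length <= 45

    def test_repeat_end_is_uncapturable(self):
        sim = simulate_genome(length=120_000, target_frag_len=3_000, seed=5,
                              plant_duplicate=True)
        genome = sim.genome
        chrom, src_start, src_end, _, dst = sim.duplicated_segment
        fragmap = digest(genome, get_enzyme("HindIII"), [(chrom, 0, genome.lengths[chrom])])
        subfragmap = double_digest(fragmap, get_enzyme("NlaIII"), genome)
        ps = design_probes(genome, fragmap, subfragmap, DesignParams(seed_len=30))
        # every probe must still be unique despite the planted duplication
        for p in ps.probes:
            assert is_unique(p.sequence, genome, 30)

    def test_tm_spread_bounded(self, designed):
        *_, ps = designed
        tms = [p.tm for p in ps.probes]
        assert max(tms) - min(tms) <= 2 * ps.params.tm_window

    def test_determinism(self, designed):
        genome, fragmap, subfragmap, ps = designed
        again = design_probes(genome, fragmap, subfragmap, DesignParams(seed_len=30))
        assert [(p.probe_id, p.start, p.stop, p.sequence, p.tm) for p in again.probes] == [
            (p.probe_id, p.start, p.stop, p.sequence, p.tm) for p in ps.probes
        ]

    def test_at_most_two_probes_per_fragment(self, designed):
        *_, ps = designed
        per_frag = {}
        for p in ps.probes:
            per_frag.setdefault(p.fragment_id, set()).add(p.end)
        assert all(len(ends) <= 2 for ends in per_frag.values())


def p_is_slid(p, fragmap):
    frag = fragmap[p.fragment_id]
    return (p.start != frag.start) if p.end == "LEFT" else (p.stop != frag.end)


class TestReplication:
    @pytest.mark.parametrize(
        "count,capacity,expected",
        [(800, 2_100_000, 2_625), (1, 7, 7), (525, 2_100_000, 4_000)],
    )
    def test_spots_per_probe(self, count, capacity, expected):
        assert replicate_probes(count, capacity) == expected

    def test_zero_probes_rejected(self):
        with pytest.raises(ValueError):
            replicate_probes(0, 100)
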