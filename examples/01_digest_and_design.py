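"""In-silico double digest of a small genome and capture-probe design.

Builds a simulated 300 kb chromosome, digests it with HindIII (fragments)
and NlaIII (subfragments), then designs 62-90 nt capture oligos at every
in-region fragment end.  Printed: fragment count and median resolution (the
map's effective resolution in bp), probe count with Tm statistics, and how
often each probe would be spotted on a 2.1M-feature array.
"""

from t2c import (
    DesignParams,
    design_probes,
    digest,
    double_digest,
    get_enzyme,
    median_resolution,
    replicate_probes,
)
from t2c.simulate import simulate_genome

sim = simulate_genome(length=300_000, target_frag_len=3_000, seed=1)
genome = sim.genome
chrom = next(iter(genome.sequences))

fragmap = digest(genome, get_enzyme("HindIII"), [(chrom, 0, genome.lengths[chrom])])
subfragmap = double_digest(fragmap, get_enzyme("NlaIII"), genome)
print(f"fragments: {len(fragmap)}  median resolution: {median_resolution(fragmap):.0f} bp")

probeset = design_probes(genome, fragmap, subfragmap, DesignParams(seed_len=30))
tms = [p.tm for p in probeset.probes]
print(
    f"probes: {len(probeset)}  (trimmed: {sum(p.trimmed for p in probeset.probes)}, "
    f"uncapturable ends: {len(probeset.uncapturable)})"
)
print(f"Tm target {probeset.params.tm_target:.1f} C, spread {max(tms) - min(tms):.1f} C")
print(f"spots per probe on a 2.1M array: {replicate_probes(probeset, 2_100_000)}")
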