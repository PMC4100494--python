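"""End-to-end pipeline: config, stage orchestration, run manifest.

One YAML config drives digest → probe design → classification → matrix →
binning → normalization → summary (→ ChIP-seq intersection when peaks are
given).  Inputs are either real files (FASTA + aligned pairs) or a
``simulate:`` block; every stage logs its read-count delta, and the manifest
records per-output checksums so a rerun with the same config and seed is
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .contacts import (
    IN_REGION,
    REGION_VS_GENOME,
    bin_matrix,
    build_contact_matrix,
    capture_efficiency,
    normalize_capture,
    summarize,
)
from .digestion import (
    ReferenceGenome,
    digest,
    double_digest,
    get_enzyme,
    parse_region,
)
from .factors import ANY, annotate_fragments, filter_interactions_by_factor, read_peaks
from .probes import DesignParams, design_probes
from .readproc import (
    FilterParams,
    PairClass,
    pairs_from_sam,
    pairs_from_tsv,
    process_pairs,
    write_tally,
    write_valid_pairs,
)
from .simulate import ContactModel, ContaminationProfile, emit_reads, sample_contacts, simulate_genome

logger = logging.getLogger("t2c")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    out_dir: str
    enzyme1: str = "HindIII"
    enzyme2: str = "NlaIII"
    genome_fasta: Optional[str] = None
    pairs: Optional[str] = None          # aligned pairs (TSV or SAM/BAM)
    regions: list = field(default_factory=list)
    seed: int = 0
    bin_size: int = 40_000
    probe: dict = field(default_factory=dict)       # DesignParams overrides
    filters: dict = field(default_factory=dict)     # FilterParams overrides
    peaks: list = field(default_factory=list)       # [{path, factor, min_height}]
    simulate: Optional[dict] = None      # generator settings when no real input
    enzymes: dict = field(default_factory=dict)     # custom site/offset defs

    def validate(self) -> None:
        if self.simulate is None:
            if not self.genome_fasta or not self.pairs:
                raise ValueError("config needs genome_fasta+pairs or a simulate block")
            for p in (self.genome_fasta, self.pairs):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        for peak in self.peaks:
            if not Path(peak["path"]).exists():
                raise FileNotFoundError(peak["path"])

    def enzyme(self, which: int):
        name = self.enzyme1 if which == 1 else self.enzyme2
        if name in self.enzymes:
            d = self.enzymes[name]
            return get_enzyme(name, d["site"], d["offset"])
        return get_enzyme(name)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: dict
    tallies: dict
    summary: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def record(stage: str, *paths: Path):
        stages[stage] = {"outputs": {str(p): _sha256(p) for p in paths}}
        logger.info("stage %s done: %s", stage, [str(p) for p in paths])

    enz1, enz2 = config.enzyme(1), config.enzyme(2)

    # --- input: real files or simulation -----------------------------------
    truth = None
    if config.simulate is not None:
        sim_cfg = dict(config.simulate)
        model = ContactModel(**sim_cfg.pop("model", {}))
        profile = ContaminationProfile(**sim_cfg.pop("contamination", {}))
        n_pairs = sim_cfg.pop("n_pairs", 20_000)
        sim = simulate_genome(enzyme1=enz1, enzyme2=enz2, seed=config.seed, **sim_cfg)
        genome = sim.genome
        regions = config.regions or [
            (chrom, 0, length) for chrom, length in genome.lengths.items()
        ]
        fragmap = digest(genome, enz1, regions)
        subfragmap = double_digest(fragmap, enz2, genome)
        true_pairs = sample_contacts(fragmap, model, n_pairs, seed=config.seed + 1)
        emitted = emit_reads(true_pairs, genome, fragmap, subfragmap, profile,
                             seed=config.seed + 2)
        pair_stream = emitted.pairs
        truth = emitted
        fasta = out / "genome.fa"
        genome.to_fasta(fasta)
        truth_tsv = out / "truth.tsv"
        emitted.truth_to_tsv(truth_tsv)
        record("simulate", fasta, truth_tsv)
    else:
        genome = ReferenceGenome.from_fasta(config.genome_fasta)
        regions = config.regions
        fragmap = digest(genome, enz1, regions)
        subfragmap = double_digest(fragmap, enz2, genome)
        if config.pairs.endswith((".sam", ".bam")):
            pair_stream = list(pairs_from_sam(config.pairs))
        else:
            pair_stream = list(pairs_from_tsv(config.pairs))

    frag_bed = out / "fragments.bed"
    fragmap.to_bed(frag_bed)
    record("digest", frag_bed)

    probeset = design_probes(genome, fragmap, subfragmap, DesignParams(**config.probe))
    probe_tsv = out / "probes.tsv"
    probeset.to_tsv(probe_tsv)
    record("design", probe_tsv)

    params = FilterParams(**config.filters)
    valid, tally = process_pairs(pair_stream, fragmap, subfragmap, params)
    valid_tsv, tally_tsv = out / "valid_pairs.tsv", out / "class_tally.tsv"
    write_valid_pairs(valid, valid_tsv)
    write_tally(tally, tally_tsv)
    record("classify", valid_tsv, tally_tsv)

    matrix = build_contact_matrix(valid, fragmap, scope=IN_REGION)
    normalized = normalize_capture(matrix)
    matrix_tsv = out / "matrix.tsv"
    matrix.to_tsv(matrix_tsv, normalized=normalized)
    record("matrix+normalize", matrix_tsv)

    binned = bin_matrix(valid, config.bin_size)
    binned_tsv = out / f"binned_{config.bin_size}.tsv"
    binned.to_tsv(binned_tsv)
    record("bin", binned_tsv)

    raw_pairs = len(pair_stream)
    mapped = raw_pairs - tally[PairClass.UNMAPPED]
    mapped_pair_frags = [
        (r.frag1, r.frag2) for r in pair_stream
        if r.end1.is_mapped and r.end2.is_mapped
    ]
    region_vs_genome = sum(
        1 for i, j in mapped_pair_frags
        if (isinstance(i, int) and fragmap[i].in_region)
        or (isinstance(j, int) and fragmap[j].in_region)
    )
    unique_filtered = len(valid)
    unique_filtered_rvg = sum(
        1 for r in valid if fragmap[r.frag1].in_region or fragmap[r.frag2].in_region
    )
    summary = summarize(
        tally, matrix, fragmap,
        raw_pairs=raw_pairs,
        mapped_pairs=mapped,
        region_vs_genome_pairs=region_vs_genome,
        unique_filtered_pairs=unique_filtered,
        unique_filtered_region_vs_genome=unique_filtered_rvg,
    )
    if probeset.probes:
        summary_extra = {
            "capture_efficiency": round(
                capture_efficiency(mapped_pair_frags, probeset.fragment_ids, fragmap), 4
            )
        }
    else:
        summary_extra = {}
    summary_tsv = out / "summary.tsv"
    summary.to_tsv(summary_tsv)
    record("summarize", summary_tsv)

    if config.peaks:
        for peak_cfg in config.peaks:
            peaks = read_peaks(peak_cfg["path"], peak_cfg["factor"],
                               height_col=peak_cfg.get("height_col", 4))
            ann = annotate_fragments(fragmap, peaks, peak_cfg.get("min_height", 20))
            subset = filter_interactions_by_factor(matrix, ann, peak_cfg.get("mode", ANY))
            sub_tsv = out / f"intersect_{peak_cfg['factor']}.tsv"
            subset.to_tsv(sub_tsv)
            record(f"intersect:{peak_cfg['factor']}", sub_tsv)
    else:
        logger.info("no peaks configured; intersect stage skipped")

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        version=__version__,
        config_hash=cfg_hash,
        stages=stages,
        tallies={c.value: n for c, n in tally.items()},
        summary={**summary.__dict__, **summary_extra},
    )
    manifest.to_json(out / "manifest.json")
    return manifest
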