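"""End-to-end orchestration: synthetic demo generation and the staged pipeline.

Stages: demultiplex -> trim/classify -> map -> filter -> end calling, and
independently ChIP track building -> chromatin-state classification and
qPCR/reporter quantitation. A run directory receives every stage's TSV
outputs plus a machine-readable run manifest (package version, parameters,
input checksums); rerunning with an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import chipsig, endcall, mapper, presets, raceio, simulate

HEADER_NOTE = "# coordinates: 1-based inclusive genomic; TSS-relative uses the +1 convention (no 0)\n"


# ---------------------------------------------------------------------------
# Read processing (demux -> trim -> classify -> filter)
# ---------------------------------------------------------------------------

DEFAULT_RACE_PARAMS = {
    "max_mismatch": 1,
    "min_overlap": 5,
    "max_error_rate": 0.1,
    "min_run": 5,
    "max_interruptions": 0,
    "min_primer_overlap": 12,
    "min_length": 20,
    "k": 11,
    "band": 32,
    "min_identity": 0.85,
    "min_aligned_fraction": 0.5,
    "profile_min_aligned_fraction": 0.9,
}

TAIL_BASE = {raceio.FIVE_PRIME: "C", raceio.THREE_PRIME: "A"}


def process_reads(
    reads,
    manifest: raceio.BarcodeManifest,
    adapter_p1: str = presets.ADAPTER_P1,
    race_adapter: str = presets.RACE_UNIVERSAL_ADAPTER,
    **params,
) -> tuple[dict[str, list[raceio.RaceProduct]], pd.DataFrame]:
    """Demux, trim adapters, classify 5'/3' products and trim homopolymer tails.

    The class-specific tail (poly(C) for 5' products, poly(A) for 3') is
    trimmed after classification so that tail trimming can never remove
    genuine genomic bases from the other product type's measured end.
    Returns per-sample product lists and a summary table of bin counts and
    stage survivorships.
    """
    p = {**DEFAULT_RACE_PARAMS, **params}
    bins, unassigned, demux_summary = raceio.demultiplex(reads, manifest, p["max_mismatch"])
    products: dict[str, list[raceio.RaceProduct]] = {}
    stage_rows = []
    for sample, sample_reads in bins.items():
        row = manifest.row(sample)
        sample_products = []
        for read in sample_reads:
            bases, removed_p1 = raceio.trim_adapter(
                read.bases, adapter_p1, "left", p["min_overlap"], p["max_error_rate"]
            )
            bases, removed_ra = raceio.trim_adapter(
                bases, race_adapter, "right", p["min_overlap"], p["max_error_rate"]
            )
            log = [("adapter_p1", removed_p1), ("race_adapter", removed_ra)]
            klass = raceio.classify_race_product(
                bases, row, p["min_primer_overlap"], p["max_error_rate"]
            )
            if klass in TAIL_BASE:
                bases, removed_tail = raceio.trim_homopolymer_tail(
                    bases, TAIL_BASE[klass], "right", p["min_run"], p["max_interruptions"]
                )
                log.append((f"poly{TAIL_BASE[klass]}_tail", removed_tail))
            sample_products.append(
                raceio.RaceProduct(read.id, sample, klass, bases, log)
            )
        kept, dropped = raceio.length_filter(sample_products, p["min_length"])
        products[sample] = kept
        stage_rows.append(
            {
                "sample": sample,
                "assigned": len(sample_reads),
                "post_filter": len(kept),
                "length_dropped": dropped,
                "five_prime": sum(x.product_class == raceio.FIVE_PRIME for x in kept),
                "three_prime": sum(x.product_class == raceio.THREE_PRIME for x in kept),
                "unclassified": sum(x.product_class == raceio.UNCLASSIFIED for x in kept),
            }
        )
    summary = {
        "stages": pd.DataFrame(stage_rows),
        "demux": demux_summary,
        "n_unassigned": len(unassigned),
    }
    return products, summary


def map_products(
    products: dict[str, list[raceio.RaceProduct]],
    ref_seq: str,
    ref_name: str = "ref",
    target_interval: tuple[int, int] | None = None,
    **params,
):
    """Map every classified product; returns (hits_by_sample, classes, stats)."""
    p = {**DEFAULT_RACE_PARAMS, **params}
    index = mapper.build_kmer_index(ref_seq, p["k"], ref_name)
    hits_by_sample: dict[str, list[mapper.AlignmentHit]] = {}
    classes: dict[str, str] = {}
    stats_rows = []
    for sample, plist in products.items():
        raw_hits = []
        for prod in plist:
            if prod.product_class == raceio.UNCLASSIFIED:
                continue
            classes[prod.read_id] = prod.product_class
            raw_hits.append(
                mapper.map_read(
                    prod.trimmed_bases, index, read_id=prod.read_id, band=p["band"]
                )
            )
        kept, stats = mapper.filter_hits(
            raw_hits, p["min_identity"], p["min_aligned_fraction"], target_interval
        )
        hits_by_sample[sample] = kept
        stats_rows.append({"sample": sample, **stats})
    return hits_by_sample, classes, pd.DataFrame(stats_rows)


def call_ends(
    hits_by_sample: dict[str, list[mapper.AlignmentHit]],
    classes: dict[str, str],
    ref: simulate.ReferenceAssembly,
    **params,
):
    """Per-sample and pooled end profiles plus the pooled consensus transcript."""
    p = {**DEFAULT_RACE_PARAMS, **params}
    locus = ref.locus
    sense = locus.erna_sense_strand
    profiles: dict[tuple[str, str], endcall.EndProfile] = {}
    pooled: dict[str, list[mapper.AlignmentHit]] = {endcall.FIVE_PRIME: [], endcall.THREE_PRIME: []}
    strand_counts = {"sense": 0, "antisense": 0}
    for sample, hits in sorted(hits_by_sample.items()):
        for end_type in (endcall.FIVE_PRIME, endcall.THREE_PRIME):
            class_hits = [h for h in hits if classes.get(h.read_id) == end_type]
            pooled[end_type].extend(class_hits)
            profiles[(sample, end_type)] = endcall.end_frequency_profile(
                class_hits,
                end_type,
                sense,
                sample=sample,
                min_aligned_fraction=p["profile_min_aligned_fraction"],
            )
        strand_counts["sense"] += sum(h.strand == sense for h in hits)
        strand_counts["antisense"] += sum(h.strand != sense for h in hits)
    p5 = endcall.end_frequency_profile(
        pooled[endcall.FIVE_PRIME], endcall.FIVE_PRIME, sense, sample="pooled",
        min_aligned_fraction=p["profile_min_aligned_fraction"],
    )
    p3 = endcall.end_frequency_profile(
        pooled[endcall.THREE_PRIME], endcall.THREE_PRIME, sense, sample="pooled",
        min_aligned_fraction=p["profile_min_aligned_fraction"],
    )
    profiles[("pooled", endcall.FIVE_PRIME)] = p5
    profiles[("pooled", endcall.THREE_PRIME)] = p3
    consensus = (
        endcall.consensus_transcript(
            p5, p3, ref.sequence, locus.tss_position, sense, ref.name
        )
        if p5.total and p3.total
        else None  # single-end runs have no consensus to call
    )
    ratio, infinite = endcall.strand_ratio(strand_counts["sense"], strand_counts["antisense"])
    return profiles, consensus, {"ratio": ratio, "infinite": infinite, **strand_counts}


# ---------------------------------------------------------------------------
# Demo input generation
# ---------------------------------------------------------------------------

def make_demo(seed: int = 0, out_dir: str | Path = "demo", n_reads: int = 4000) -> Path:
    """Write a complete synthetic input set for the pipeline into ``out_dir``.

    Emits the HMLE-like reference FASTA and locus YAML, the 4-sample
    barcode/primer manifest, a pooled barcoded RACE FASTQ with its truth
    table, per-bp ChIP/input coverage bedGraphs with a depth table, a Ct
    table, a reporter table, and a ready-to-run pipeline config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    locus = presets.hmle_like_locus()
    ref = simulate.make_reference(
        presets.REFERENCE_LENGTH, presets.GENOME_GC, locus, seed,
        enhancer_gc=presets.ENHANCER_GC,
    )
    ref.write_fasta(out / "reference.fa")
    simulate.save_config(locus, out / "locus.yaml")
    manifest = presets.make_manifest(ref)
    manifest.to_tsv(out / "manifest.tsv")

    read_cfg = presets.default_read_config(n_reads=n_reads, seed=seed + 1)
    reads, truth = simulate.simulate_race_reads(ref, locus, read_cfg)
    raceio.write_fastq(reads, out / "reads.fastq")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    chip_cfg = presets.default_chip_config(locus, "epithelial", seed=seed + 2)
    coverage = simulate.simulate_chip_coverage(ref, chip_cfg)
    chip_dir = out / "chip"
    chip_dir.mkdir(exist_ok=True)
    meta_rows = []
    for mark, cov in coverage.items():
        path = chip_dir / f"{mark}.bedgraph"
        _write_coverage_bedgraph(cov, ref.name, path)
        depth = chip_cfg.input_depth if mark == "input" else chip_cfg.library_depth
        meta_rows.append({"mark": mark, "bedgraph": str(path), "depth": depth})
    pd.DataFrame(meta_rows).to_csv(out / "chip_meta.tsv", sep="\t", index=False)

    ct_cfg = presets.default_ct_config(seed=seed + 3)
    simulate.simulate_ct_table(ct_cfg).to_csv(out / "ct_table.tsv", sep="\t", index=False)
    make_reporter_table(seed + 4).to_csv(out / "reporter.tsv", sep="\t", index=False)

    config = {
        "seed": seed,
        "reference_fasta": str(out / "reference.fa"),
        "locus_yaml": str(out / "locus.yaml"),
        "race": {
            "reads_fastq": str(out / "reads.fastq"),
            "manifest_tsv": str(out / "manifest.tsv"),
            **DEFAULT_RACE_PARAMS,
        },
        "chip": {"meta_tsv": str(out / "chip_meta.tsv"), "bin_size": 50, "mad_k": 3.0},
        "quant": {
            "ct_table": str(out / "ct_table.tsv"),
            "target": "eRNA",
            "normalizer": "GAPDH",
            "calibrator": "HMLE",
            "reporter_tsv": str(out / "reporter.tsv"),
            "control_construct": "PRO",
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out / "config.yaml"


def _write_coverage_bedgraph(cov: np.ndarray, ref_name: str, path: Path) -> None:
    """Run-length-compressed per-bp coverage as bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="coverage"\n')
        start = 0
        for i in range(1, len(cov) + 1):
            if i == len(cov) or cov[i] != cov[start]:
                fh.write(f"{ref_name}\t{start}\t{i}\t{int(cov[start])}\n")
                start = i


def _read_coverage_bedgraph(path: str | Path, length: int | None = None) -> np.ndarray:
    segments = []
    end_max = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            _, s, e, v = line.split()
            segments.append((int(s), int(e), float(v)))
            end_max = max(end_max, int(e))
    cov = np.zeros(length or end_max)
    for s, e, v in segments:
        cov[s:e] = v
    return cov


def make_reporter_table(seed: int, n_replicates: int = 3) -> pd.DataFrame:
    """Dual-luciferase readings for the promoter/enhancer construct series.

    Design folds over the minimal promoter: LOCUS ~27x, PRO&ENH ~20x,
    ENH ~20x; multiplicative lognormal noise on firefly, renilla around a
    common transfection level.
    """
    rng = np.random.default_rng(seed)
    folds = {"PRO": 1.0, "LOCUS": 27.0, "PRO&ENH": 20.0, "ENH": 20.0}
    rows = []
    for construct, fold in folds.items():
        for rep in range(1, n_replicates + 1):
            renilla = rng.lognormal(np.log(5000.0), 0.1)
            firefly = fold * 0.2 * renilla * rng.lognormal(0.0, 0.1)
            rows.append(
                {
                    "sample": "HMLE",
                    "construct": construct,
                    "replicate": rep,
                    "firefly": round(firefly, 3),
                    "renilla": round(renilla, 3),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config-driven run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated pipeline configuration (paths + per-stage parameters)."""

    seed: int = 0
    reference_fasta: str = ""
    locus_yaml: str = ""
    race: dict = field(default_factory=dict)
    chip: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.reference_fasta, self.locus_yaml]
        for section, keys in ((self.race, ("reads_fastq", "manifest_tsv")),
                              (self.chip, ("meta_tsv",)),
                              (self.quant, ("ct_table", "reporter_tsv"))):
            for key in keys:
                if section.get(key):
                    paths.append(section[key])
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")
        if not self.reference_fasta or not self.locus_yaml:
            raise ValueError("reference_fasta and locus_yaml are required")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reference(config: PipelineConfig) -> simulate.ReferenceAssembly:
    from Bio import SeqIO

    record = next(SeqIO.parse(config.reference_fasta, "fasta"))
    locus = simulate.load_config(config.locus_yaml)
    return simulate.ReferenceAssembly(record.id, str(record.seq).upper(), locus)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER_NOTE)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> dict:
    """Execute every configured stage; write outputs and a run manifest.

    Returns a dict of in-memory results (consensus call, state call,
    expression tables, stats). Any stage failure raises with the failing
    stage named; outputs of completed stages remain on disk.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    inputs: dict[str, str] = {}
    ref = _load_reference(config)
    inputs[config.reference_fasta] = _sha256(config.reference_fasta)
    inputs[config.locus_yaml] = _sha256(config.locus_yaml)

    stage = "race"
    try:
        if config.race.get("reads_fastq"):
            results["race"] = _run_race_stage(config, ref, out, inputs)
        stage = "chip"
        if config.chip.get("meta_tsv"):
            results["chip"] = _run_chip_stage(config, ref, out, inputs)
        stage = "quant"
        if config.quant.get("ct_table") or config.quant.get("reporter_tsv"):
            results["quant"] = _run_quant_stage(config, out, inputs)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    manifest = {
        "package": "enhancerscope",
        "version": __version__,
        "seed": config.seed,
        "parameters": {"race": config.race, "chip": config.chip, "quant": config.quant},
        "input_checksums": inputs,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results


def _run_race_stage(config: PipelineConfig, ref, out: Path, inputs: dict) -> dict:
    p = {**DEFAULT_RACE_PARAMS, **{k: v for k, v in config.race.items()
                                   if k in DEFAULT_RACE_PARAMS}}
    inputs[config.race["reads_fastq"]] = _sha256(config.race["reads_fastq"])
    inputs[config.race["manifest_tsv"]] = _sha256(config.race["manifest_tsv"])
    manifest = raceio.BarcodeManifest.from_tsv(config.race["manifest_tsv"])
    reads = raceio.read_fastq(config.race["reads_fastq"])
    products, summary = process_reads(reads, manifest, **p)
    _write_tsv(summary["demux"], out / "demux_summary.tsv")
    _write_tsv(summary["stages"], out / "race_summary.tsv")
    for sample, plist in products.items():
        for klass in (raceio.FIVE_PRIME, raceio.THREE_PRIME):
            sel = [x for x in plist if x.product_class == klass]
            raceio.write_fastq(
                (raceio.SequencingRead(x.read_id, x.trimmed_bases, "?" * len(x.trimmed_bases))
                 for x in sel),
                out / f"{sample}.{klass}.fastq",
            )
    target = ref.locus.genomic_interval(ref.locus.enhancer_interval)
    hits_by_sample, classes, map_stats = map_products(
        products, ref.sequence, ref.name, target_interval=target, **p
    )
    all_hits = [h for hits in hits_by_sample.values() for h in hits]
    _write_tsv(mapper.hits_to_frame(all_hits), out / "hits.tsv")
    mapper.hits_to_bed(all_hits, out / "hits.bed")
    _write_tsv(map_stats, out / "mapping_stats.tsv")
    profiles, consensus, strand = call_ends(hits_by_sample, classes, ref, **p)
    frames = [
        prof.to_frame(ref.locus.tss_position, ref.locus.strand)
        for prof in profiles.values()
        if prof.total
    ]
    _write_tsv(pd.concat(frames, ignore_index=True), out / "end_profiles.tsv")
    _write_tsv(pd.DataFrame([consensus.__dict__]), out / "consensus.tsv")
    with open(out / "consensus.bed", "w") as fh:
        fh.write(
            f"{consensus.ref_name}\t{consensus.start - 1}\t{consensus.end}\t"
            f"consensus_transcript\t0\t{consensus.strand}\n"
        )
    _write_tsv(pd.DataFrame([strand]), out / "strand_ratio.tsv")
    return {"profiles": profiles, "consensus": consensus, "strand": strand,
            "summary": summary, "map_stats": map_stats}


def _run_chip_stage(config: PipelineConfig, ref, out: Path, inputs: dict) -> dict:
    meta = pd.read_csv(config.chip["meta_tsv"], sep="\t")
    inputs[config.chip["meta_tsv"]] = _sha256(config.chip["meta_tsv"])
    bin_size = int(config.chip.get("bin_size", 50))
    mad_k = float(config.chip.get("mad_k", 3.0))
    length = len(ref.sequence)
    coverage = {}
    depths = {}
    for row in meta.itertuples(index=False):
        coverage[row.mark] = _read_coverage_bedgraph(row.bedgraph, length)
        depths[row.mark] = float(row.depth)
        inputs[row.bedgraph] = _sha256(row.bedgraph)
    if "input" not in coverage:
        raise ValueError("chip meta table must contain an 'input' row")
    tracks = {}
    for mark in sorted(coverage):
        if mark == "input":
            continue
        track = chipsig.normalize_and_subtract(
            coverage[mark], depths[mark], coverage["input"], depths["input"],
            bin_size=bin_size, origin=1, mark=mark, ref_name=ref.name,
        )
        tracks[mark] = track
        track.clamp_nonnegative().to_bedgraph(out / f"track_{mark}.bedgraph")
    interval = ref.locus.genomic_interval(ref.locus.enhancer_interval)
    call = chipsig.classify_enhancer_state(tracks, interval, mad_k=mad_k)
    rows = [
        {"interval_start": interval[0], "interval_end": interval[1], "state": call.state,
         "mark": mark, **ev}
        for mark, ev in sorted(call.evidence.items())
    ]
    _write_tsv(pd.DataFrame(rows), out / "state_call.tsv")
    return {"tracks": tracks, "state_call": call}


def _run_quant_stage(config: PipelineConfig, out: Path, inputs: dict) -> dict:
    from . import quant

    results = {}
    if config.quant.get("ct_table"):
        inputs[config.quant["ct_table"]] = _sha256(config.quant["ct_table"])
        table = quant.read_ct_table(config.quant["ct_table"])
        rel = quant.comparative_quantitation(
            table,
            config.quant["target"],
            config.quant["normalizer"],
            config.quant["calibrator"],
        )
        _write_tsv(rel, out / "relative_expression.tsv")
        results["relative_expression"] = rel
    if config.quant.get("reporter_tsv"):
        inputs[config.quant["reporter_tsv"]] = _sha256(config.quant["reporter_tsv"])
        readings = pd.read_csv(config.quant["reporter_tsv"], sep="\t", comment="#")
        folds = quant.luciferase_normalize(readings, config.quant["control_construct"])
        _write_tsv(folds, out / "reporter_folds.tsv")
        results["reporter_folds"] = folds
    return results
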