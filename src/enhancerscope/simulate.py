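"""Seedable generators for every input the pipeline consumes.

Emulated data: a mini-genome carrying a pri-miR TSS and an upstream
enhancer; barcoded pooled 5'/3' RACE reads with heterogeneous end
positions, homopolymer tails, adapters, substitution errors and off-target
reads; ChIP fragment coverage with mark-specific enrichment over promoter,
enhancer and background; and qPCR Ct tables following a log-linear
standard-curve model with Gaussian noise. Every generator is a pure
function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import reverse_complement

from .locus import LocusModel
from .raceio import SequencingRead

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    """Configuration for the pooled RACE-seq read simulator.

    Reads are laid out as barcode + library adapter + insert + homopolymer
    tail + RACE universal adapter. ``five_prime_fraction`` sets the expected
    share of 5' products among on-target reads (5' and 3' RACE products are
    pooled in equal amounts by default).
    """

    n_reads: int = 10_000
    barcode_table: dict[str, str] = field(default_factory=dict)
    adapter_p1: str = "CCTCTCTATGGGCAGTCGGTGAT"
    race_universal_adapter: str = "GGCCACGCGTCGACTAGTAC"
    tail_length_range: tuple[int, int] = (8, 16)
    substitution_error_rate: float = 0.0
    off_target_fraction: float = 0.0
    five_prime_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not self.barcode_table:
            raise ValueError("barcode_table must not be empty")
        lo, hi = self.tail_length_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid tail_length_range {self.tail_length_range}")
        for name in ("substitution_error_rate", "off_target_fraction", "five_prime_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def check_barcode_separation(self, max_mismatch: int) -> None:
        """Require pairwise barcode Hamming distance > 2 * max_mismatch."""
        barcodes = list(self.barcode_table.values())
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                d = sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))
                if d <= 2 * max_mismatch:
                    raise ValueError(
                        f"barcodes {a}/{b} differ at {d} positions; "
                        f"need > {2 * max_mismatch} for max_mismatch={max_mismatch}"
                    )


@dataclass
class ChipSimConfig:
    """Fragment-sampling model for ChIP and input coverage.

    ``profiles`` maps mark -> {(start, end): fold_enrichment} with genomic
    1-based inclusive intervals; fragment midpoints are sampled with weight
    background (1) + enrichment. Sonication fragment lengths are Gaussian
    around ``fragment_length_mean`` (the bench target was ~500 bp).
    """

    profiles: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)
    library_depth: int = 100_000
    fragment_length_mean: float = 500.0
    fragment_length_sd: float = 50.0
    input_depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_depth < 0 or self.input_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.fragment_length_mean <= 0:
            raise ValueError("fragment_length_mean must be > 0")
        for mark, profile in self.profiles.items():
            for (s, e), fold in profile.items():
                if fold < 0:
                    raise ValueError(f"{mark} interval ({s},{e}): enrichment must be >= 0")
                if s > e or s < 1:
                    raise ValueError(f"{mark}: invalid interval ({s},{e})")


@dataclass
class CtSimConfig:
    """Log-linear qPCR model: Ct = intercept + slope*log10(quantity) + noise."""

    slope: float = -3.3219
    intercept: float = 30.0
    noise_sd: float = 0.0
    design: dict[str, dict[str, float]] = field(default_factory=dict)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for sample, genes in self.design.items():
            for gene, q in genes.items():
                if q <= 0:
                    raise ValueError(f"design[{sample}][{gene}] = {q}: quantities must be > 0")


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

@dataclass
class ReferenceAssembly:
    """A generated mini-genome with its locus annotation."""

    name: str
    sequence: str
    locus: LocusModel

    @property
    def annotation(self) -> dict:
        return {
            "reference_name": self.name,
            "length": len(self.sequence),
            "tss_position": self.locus.tss_position,
            "strand": self.locus.strand,
            "enhancer_interval": list(self.locus.genomic_interval(self.locus.enhancer_interval)),
            "consensus_interval": list(self.locus.consensus_interval())
            if self.locus.erna_five_prime_dist and self.locus.erna_three_prime_dist
            else None,
        }

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i : i + width] + "\n")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def make_reference(
    length: int,
    gc_fraction: float,
    locus: LocusModel,
    seed: int,
    enhancer_gc: float = 0.63,
    gc_tolerance: float = 0.05,
) -> ReferenceAssembly:
    """Generate an uppercase A/C/G/T mini-genome hosting the locus.

    Bases are i.i.d. with expected GC ``gc_fraction``, except over the eRNA
    consensus interval which is resampled until its realized GC fraction is
    within ``gc_tolerance`` of ``enhancer_gc`` (the transcript is GC-rich).
    The base at every modelled eRNA end position is pinned to C in
    transcript orientation: CpG-island initiators favor a C/G start, and a
    non-A terminal base keeps the in-vitro-polyadenylated 3' end
    identifiable once the poly(A) tail is trimmed (a templated terminal A
    is indistinguishable from the tail). Deterministic given seed.
    """
    if not 0.0 < gc_fraction < 1.0 and gc_fraction not in (0.0, 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    lo, hi = locus.span()
    if lo < 1 or hi > length:
        raise ValueError(
            f"locus span [{lo}, {hi}] outside reference [1, {length}]"
        )
    rng = np.random.default_rng(seed)
    bases = _random_bases(rng, length, gc_fraction)
    if locus.erna_five_prime_dist and locus.erna_three_prime_dist:
        c_lo, c_hi = locus.consensus_interval()
        n = c_hi - c_lo + 1
        for _ in range(1000):
            segment = _random_bases(rng, n, enhancer_gc)
            realized = np.isin(segment, ["G", "C"]).mean()
            if abs(realized - enhancer_gc) <= gc_tolerance:
                break
        else:  # pragma: no cover - p(failure) vanishes for any sane tolerance
            raise RuntimeError("could not hit enhancer GC target")
        bases[c_lo - 1 : c_hi] = segment
        end_base = "C" if locus.erna_sense_strand == "+" else "G"
        for dist in (locus.erna_five_prime_dist, locus.erna_three_prime_dist):
            for rel in dist:
                bases[locus.genomic(rel) - 1] = end_base
    return ReferenceAssembly(locus.reference_name, "".join(bases), locus)


# ---------------------------------------------------------------------------
# RACE reads
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, dist: dict[int, float]) -> int:
    positions = sorted(dist)
    probs = np.array([dist[p] for p in positions])
    return int(rng.choice(positions, p=probs / probs.sum()))


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        lookup = {b: i for i, b in enumerate("ACGT")}
        idx = np.array([lookup.get(b, 0) for b in arr[hit]])
        arr[hit] = _BASES[(idx + shifts) % 4]
    return "".join(arr)


def simulate_race_reads(
    ref: ReferenceAssembly | str,
    locus: LocusModel | None = None,
    cfg: ReadSimConfig | None = None,
) -> tuple[list[SequencingRead], pd.DataFrame]:
    """Simulate a pooled, barcoded 5'/3' RACE-seq library with its truth table.

    Each on-target read is barcode + adapter_p1 + insert + tail +
    race_universal_adapter. A 5' product's insert runs from a start drawn
    from the locus 5'-end distribution to the fixed 5'-GSP site (poly(C)
    tail); a 3' product's insert runs from the fixed 3'-GSP site to an end
    drawn from the 3'-end distribution (poly(A) tail from in-vitro
    polyadenylation). Antisense molecules are emitted with probability
    ``locus.antisense_fraction`` as reverse-complemented inserts; off-target
    reads are uniform reference slices without a GSP. Substitution errors
    apply across the whole read. Quality is constant Phred 30.

    The truth table has one row per emitted read: read_id, sample,
    product_class (five_prime / three_prime / off_target), true_end
    (genomic, -1 for off-target) and strand.
    """
    if isinstance(ref, ReferenceAssembly):
        locus = ref.locus if locus is None else locus
        seq = ref.sequence
    else:
        seq = ref
    if locus is None or cfg is None:
        raise ValueError("locus and cfg are required")
    rng = np.random.default_rng(cfg.seed)
    samples = sorted(cfg.barcode_table)
    sense = locus.erna_sense_strand
    g5_end = locus.genomic(locus.gsp_five_site[1])
    g3_start = locus.genomic(locus.gsp_three_site[0])
    tail_lo, tail_hi = cfg.tail_length_range
    reads: list[SequencingRead] = []
    truth: list[dict] = []
    for i in range(cfg.n_reads):
        read_id = f"read{i:07d}"
        sample = samples[int(rng.integers(len(samples)))]
        barcode = cfg.barcode_table[sample]
        tail_len = int(rng.integers(tail_lo, tail_hi + 1))
        if rng.random() < cfg.off_target_fraction:
            length = int(rng.integers(60, 121))
            start = int(rng.integers(1, len(seq) - length + 1))
            insert = seq[start - 1 : start + length - 1]
            tail = ""
            klass, true_end, strand = "off_target", -1, "+"
        else:
            is_five = rng.random() < cfg.five_prime_fraction
            antisense = rng.random() < locus.antisense_fraction
            strand = sense if not antisense else ("-" if sense == "+" else "+")
            if is_five:
                end_rel = _draw(rng, locus.erna_five_prime_dist)
                g = locus.genomic(end_rel)
                iv = (min(g, g5_end), max(g, g5_end))
                tail_base, klass, true_end = "C", "five_prime", g
            else:
                end_rel = _draw(rng, locus.erna_three_prime_dist)
                g = locus.genomic(end_rel)
                iv = (min(g, g3_start), max(g, g3_start))
                tail_base, klass, true_end = "A", "three_prime", g
            insert = seq[iv[0] - 1 : iv[1]]
            if (sense == "-") != antisense:  # molecule reads on the - strand
                insert = reverse_complement(insert)
            tail = tail_base * tail_len
        bases = barcode + cfg.adapter_p1 + insert + tail + cfg.race_universal_adapter
        bases = _substitute(rng, bases, cfg.substitution_error_rate)
        reads.append(SequencingRead(read_id, bases, "?" * len(bases)))
        truth.append(
            {
                "read_id": read_id,
                "sample": sample,
                "product_class": klass,
                "true_end": true_end,
                "strand": strand,
            }
        )
    return reads, pd.DataFrame(truth, columns=["read_id", "sample", "product_class", "true_end", "strand"])


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------

def _sample_coverage(
    rng: np.random.Generator,
    ref_length: int,
    weights: np.ndarray,
    depth: int,
    frag_mean: float,
    frag_sd: float,
) -> np.ndarray:
    """Place ``depth`` fragments with midpoint density ∝ weights; return per-bp coverage."""
    coverage = np.zeros(ref_length, dtype=np.int64)
    if depth == 0:
        return coverage
    p = weights / weights.sum()
    mids = rng.choice(ref_length, size=depth, p=p)  # 0-based midpoints
    lengths = np.maximum(20, rng.normal(frag_mean, frag_sd, size=depth)).astype(np.int64)
    starts = np.clip(mids - lengths // 2, 0, ref_length - 1)
    ends = np.clip(starts + lengths, 1, ref_length)  # half-open
    diff = np.zeros(ref_length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1])


def simulate_chip_coverage(
    ref: ReferenceAssembly | str | int, cfg: ChipSimConfig
) -> dict[str, np.ndarray]:
    """Per-bp fragment coverage for each configured mark plus the input sample.

    Fragment midpoints are drawn with weight 1 (background) plus the
    mark's fold enrichment over its profile intervals; input uses flat
    weights. Total fragments per sample equal the configured depths.
    """
    if isinstance(ref, ReferenceAssembly):
        ref_length = len(ref.sequence)
    elif isinstance(ref, str):
        ref_length = len(ref)
    else:
        ref_length = int(ref)
    if ref_length <= 0:
        raise ValueError("zero-length reference")
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, np.ndarray] = {}
    for mark in sorted(cfg.profiles):
        weights = np.ones(ref_length)
        for (s, e), fold in cfg.profiles[mark].items():
            weights[s - 1 : e] += fold
        out[mark] = _sample_coverage(
            rng, ref_length, weights, cfg.library_depth,
            cfg.fragment_length_mean, cfg.fragment_length_sd,
        )
    out["input"] = _sample_coverage(
        rng, ref_length, np.ones(ref_length), cfg.input_depth,
        cfg.fragment_length_mean, cfg.fragment_length_sd,
    )
    return out


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(cfg: CtSimConfig) -> pd.DataFrame:
    """Ct table (sample, gene, replicate, Ct) from the log-linear standard-curve model."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for sample in sorted(cfg.design):
        for gene in sorted(cfg.design[sample]):
            q = cfg.design[sample][gene]
            base_ct = cfg.intercept + cfg.slope * np.log10(q)
            for rep in range(1, cfg.n_replicates + 1):
                noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep, "Ct": base_ct + noise}
                )
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "Ct"])


# ---------------------------------------------------------------------------
# YAML round-trip for configs
# ---------------------------------------------------------------------------

_CONFIG_TYPES = {
    "ReadSimConfig": ReadSimConfig,
    "ChipSimConfig": ChipSimConfig,
    "CtSimConfig": CtSimConfig,
    "LocusModel": LocusModel,
}


def _to_plain(obj):
    if isinstance(obj, dict):
        return {_key(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _key(k):
    if isinstance(k, tuple):
        return ",".join(str(x) for x in k)
    return k


def _restore_keys(d, tuple_keys: bool, int_keys: bool):
    out = {}
    for k, v in d.items():
        if tuple_keys and isinstance(k, str) and "," in k:
            k = tuple(int(x) for x in k.split(","))
        elif int_keys and isinstance(k, str):
            k = int(k)
        out[k] = v
    return out


def save_config(cfg, path: str | Path) -> None:
    """Serialize any simulator config (or LocusModel) to YAML."""
    payload = {"type": type(cfg).__name__, "fields": _to_plain(dict(cfg.__dict__))}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config(path: str | Path):
    """Load a config written by :func:`save_config`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    cls = _CONFIG_TYPES[payload["type"]]
    fields = payload["fields"]
    if cls is LocusModel:
        for name in ("erna_five_prime_dist", "erna_three_prime_dist"):
            fields[name] = _restore_keys(fields.get(name, {}), False, True)
        for name in ("gsp_five_site", "gsp_three_site", "enhancer_interval"):
            if name in fields:
                fields[name] = tuple(fields[name])
    if cls is ChipSimConfig:
        fields["profiles"] = {
            mark: _restore_keys(prof, True, False)
            for mark, prof in fields.get("profiles", {}).items()
        }
    if cls is ReadSimConfig and "tail_length_range" in fields:
        fields["tail_length_range"] = tuple(fields["tail_length_range"])
    return cls(**fields)
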