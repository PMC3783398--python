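"""Desk-scale local read mapping: k-mer seeding, diagonal clustering, windowed
affine-gap local alignment.

Designed for kilobase-scale references (a simulated locus or a genomic
slice), not whole genomes. Coordinates are 1-based inclusive internally;
BED export converts to 0-based half-open. An import path for externally
produced alignments (BED6 of read placements) lets real data bypass the
built-in aligner entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement

HIT_COLUMNS = [
    "read_id", "ref_name", "ref_start", "ref_end", "strand",
    "score", "identity", "aligned_read_fraction",
]


@dataclass
class KmerIndex:
    """Forward-strand k-mer -> sorted 1-based positions; k-mers with N omitted."""

    k: int
    ref_name: str
    ref_seq: str
    positions: dict[str, list[int]] = field(repr=False, default_factory=dict)


@dataclass
class AlignmentHit:
    read_id: str
    ref_name: str
    ref_start: int  # 1-based inclusive
    ref_end: int
    strand: str
    score: float
    identity: float
    aligned_read_fraction: float

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError("ref_start must be <= ref_end")

    def overlaps(self, start: int, end: int) -> bool:
        return self.ref_start <= end and self.ref_end >= start


def build_kmer_index(ref: str, k: int = 11, ref_name: str = "ref") -> KmerIndex:
    """Index every overlapping k-mer of the forward reference strand."""
    if not 4 <= k <= 32:
        raise ValueError("k must be in [4, 32]")
    if len(ref) < k:
        raise ValueError(f"reference length {len(ref)} shorter than k={k}")
    ref = ref.upper()
    positions: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        kmer = ref[i : i + k]
        if "N" in kmer:
            continue
        positions.setdefault(kmer, []).append(i + 1)
    return KmerIndex(k=k, ref_name=ref_name, ref_seq=ref, positions=positions)


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def _seed_cluster(seq: str, index: KmerIndex) -> tuple[int, int, int] | None:
    """Best co-linear seed cluster for seq: (n_seeds, min_ref, max_ref).

    Seeds sharing (up to a small tolerance) the same alignment diagonal
    ``ref_pos - read_pos`` are clustered; the cluster with the most seeds
    wins, ties to the leftmost reference position for determinism.
    """
    k = index.k
    seeds: list[tuple[int, int]] = []  # (diagonal, ref_pos)
    for i in range(len(seq) - k + 1):
        for p in index.positions.get(seq[i : i + k], ()):
            seeds.append((p - i, p))
    if not seeds:
        return None
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    tol = 16  # diagonal drift allowed within one cluster (indels)
    for d, p in seeds:
        if clusters and d - clusters[-1][-1][0] <= tol:
            clusters[-1].append((d, p))
        else:
            clusters.append([(d, p)])
    best = max(clusters, key=lambda c: (len(c), -min(p for _, p in c)))
    refs = [p for _, p in best]
    return len(best), min(refs), max(refs)


def _window_hit(
    read_id: str,
    seq: str,
    index: KmerIndex,
    strand: str,
    cluster: tuple[int, int, int],
    aligner: Align.PairwiseAligner,
    band: int,
) -> AlignmentHit | None:
    _, ref_lo, ref_hi = cluster
    w_lo = max(0, ref_lo - 1 - len(seq) - band)  # 0-based window bounds
    w_hi = min(len(index.ref_seq), ref_hi + len(seq) + band)
    window = index.ref_seq[w_lo:w_hi]
    try:
        aln = aligner.align(window, seq)[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identities = counts.identities
    ref_segments, read_segments = aln.aligned
    if len(ref_segments) == 0:
        return None
    ref_start = int(ref_segments[0][0]) + w_lo + 1
    ref_end = int(ref_segments[-1][1]) + w_lo
    aligned_read = int(sum(e - s for s, e in read_segments))
    return AlignmentHit(
        read_id=read_id,
        ref_name=index.ref_name,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        score=float(aln.score),
        identity=identities / columns if columns else 0.0,
        aligned_read_fraction=aligned_read / len(seq) if seq else 0.0,
    )


def map_read(
    product: str,
    index: KmerIndex,
    read_id: str = "read",
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    band: int = 32,
) -> AlignmentHit | None:
    """Map one trimmed product; return the best local alignment or None.

    Seeds the read and its reverse complement against the forward index,
    clusters co-linear seeds per strand, and runs an affine-gap local
    alignment over a reference window around the best cluster. The
    higher-scoring strand wins; ties break by higher identity, then lower
    ref_start, then + strand. Unmappable reads (no seed cluster or
    non-positive score) return None.
    """
    seq = product.upper()
    if len(seq) < index.k:
        return None
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    candidates: list[AlignmentHit] = []
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        cluster = _seed_cluster(oriented, index)
        if cluster is None:
            continue
        hit = _window_hit(read_id, oriented, index, strand, cluster, aligner, band)
        if hit is not None:
            candidates.append(hit)
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda h: (h.score, h.identity, -h.ref_start, h.strand == "+"),
    )


def filter_hits(
    hits: list[AlignmentHit | None],
    min_identity: float = 0.85,
    min_aligned_fraction: float = 0.5,
    target_interval: tuple[int, int] | None = None,
) -> tuple[list[AlignmentHit], dict]:
    """Threshold hits on identity and aligned fraction; report mapping stats.

    ``hits`` may contain None entries for unmapped reads so that
    ``mapped_fraction`` is meaningful. When ``target_interval`` (1-based
    inclusive) is given, on-target means >= 1 bp overlap.
    """
    for name, v in (("min_identity", min_identity), ("min_aligned_fraction", min_aligned_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if target_interval is not None:
        t_lo, t_hi = target_interval
        if t_lo > t_hi or t_lo < 1:
            raise ValueError(f"malformed target interval {target_interval}")
    mapped = [h for h in hits if h is not None]
    kept = [
        h
        for h in mapped
        if h.identity >= min_identity and h.aligned_read_fraction >= min_aligned_fraction
    ]
    stats = {
        "n_input": len(hits),
        "n_mapped": len(mapped),
        "n_pass": len(kept),
        "mapped_fraction": len(mapped) / len(hits) if hits else 0.0,
    }
    if target_interval is not None:
        on_target = sum(h.overlaps(t_lo, t_hi) for h in kept)
        stats["n_on_target"] = on_target
        stats["on_target_fraction"] = on_target / len(kept) if kept else 0.0
    return kept, stats


# ---------------------------------------------------------------------------
# Tabular / BED interchange
# ---------------------------------------------------------------------------

def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS)


def hits_to_bed(hits: list[AlignmentHit], path: str | Path) -> None:
    """Write hits as BED6 (0-based half-open; name=read_id, score=alignment score)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.ref_name}\t{h.ref_start - 1}\t{h.ref_end}\t{h.read_id}\t"
                f"{h.score:g}\t{h.strand}\n"
            )


def hits_from_bed(path: str | Path) -> list[AlignmentHit]:
    """Import externally produced read placements from BED6.

    Identity and aligned fraction are not represented in BED; imported hits
    carry 1.0 for both so that downstream thresholds pass them through.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split()[:6]
            hits.append(
                AlignmentHit(
                    read_id=name,
                    ref_name=chrom,
                    ref_start=int(start) + 1,
                    ref_end=int(end),
                    strand=strand,
                    score=float(score),
                    identity=1.0,
                    aligned_read_fraction=1.0,
                )
            )
    return hits
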