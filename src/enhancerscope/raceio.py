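"""Demultiplexing, adapter/tail trimming and 5'/3' product binning for pooled RACE-seq reads.

A pooled RACE-seq library mixes barcoded 5'- and 3'-RACE products from
several samples in one FASTQ. This module assigns each read to its sample
bin by prefix barcode matching, strips the library adapter, the RACE
universal adapter and the homopolymer tail added during RACE (poly(C) for
5' products, poly(A) for 3' products), and classifies each trimmed read as
a 5' or 3' RACE product by locating the sample's gene-specific primer.

Conventions: barcode matching is prefix-anchored Hamming distance (no
indels); ties and over-budget distances go to the unassigned bin; N bases
count as mismatches everywhere; reads are processed single-pass in file
order so outputs are order-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import reverse_complement

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
UNCLASSIFIED = "unclassified"


@dataclass
class SequencingRead:
    """One raw or trimmed read (bases and Phred+33 quality string)."""

    id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id}: empty sequence")
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")


@dataclass(frozen=True)
class ManifestRow:
    sample: str
    barcode: str
    gsp_5prime: str
    gsp_3prime: str


@dataclass
class BarcodeManifest:
    """Per-sample barcode and gene-specific primer table."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty barcode manifest")
        samples = [r.sample for r in self.rows]
        barcodes = [r.barcode for r in self.rows]
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample names in manifest")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in manifest")
        for r in self.rows:
            if not r.barcode or not r.gsp_5prime or not r.gsp_3prime:
                raise ValueError(f"manifest row {r.sample}: empty sequence field")

    @property
    def samples(self) -> list[str]:
        return [r.sample for r in self.rows]

    def row(self, sample: str) -> ManifestRow:
        for r in self.rows:
            if r.sample == sample:
                return r
        raise KeyError(sample)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeManifest":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = ["sample", "barcode", "gsp_5prime", "gsp_3prime"]
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        return cls([ManifestRow(*row) for row in df[required].itertuples(index=False)])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame([r.__dict__ for r in self.rows])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class RaceProduct:
    """A demultiplexed, trimmed read with its 5'/3' product call."""

    read_id: str
    sample: str
    product_class: str
    trimmed_bases: str
    trim_log: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, Phred+33)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path):
    """Yield :class:`SequencingRead` from a FASTQ file (gz-transparent)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            bases = fh.readline().strip()
            fh.readline()
            quals = fh.readline().strip()
            yield SequencingRead(header.strip()[1:].split()[0], bases, quals)


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.quals}\n")


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads,
    manifest: BarcodeManifest,
    max_mismatch: int = 1,
) -> tuple[dict[str, list[SequencingRead]], list[SequencingRead], pd.DataFrame]:
    """Assign reads to per-sample bins by prefix barcode match.

    Each read goes to the unique barcode with minimal Hamming distance to
    the read prefix (compared at each barcode's own length) provided that
    distance is <= ``max_mismatch``; distance ties or over-budget distances
    leave the read unassigned. Assigned reads have the barcode prefix
    removed.

    Returns (bins, unassigned, summary) where summary has one row per bin
    plus ``unassigned`` with columns bin/count/fraction.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    exact = {r.barcode: r.sample for r in manifest.rows}
    bins: dict[str, list[SequencingRead]] = {s: [] for s in manifest.samples}
    unassigned: list[SequencingRead] = []
    total = 0
    for read in reads:
        total += 1
        # fast path: exact barcode prefix
        assigned = None
        for bc, sample in exact.items():
            if read.bases.startswith(bc):
                assigned, bc_len = sample, len(bc)
                break
        if assigned is None and max_mismatch > 0:
            best_d, best_sample, best_len, tie = math.inf, None, 0, False
            for row in manifest.rows:
                d = _hamming(read.bases[: len(row.barcode)], row.barcode)
                if d < best_d:
                    best_d, best_sample, best_len, tie = d, row.sample, len(row.barcode), False
                elif d == best_d:
                    tie = True
            if best_d <= max_mismatch and not tie:
                assigned, bc_len = best_sample, best_len
        if assigned is None:
            unassigned.append(read)
        else:
            bins[assigned].append(
                SequencingRead(read.id, read.bases[bc_len:], read.quals[bc_len:])
            )
    rows = [
        {"bin": s, "count": len(bins[s]), "fraction": len(bins[s]) / total if total else 0.0}
        for s in manifest.samples
    ]
    rows.append(
        {
            "bin": "unassigned",
            "count": len(unassigned),
            "fraction": len(unassigned) / total if total else 0.0,
        }
    )
    return bins, unassigned, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_adapter(
    bases: str,
    adapter: str,
    end: str,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> tuple[str, int]:
    """Remove an adapter occurrence anchored at one end of the sequence.

    Considers every partial overlap of length >= ``min_overlap`` (for
    ``end='left'`` the adapter's suffix against the sequence's prefix; for
    ``end='right'`` the adapter's prefix against the sequence's suffix) and
    removes the longest overlap whose mismatch fraction is
    <= ``max_error_rate``. Absent adapter is a no-op.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    best = 0
    upper = min(len(adapter), len(bases))
    for n in range(min_overlap, upper + 1):
        if end == "left":
            mism = _hamming(adapter[-n:], bases[:n])
        else:
            mism = _hamming(adapter[:n], bases[len(bases) - n :])
        if mism <= max_error_rate * n:
            best = n
    if best == 0:
        return bases, 0
    return (bases[best:], best) if end == "left" else (bases[: len(bases) - best], best)


def trim_homopolymer_tail(
    bases: str,
    base: str,
    end: str,
    min_run: int = 5,
    max_interruptions: int = 0,
) -> tuple[str, int]:
    """Strip a terminal homopolymer run of ``base``.

    The run may contain up to ``max_interruptions`` non-matching bases but
    must end on a matching base; it is removed only if it contains at least
    ``min_run`` matching bases.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    seq = bases if end == "left" else bases[::-1]
    matches = 0
    interruptions = 0
    cut = 0  # length of the run, ending on the last matching base seen
    for i, b in enumerate(seq):
        if b == base:
            matches += 1
            cut = i + 1
        else:
            interruptions += 1
            if interruptions > max_interruptions:
                break
    if matches < min_run:
        return bases, 0
    return (bases[cut:], cut) if end == "left" else (bases[: len(bases) - cut], cut)


# ---------------------------------------------------------------------------
# 5'/3' product classification
# ---------------------------------------------------------------------------

def _best_primer_matches(
    bases: str, primer: str, min_overlap: int, max_error_rate: float
) -> int:
    """Best qualifying match count of primer (either orientation) in bases.

    Slides the primer across every offset, allowing partial overlap of at
    least ``min_overlap`` at the read edges; a placement qualifies when its
    mismatch fraction over the overlap is <= ``max_error_rate``. Returns the
    maximum number of matching bases over qualifying placements (0 if none).
    """
    best = 0
    n = len(bases)
    for p in (primer, reverse_complement(primer)):
        if p in bases:  # fast path, full-length exact hit
            best = max(best, len(p))
            continue
        m = len(p)
        for offset in range(-(m - min_overlap), n - min_overlap + 1):
            lo = max(0, offset)
            hi = min(n, offset + m)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            mism = _hamming(bases[lo:hi], p[lo - offset : hi - offset])
            if mism <= max_error_rate * overlap:
                best = max(best, overlap - mism)
    return best


def classify_race_product(
    bases: str,
    manifest_row: ManifestRow,
    min_primer_overlap: int = 12,
    max_error_rate: float = 0.1,
) -> str:
    """Call a trimmed read as a 5' or 3' RACE product by its gene-specific primer.

    The class is ``five_prime`` when the sample's 5' gene-specific primer
    (or its reverse complement) matches within the read better than the 3'
    primer does, and symmetrically for ``three_prime``; no qualifying match
    for either primer, or an exact score tie, yields ``unclassified``.
    """
    s5 = _best_primer_matches(bases, manifest_row.gsp_5prime, min_primer_overlap, max_error_rate)
    s3 = _best_primer_matches(bases, manifest_row.gsp_3prime, min_primer_overlap, max_error_rate)
    if s5 == s3:
        return UNCLASSIFIED
    return FIVE_PRIME if s5 > s3 else THREE_PRIME


def length_filter(
    products: list[RaceProduct], min_length: int = 20
) -> tuple[list[RaceProduct], int]:
    """Keep products whose trimmed length is >= ``min_length``; report drops."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = [p for p in products if len(p.trimmed_bases) >= min_length]
    return kept, len(products) - len(kept)
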