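"""Transcript end-frequency profiles, modal end calling and the consensus transcript.

An eRNA's boundaries are read off mapped RACE products: for a sense-strand
(+) transcript a 5'-RACE product's transcript end is its alignment's
ref_start and a 3'-RACE product's is its ref_end (mirrored on -). Ends are
tallied per genomic position as % total reads; the consensus transcript
spans the modal 5' to the modal 3' end inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .locus import from_tss_relative, to_tss_relative  # noqa: F401  (re-export)
from .mapper import AlignmentHit

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class EndProfile:
    """Per-position transcript-end counts for one sample x end type."""

    sample: str
    end_type: str
    counts: dict[int, int] = field(default_factory=dict)
    sense_strand: str = "+"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percent(self) -> dict[int, float]:
        t = self.total
        return {pos: 100.0 * c / t for pos, c in self.counts.items()} if t else {}

    def to_frame(self, tss: int | None = None, strand: str = "+") -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample,
                "end_type": self.end_type,
                "position": pos,
                "count": c,
                "percent": 100.0 * c / self.total,
                **(
                    {"tss_relative": to_tss_relative(pos, tss, strand)}
                    if tss is not None
                    else {}
                ),
            }
            for pos, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class ModalEnd:
    position: int
    percent: float
    tie: bool = False


@dataclass
class TranscriptCall:
    """Consensus transcript between the modal 5' and modal 3' ends."""

    ref_name: str
    start: int
    end: int
    strand: str
    modal5: int
    modal3: int
    modal5_pct: float
    modal3_pct: float
    length: int
    gc_fraction: float
    tss_relative_start: int
    tss_relative_end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.length != self.end - self.start + 1:
            raise ValueError("length inconsistent with interval")


def end_frequency_profile(
    hits: list[AlignmentHit],
    end_type: str,
    sense_strand: str = "+",
    sample: str = "pooled",
    min_aligned_fraction: float = 0.9,
    product_classes: dict[str, str] | None = None,
) -> EndProfile:
    """Tally transcript-end positions over on-target hits of one product class.

    Only hits on the transcript's sense strand with
    ``aligned_read_fraction >= min_aligned_fraction`` contribute (residual
    untrimmed bases shift an alignment terminus, so poorly covered hits are
    excluded). If ``product_classes`` (read_id -> class) is supplied, a hit
    whose class differs from ``end_type`` raises.
    """
    if end_type not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown end_type {end_type!r}")
    counts: dict[int, int] = {}
    use_start = (end_type == FIVE_PRIME) == (sense_strand == "+")
    for h in hits:
        if product_classes is not None:
            klass = product_classes.get(h.read_id)
            if klass is not None and klass != end_type:
                raise ValueError(
                    f"hit {h.read_id} is a {klass} product, profile is {end_type}"
                )
        if h.strand != sense_strand or h.aligned_read_fraction < min_aligned_fraction:
            continue
        pos = h.ref_start if use_start else h.ref_end
        counts[pos] = counts.get(pos, 0) + 1
    return EndProfile(sample=sample, end_type=end_type, counts=counts, sense_strand=sense_strand)


def modal_end(profile: EndProfile) -> ModalEnd:
    """Arg-max end position; count ties break transcript-outward (flagged).

    Outward means the 5'-most position for a five_prime profile and the
    3'-most for a three_prime profile, favoring the longest transcript.
    For a sense(+) transcript 5'-most is the smallest genomic coordinate.
    """
    if profile.total < 1:
        raise ValueError("empty end profile")
    best = max(profile.counts.values())
    argmax = sorted(pos for pos, c in profile.counts.items() if c == best)
    tie = len(argmax) > 1
    # outward = 5'-most for a 5' profile, 3'-most for a 3' profile; on the
    # sense - strand the genomic axis is mirrored
    outer_is_min = (profile.end_type == FIVE_PRIME) == (profile.sense_strand == "+")
    pos = argmax[0] if outer_is_min else argmax[-1]
    return ModalEnd(position=pos, percent=100.0 * best / profile.total, tie=tie)


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N and other ambiguity codes are excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def consensus_transcript(
    p5: EndProfile,
    p3: EndProfile,
    ref: str,
    tss: int,
    sense_strand: str = "+",
    ref_name: str = "ref",
) -> TranscriptCall:
    """Call the consensus transcript spanning the modal 5' and 3' ends."""
    m5 = modal_end(p5)
    m3 = modal_end(p3)
    upstream_ok = m5.position < m3.position if sense_strand == "+" else m5.position > m3.position
    if not upstream_ok:
        raise ValueError(
            f"inconsistent profiles: modal 5' at {m5.position} is not "
            f"transcript-upstream of modal 3' at {m3.position}"
        )
    start, end = min(m5.position, m3.position), max(m5.position, m3.position)
    return TranscriptCall(
        ref_name=ref_name,
        start=start,
        end=end,
        strand=sense_strand,
        modal5=m5.position,
        modal3=m3.position,
        modal5_pct=m5.percent,
        modal3_pct=m3.percent,
        length=end - start + 1,
        gc_fraction=gc_content(ref[start - 1 : end]),
        tss_relative_start=to_tss_relative(m5.position, tss, sense_strand),
        tss_relative_end=to_tss_relative(m3.position, tss, sense_strand),
    )


def strand_ratio(
    sense_count: int, antisense_count: int, pseudocount: float = 0.0
) -> tuple[float, bool]:
    """Sense/antisense fold ratio; returns (ratio, infinite_flag)."""
    if sense_count < 0 or antisense_count < 0:
        raise ValueError("counts must be >= 0")
    denom = antisense_count + pseudocount
    if denom == 0:
        return float("inf"), True
    return (sense_count + pseudocount) / denom, False


def write_wiggle(profile: EndProfile, path: str | Path, ref_name: str = "ref") -> None:
    """Per-position % total reads as variableStep wiggle."""
    with open(path, "w") as fh:
        fh.write(f"variableStep chrom={ref_name}\n")
        for pos, pct in sorted(profile.percent.items()):
            fh.write(f"{pos}\t{pct:.6f}\n")
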