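"""Locus model and TSS-relative coordinate conventions.

Genomic coordinates are 1-based inclusive throughout the package.
TSS-relative coordinates follow the promoter-construct convention in which
the TSS base itself is +1 and there is no position 0: the base immediately
upstream of the TSS is -1, so a construct named "-321/+19" spans 340 bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def to_tss_relative(pos: int, tss: int, strand: str = "+") -> int:
    """Convert a 1-based genomic position to a signed TSS-relative coordinate.

    On the + strand, positions at or downstream of the TSS map to
    ``pos - tss + 1`` (so the TSS itself is +1) and upstream positions to
    ``pos - tss`` (no zero). On the - strand the axis is mirrored:
    downstream means decreasing genomic coordinate.
    """
    if strand == "+":
        return pos - tss + 1 if pos >= tss else pos - tss
    if strand == "-":
        return tss - pos + 1 if pos <= tss else tss - pos
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def from_tss_relative(rel: int, tss: int, strand: str = "+") -> int:
    """Inverse of :func:`to_tss_relative` (rel may not be 0)."""
    if rel == 0:
        raise ValueError("TSS-relative coordinate 0 does not exist (+1 convention)")
    if strand == "+":
        return tss + rel - 1 if rel > 0 else tss + rel
    if strand == "-":
        return tss - rel + 1 if rel > 0 else tss - rel
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass
class LocusModel:
    """Geometry and transcriptional model of the mini-genome locus.

    The locus carries one pri-miR TSS and, upstream of it, an enhancer that
    transcribes a short eRNA. End-position distributions are expressed in
    TSS-relative coordinates and describe where eRNA molecules start (5')
    and stop (3') along the eRNA's sense strand.

    Parameters
    ----------
    erna_five_prime_dist, erna_three_prime_dist
        Mapping TSS-relative position -> probability. Each must sum to 1,
        and every 5'-end support position must lie transcript-upstream of
        every 3'-end support position.
    antisense_fraction
        Proportion of eRNA molecules transcribed from the opposite strand.
    gsp_five_site, gsp_three_site
        TSS-relative inclusive intervals of the gene-specific primer
        annealing sites used by the RACE read simulator and the product
        classifier: a 5'-RACE insert ends at ``gsp_five_site[1]`` and a
        3'-RACE insert starts at ``gsp_three_site[0]``.
    enhancer_interval
        TSS-relative inclusive interval of the enhancer element.
    """

    reference_name: str = "minigenome"
    tss_position: int = 10_000
    strand: str = "+"
    erna_five_prime_dist: dict[int, float] = field(default_factory=dict)
    erna_three_prime_dist: dict[int, float] = field(default_factory=dict)
    erna_sense_strand: str = "+"
    antisense_fraction: float = 0.0
    gsp_five_site: tuple[int, int] = (-5071, -5052)
    gsp_three_site: tuple[int, int] = (-5062, -5043)
    enhancer_interval: tuple[int, int] = (-5771, -4607)

    def __post_init__(self) -> None:
        if self.strand not in "+-" or self.erna_sense_strand not in "+-":
            raise ValueError("strands must be '+' or '-'")
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ValueError("antisense_fraction must be in [0, 1]")
        for name, dist in (
            ("erna_five_prime_dist", self.erna_five_prime_dist),
            ("erna_three_prime_dist", self.erna_three_prime_dist),
        ):
            if dist:
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name} sums to {total}, expected 1")
                if any(p <= 0 for p in dist.values()):
                    raise ValueError(f"{name} has non-positive probabilities")
        if self.erna_five_prime_dist and self.erna_three_prime_dist:
            # along the sense strand every 5' support position precedes
            # every 3' support position
            five = self.erna_five_prime_dist
            three = self.erna_three_prime_dist
            if self.erna_sense_strand == "+":
                if max(five) >= min(three):
                    raise ValueError("5'-end support must lie upstream of 3'-end support")
            else:
                if min(five) <= max(three):
                    raise ValueError("5'-end support must lie upstream of 3'-end support")

    # -- genomic-coordinate views -------------------------------------------------

    def genomic(self, rel: int) -> int:
        """Genomic position of a TSS-relative coordinate on the pri-miR strand."""
        return from_tss_relative(rel, self.tss_position, self.strand)

    def relative(self, pos: int) -> int:
        return to_tss_relative(pos, self.tss_position, self.strand)

    def genomic_interval(self, rel_interval: tuple[int, int]) -> tuple[int, int]:
        a = self.genomic(rel_interval[0])
        b = self.genomic(rel_interval[1])
        return (min(a, b), max(a, b))

    def span(self) -> tuple[int, int]:
        """Smallest genomic interval containing every modelled feature."""
        rel_points = [1]
        has_erna = bool(self.erna_five_prime_dist or self.erna_three_prime_dist)
        for dist in (self.erna_five_prime_dist, self.erna_three_prime_dist):
            rel_points.extend(dist)
        if has_erna:  # enhancer geometry only constrains an eRNA-bearing locus
            for iv in (self.gsp_five_site, self.gsp_three_site, self.enhancer_interval):
                rel_points.extend(iv)
        positions = [self.genomic(r) for r in rel_points]
        return (min(positions), max(positions))

    def consensus_interval(self) -> tuple[int, int]:
        """Genomic interval from the modal 5' end to the modal 3' end."""
        mode5 = max(self.erna_five_prime_dist, key=self.erna_five_prime_dist.get)
        mode3 = max(self.erna_three_prime_dist, key=self.erna_three_prime_dist.get)
        return self.genomic_interval((mode5, mode3))
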