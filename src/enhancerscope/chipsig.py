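"""Input-subtracted binned ChIP signal tracks, ChIP-qPCR percent-input,
methylation beta-values, and enhancer chromatin-state classification.

Signal convention: per-bp signal = coverage-per-million(ChIP) minus
coverage-per-million(input); bin values are means of per-bp signal over
fixed-width bins (default 50 bp, trailing partial bin averaged over its
actual width). Negative post-subtraction values are retained in the raw
track and clamped to zero only in the display/export variant.

Chromatin-state rules follow the standard histone-mark signatures:
H3K4me1 marks the enhancer; co-occurring H3K27ac (without H3K27me3) makes
it active, co-occurring H3K27me3 (without H3K27ac) poised, H3K4me1 alone
intermediate. RNAPII occupancy and CpG hypomethylation strengthen an
active call when supplied but are not required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import median_abs_deviation

ACTIVE = "active"
POISED = "poised"
INTERMEDIATE = "intermediate"
NONE = "none"

REQUIRED_MARK = "H3K4me1"


@dataclass
class SignalTrack:
    """Binned, depth-normalized, input-subtracted coverage for one mark.

    ``origin`` is the 1-based genomic start of bin 0; bin i covers
    [origin + i*bin_size, origin + (i+1)*bin_size - 1].
    """

    ref_name: str
    mark: str
    bin_size: int
    origin: int
    values: np.ndarray
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    def clamp_nonnegative(self) -> "SignalTrack":
        """Display/export variant with negatives clamped to 0 (flagged)."""
        return SignalTrack(
            self.ref_name, self.mark, self.bin_size, self.origin,
            np.maximum(self.values, 0.0), clamped=True,
        )

    def mean_over(self, start: int, end: int) -> float:
        """Mean bin value over bins overlapping the 1-based interval [start, end]."""
        first = (start - self.origin) // self.bin_size
        last = (end - self.origin) // self.bin_size
        first = max(first, 0)
        last = min(last, len(self.values) - 1)
        if first > last:
            raise ValueError(f"interval [{start}, {end}] not covered by track")
        return float(self.values[first : last + 1].mean())

    def to_bedgraph(self, path: str | Path) -> None:
        """4-column bedGraph, 0-based half-open."""
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.mark}"\n')
            for i, v in enumerate(self.values):
                start0 = self.origin - 1 + i * self.bin_size
                fh.write(f"{self.ref_name}\t{start0}\t{start0 + self.bin_size}\t{v:.6f}\n")


@dataclass
class ChipQpcrMeasurement:
    mark: str
    region: str
    ct_chip: float
    ct_input: float
    input_dilution_factor: float = 10.0
    mode: str = "conventional"

    @property
    def percent_input_value(self) -> float:
        return percent_input(self.ct_chip, self.ct_input, self.input_dilution_factor, self.mode)


@dataclass
class EnhancerStateCall:
    interval: tuple[int, int]
    state: str
    evidence: dict[str, dict] = field(default_factory=dict)


def normalize_and_subtract(
    chip_cov: np.ndarray,
    chip_depth: float,
    input_cov: np.ndarray,
    input_depth: float,
    bin_size: int = 50,
    origin: int = 1,
    mark: str = "mark",
    ref_name: str = "ref",
) -> SignalTrack:
    """Depth-normalize ChIP and input coverage, subtract, and bin.

    Per-bp signal is 1e6*chip/chip_depth - 1e6*input/input_depth
    (coverage per million reads); each bin value is the mean per-bp signal
    over the bin, with the trailing partial bin averaged over its actual
    width. Mass is conserved: the width-weighted mean of bin values equals
    the mean per-bp signal.
    """
    chip_cov = np.asarray(chip_cov, dtype=float)
    input_cov = np.asarray(input_cov, dtype=float)
    if chip_cov.shape != input_cov.shape:
        raise ValueError("chip and input coverage arrays differ in length")
    if chip_depth <= 0 or input_depth <= 0:
        raise ValueError("depths must be > 0")
    signal = 1e6 * chip_cov / chip_depth - 1e6 * input_cov / input_depth
    n_bins = math.ceil(len(signal) / bin_size)
    values = np.empty(n_bins)
    for i in range(n_bins):
        values[i] = signal[i * bin_size : (i + 1) * bin_size].mean()
    return SignalTrack(
        ref_name=ref_name, mark=mark, bin_size=bin_size, origin=origin, values=values
    )


def percent_input(
    ct_chip: float,
    ct_input: float,
    dilution_factor: float = 10.0,
    mode: str = "conventional",
) -> float:
    """ChIP enrichment as % of input chromatin via 2^dCt scaling.

    ``conventional`` (default): 100 * DF * 2**(ct_input - ct_chip), the
    standard derivation in which fewer cycles for the ChIP sample mean more
    material. ``as_printed`` implements the same formula with the exponent
    written as Ct(ChIP) - Ct(Input); that sign yields values above 100%
    precisely when the ChIP is weaker than the diluted input, so it is not
    the default (the two modes agree only at ct_chip == ct_input).
    """
    if not (math.isfinite(ct_chip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    if mode == "conventional":
        exponent = ct_input - ct_chip
    elif mode == "as_printed":
        exponent = ct_chip - ct_input
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * dilution_factor * 2.0 ** exponent


def h3_normalize(percent_input_mark: float, percent_input_h3: float) -> float:
    """Express a histone-mark %-input relative to total histone H3 %-input."""
    if percent_input_h3 <= 0:
        raise ValueError("H3 percent-input must be > 0")
    return percent_input_mark / percent_input_h3


def beta_value(meth_intensity: float, unmeth_intensity: float, alpha: float = 100.0) -> float:
    """Methylation beta-value M / (M + U + alpha), in [0, 1].

    ``alpha`` is the standard array stabilization offset; alpha=0 gives the
    pure intensity ratio (0 = non-methylated, 1 = completely methylated).
    """
    if meth_intensity < 0 or unmeth_intensity < 0:
        raise ValueError("intensities must be >= 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    denom = meth_intensity + unmeth_intensity + alpha
    if denom == 0:
        raise ValueError("M + U + alpha must be > 0")
    return meth_intensity / denom


def background_threshold(track: SignalTrack, k: float = 3.0) -> float:
    """Locus-wide background cutoff: median + k * MAD of the bin values."""
    values = track.values
    return float(np.median(values) + k * median_abs_deviation(values))


def classify_enhancer_state(
    tracks: dict[str, SignalTrack],
    interval: tuple[int, int],
    thresholds: dict[str, float] | None = None,
    mad_k: float = 3.0,
) -> EnhancerStateCall:
    """Classify the chromatin state of an interval from per-mark signal tracks.

    Per-mark evidence is mean binned signal over the interval exceeding the
    mark's threshold (an absolute cutoff from ``thresholds``, else the
    track's locus-wide median + ``mad_k``*MAD). States:

    - active: H3K4me1+ and H3K27ac+ and H3K27me3-
    - poised: H3K4me1+ and H3K27me3+ and H3K27ac-
    - intermediate: H3K4me1+ with neither H3K27ac nor H3K27me3
    - none: otherwise

    RNAPII (and low methylation, when its track is supplied) are recorded
    as supporting evidence but do not gate the call.
    """
    if REQUIRED_MARK not in tracks:
        raise ValueError(f"required mark {REQUIRED_MARK} missing from tracks")
    evidence: dict[str, dict] = {}
    positive: dict[str, bool] = {}
    for mark, track in tracks.items():
        cutoff = (
            thresholds[mark]
            if thresholds is not None and mark in thresholds
            else background_threshold(track, mad_k)
        )
        mean = track.mean_over(*interval)
        positive[mark] = mean > cutoff
        evidence[mark] = {"mean": mean, "threshold": cutoff, "positive": positive[mark]}
    k4me1 = positive.get("H3K4me1", False)
    k27ac = positive.get("H3K27ac", False)
    k27me3 = positive.get("H3K27me3", False)
    if k4me1 and k27ac and not k27me3:
        state = ACTIVE
    elif k4me1 and k27me3 and not k27ac:
        state = POISED
    elif k4me1 and not k27ac and not k27me3:
        state = INTERMEDIATE
    else:
        state = NONE
    return EnhancerStateCall(interval=interval, state=state, evidence=evidence)


def read_bedgraph(path: str | Path) -> tuple[str, int, int, np.ndarray]:
    """Read a uniform-bin bedGraph back into (ref_name, origin, bin_size, values)."""
    ref_name, origin, bin_size = None, None, None
    values = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            chrom, start, end, value = line.split()
            start, end = int(start), int(end)
            if ref_name is None:
                ref_name, origin, bin_size = chrom, start + 1, end - start
            values.append(float(value))
    if ref_name is None:
        raise ValueError(f"no data lines in {path}")
    return ref_name, origin, bin_size, np.array(values)
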