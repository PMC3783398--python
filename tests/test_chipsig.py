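"""Signal tracks, percent-input, beta-values and chromatin-state calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerscope import presets, simulate
from enhancerscope.chipsig import (
    SignalTrack,
    beta_value,
    classify_enhancer_state,
    h3_normalize,
    normalize_and_subtract,
    percent_input,
    read_bedgraph,
)


class TestNormalizeAndSubtract:
    def test_self_subtraction_is_zero(self):
        cov = np.arange(500, dtype=float)
        track = normalize_and_subtract(cov, 1e6, cov, 1e6, bin_size=50)
        assert np.allclose(track.values, 0.0)

    def test_arithmetic_in_per_million_units(self):
        chip = np.full(50, 10.0)
        inp = np.full(50, 2.0)
        track = normalize_and_subtract(chip, 2e6, inp, 1e6, bin_size=50)
        assert track.values == pytest.approx([3.0])  # 10/2 - 2/1

    def test_default_bin_width_is_50(self):
        track = normalize_and_subtract(np.zeros(500), 1e6, np.zeros(500), 1e6)
        assert track.bin_size == 50 and len(track.values) == 10

    def test_binning_conserves_mass(self):
        rng = np.random.default_rng(12)
        chip = rng.poisson(30, size=1_037).astype(float)  # trailing partial bin
        inp = rng.poisson(25, size=1_037).astype(float)
        track = normalize_and_subtract(chip, 3e6, inp, 2e6, bin_size=50)
        signal = 1e6 * chip / 3e6 - 1e6 * inp / 2e6
        widths = np.array([50] * 20 + [37])
        weighted = (track.values * widths).sum() / widths.sum()
        assert weighted == pytest.approx(signal.mean(), abs=1e-9)

    def test_negatives_kept_then_clamped_on_export(self):
        track = normalize_and_subtract(np.zeros(100), 1e6, np.full(100, 5.0), 1e6)
        assert (track.values < 0).all() and not track.clamped
        clamped = track.clamp_nonnegative()
        assert (clamped.values == 0).all() and clamped.clamped

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            normalize_and_subtract(np.zeros(10), 1e6, np.zeros(11), 1e6)


class TestPercentInput:
    def test_identity_case_both_modes(self):
        for mode in ("conventional", "as_printed"):
            assert percent_input(25.0, 25.0, 1.0, mode) == pytest.approx(100.0)

    def test_conventional_closed_form(self):
        assert percent_input(25.0, 20.0, 10.0, "conventional") == pytest.approx(31.25)

    def test_as_printed_sign_behavior(self):
        # the printed exponent direction inflates weak ChIP above 100%
        assert percent_input(25.0, 20.0, 10.0, "as_printed") == pytest.approx(32_000.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        ct=st.floats(min_value=10, max_value=35),
        offset=st.floats(min_value=-5, max_value=5),
        delta=st.floats(min_value=-8, max_value=8),
    )
    def test_invariant_to_common_ct_offset(self, ct, offset, delta):
        a = percent_input(ct + delta, ct)
        b = percent_input(ct + delta + offset, ct + offset)
        assert a == pytest.approx(b, rel=1e-9)


class TestH3Normalize:
    def test_ratios(self):
        assert h3_normalize(5.0, 5.0) == 1.0
        assert h3_normalize(6.0, 2.0) == 3.0

    def test_zero_h3_rejected(self):
        with pytest.raises(ValueError):
            h3_normalize(5.0, 0.0)


class TestBetaValue:
    def test_boundary_conventions(self):
        assert beta_value(0.0, 5_000.0, alpha=0) == 0.0
        assert beta_value(5_000.0, 0.0, alpha=0) == 1.0

    def test_offset_formula(self):
        assert beta_value(1000.0, 1000.0, alpha=100) == pytest.approx(1000 / 2100)

    @settings(derandomize=True, max_examples=50)
    @given(
        m=st.floats(min_value=1, max_value=1e5),
        u=st.floats(min_value=0, max_value=1e5),
        bump=st.floats(min_value=1, max_value=1e4),
    )
    def test_monotone_in_intensities(self, m, u, bump):
        base = beta_value(m, u)
        assert beta_value(m + bump, u) > base
        assert beta_value(m, u + bump) < base  # strict since m > 0


def _flat_track(mark, level=0.0, n=240, noise_seed=0):
    rng = np.random.default_rng(noise_seed)
    values = rng.normal(0, 0.05, size=n)
    return SignalTrack("ref", mark, 50, 1, values + level * 0)


def _enriched_track(mark, interval, level=5.0, n=240, noise_seed=0):
    rng = np.random.default_rng(noise_seed)
    values = rng.normal(0, 0.05, size=n)
    lo_bin, hi_bin = (interval[0] - 1) // 50, (interval[1] - 1) // 50
    values[lo_bin : hi_bin + 1] += level
    return SignalTrack("ref", mark, 50, 1, values)


class TestClassifyEnhancerState:
    INTERVAL = (4_229, 5_393)

    def test_active_signature(self):
        tracks = {
            "H3K4me1": _enriched_track("H3K4me1", self.INTERVAL, noise_seed=1),
            "H3K27ac": _enriched_track("H3K27ac", self.INTERVAL, noise_seed=2),
            "H3K27me3": _flat_track("H3K27me3", noise_seed=3),
        }
        assert classify_enhancer_state(tracks, self.INTERVAL).state == "active"

    def test_poised_signature(self):
        tracks = {
            "H3K4me1": _enriched_track("H3K4me1", self.INTERVAL, noise_seed=1),
            "H3K27me3": _enriched_track("H3K27me3", self.INTERVAL, noise_seed=2),
            "H3K27ac": _flat_track("H3K27ac", noise_seed=3),
        }
        assert classify_enhancer_state(tracks, self.INTERVAL).state == "poised"

    def test_all_below_threshold_is_none(self):
        tracks = {
            mark: _flat_track(mark, noise_seed=i)
            for i, mark in enumerate(["H3K4me1", "H3K27ac", "H3K27me3"])
        }
        call = classify_enhancer_state(tracks, self.INTERVAL)
        assert call.state == "none"
        assert set(call.evidence) == set(tracks)

    def test_k4me1_only_is_intermediate(self):
        tracks = {
            "H3K4me1": _enriched_track("H3K4me1", self.INTERVAL, noise_seed=1),
            "H3K27ac": _flat_track("H3K27ac", noise_seed=2),
            "H3K27me3": _flat_track("H3K27me3", noise_seed=3),
        }
        assert classify_enhancer_state(tracks, self.INTERVAL).state == "intermediate"

    def test_missing_required_mark_rejected(self):
        with pytest.raises(ValueError, match="H3K4me1"):
            classify_enhancer_state({"H3K27ac": _flat_track("H3K27ac")}, self.INTERVAL)

    def test_simulated_coverage_active_and_swap_gives_poised(self, hmle_locus):
        """On simulated fragment coverage, the epithelial profile classifies
        active and swapping H3K27ac with H3K27me3 classifies poised."""
        cfg = presets.default_chip_config(hmle_locus, "epithelial", depth=100_000, seed=14)
        coverage = simulate.simulate_chip_coverage(12_000, cfg)
        interval = hmle_locus.genomic_interval(hmle_locus.enhancer_interval)

        def tracks_from(cov):
            return {
                mark: normalize_and_subtract(
                    cov[mark], cfg.library_depth, cov["input"], cfg.input_depth,
                    bin_size=50, mark=mark,
                )
                for mark in cfg.profiles
            }

        assert classify_enhancer_state(tracks_from(coverage), interval).state == "active"
        swapped = dict(coverage)
        swapped["H3K27ac"], swapped["H3K27me3"] = coverage["H3K27me3"], coverage["H3K27ac"]
        assert classify_enhancer_state(tracks_from(swapped), interval).state == "poised"


class TestBedgraphRoundTrip:
    def test_track_survives(self, tmp_path):
        track = SignalTrack("chr", "H3K4me1", 50, 1, np.array([1.5, -0.25, 3.0]))
        path = tmp_path / "t.bedgraph"
        track.to_bedgraph(path)
        ref_name, origin, bin_size, values = read_bedgraph(path)
        assert (ref_name, origin, bin_size) == ("chr", 1, 50)
        assert values == pytest.approx(track.values)
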