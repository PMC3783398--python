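import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for sw_oracle

from enhancerscope import pipeline, presets, simulate


@pytest.fixture(scope="session")
def hmle_locus():
    return presets.hmle_like_locus()


@pytest.fixture(scope="session")
def reference(hmle_locus):
    return simulate.make_reference(
        presets.REFERENCE_LENGTH, presets.GENOME_GC, hmle_locus, seed=11,
        enhancer_gc=presets.ENHANCER_GC,
    )


@pytest.fixture(scope="session")
def manifest(reference):
    return presets.make_manifest(reference)


@pytest.fixture(scope="session")
def clean_read_pool(reference, hmle_locus, manifest):
    """Error-free, fully on-target read pool with its truth table."""
    cfg = presets.default_read_config(
        n_reads=600, substitution_error_rate=0.0, seed=5, off_target_fraction=0.0
    )
    reads, truth = simulate.simulate_race_reads(reference, hmle_locus, cfg)
    return reads, truth


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    config = pipeline.make_demo(seed=3, out_dir=out, n_reads=800)
    return out, config
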