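"""Packaged "HMLE-like" study configuration.

A 12-kb mini-genome stands in for the miR-200b~200a~429 locus slice: the
pri-miR TSS sits at genomic position 10,000 on the + strand, the enhancer
element occupies -5771..-4607 (TSS-relative) and transcribes a short
GC-rich eRNA whose dominant start is the position 5185 bp upstream of the
TSS, with heterogeneous near-modal minor starts, and whose more homogeneous
3' end peaks at -5000. Sense transcription outweighs antisense about
5-fold. Everything here is overridable; these defaults define the study
conditions the test-suite and acceptance runs exercise.
"""

from __future__ import annotations

from .locus import LocusModel
from .raceio import BarcodeManifest, ManifestRow
from .simulate import ChipSimConfig, CtSimConfig, ReadSimConfig, ReferenceAssembly

SAMPLES = ["HMLE", "mesHMLE", "MDA-MB-468", "MDA-MB-231"]

# Ion Xpress barcodes 5-8 (pairwise Hamming distance >= 5)
BARCODES = {
    "HMLE": "CAGAAGGAAC",
    "mesHMLE": "CTGCAAGTTC",
    "MDA-MB-468": "TTCGTGATTC",
    "MDA-MB-231": "TTCCGATAAC",
}

ADAPTER_P1 = "CCTCTCTATGGGCAGTCGGTGAT"
RACE_UNIVERSAL_ADAPTER = "GGCCACGCGTCGACTAGTAC"

REFERENCE_LENGTH = 12_000
GENOME_GC = 0.50
ENHANCER_GC = 0.63

# dominant modal 5' start (-5185) among heterogeneous nearby starts; the
# 3' end is more homogeneous around -5000
FIVE_PRIME_DIST = {
    -5195: 0.05, -5192: 0.08, -5190: 0.03, -5188: 0.10, -5185: 0.40,
    -5183: 0.12, -5180: 0.09, -5179: 0.00, -5176: 0.07, -5172: 0.04, -5170: 0.02,
}
FIVE_PRIME_DIST = {k: v for k, v in FIVE_PRIME_DIST.items() if v > 0}
THREE_PRIME_DIST = {-5005: 0.05, -5002: 0.12, -5000: 0.70, -4998: 0.10, -4996: 0.03}


def hmle_like_locus() -> LocusModel:
    return LocusModel(
        reference_name="minigenome",
        tss_position=10_000,
        strand="+",
        erna_five_prime_dist=dict(FIVE_PRIME_DIST),
        erna_three_prime_dist=dict(THREE_PRIME_DIST),
        erna_sense_strand="+",
        antisense_fraction=1.0 / 6.0,  # sense ~5-fold over antisense
        gsp_five_site=(-5071, -5052),
        gsp_three_site=(-5062, -5043),
        enhancer_interval=(-5771, -4607),
    )


def default_read_config(
    n_reads: int = 10_000,
    substitution_error_rate: float = 0.01,
    seed: int = 0,
    **overrides,
) -> ReadSimConfig:
    kwargs = dict(
        n_reads=n_reads,
        barcode_table=dict(BARCODES),
        adapter_p1=ADAPTER_P1,
        race_universal_adapter=RACE_UNIVERSAL_ADAPTER,
        tail_length_range=(8, 16),
        substitution_error_rate=substitution_error_rate,
        off_target_fraction=0.02,
        five_prime_fraction=0.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return ReadSimConfig(**kwargs)


def make_manifest(ref: ReferenceAssembly) -> BarcodeManifest:
    """Barcode/primer manifest with gene-specific primers read off the reference.

    The 5' GSP site closes a 5'-RACE insert (primer given genome-sense) and
    the 3' GSP site opens a 3'-RACE insert; the same primer pair serves all
    four cell-line pools, as in a single-locus RACE design.
    """
    locus = ref.locus
    g5 = locus.genomic_interval(locus.gsp_five_site)
    g3 = locus.genomic_interval(locus.gsp_three_site)
    gsp5 = ref.sequence[g5[0] - 1 : g5[1]]
    gsp3 = ref.sequence[g3[0] - 1 : g3[1]]
    return BarcodeManifest(
        [ManifestRow(sample, BARCODES[sample], gsp5, gsp3) for sample in SAMPLES]
    )


def _chip_profiles(locus: LocusModel, state: str = "epithelial") -> dict:
    """Fold-enrichment profiles reproducing the qualitative locus layout.

    Epithelial: active enhancer (H3K4me1/H3K27ac/RNAPII, some H3K4me3) and
    an active promoter; no H3K27me3. Mesenchymal: H3K27me3 covers the
    promoter after silencing but does not spread into the enhancer domain.
    """
    enh = locus.genomic_interval(locus.enhancer_interval)
    pro = locus.genomic_interval((-321, 19))
    profiles = {
        "H3K4me1": {enh: 8.0, pro: 1.0},
        "H3K4me3": {enh: 3.0, pro: 8.0},
        "H3K9_14ac": {enh: 5.0, pro: 5.0},
        "H3K27ac": {enh: 6.0, pro: 6.0},
        "H3K27me3": {},
        "RNAPII": {enh: 3.0, pro: 6.0},
    }
    if state == "mesenchymal":
        profiles["H3K27me3"] = {pro: 6.0}
        profiles["H3K27ac"] = {enh: 6.0}
        profiles["RNAPII"] = {enh: 3.0}
    elif state != "epithelial":
        raise ValueError(f"unknown cell state {state!r}")
    return profiles


def default_chip_config(
    locus: LocusModel | None = None,
    state: str = "epithelial",
    depth: int = 200_000,
    seed: int = 0,
) -> ChipSimConfig:
    locus = locus or hmle_like_locus()
    return ChipSimConfig(
        profiles=_chip_profiles(locus, state),
        library_depth=depth,
        fragment_length_mean=500.0,
        fragment_length_sd=50.0,
        input_depth=depth,
        seed=seed,
    )


def default_ct_config(noise_sd: float = 0.1, seed: int = 0) -> CtSimConfig:
    """Expression design mirroring the cell-line panel's qualitative pattern.

    Quantities are relative to GAPDH-normalized HMLE levels: E-cadherin
    epithelial-restricted, ZEB1 mesenchymal-restricted, the eRNA expressed
    everywhere at low level and ~2-fold up after EMT.
    """
    design = {
        "HMLE": {"GAPDH": 1000.0, "CDH1": 200.0, "ZEB1": 0.5, "eRNA": 1.0},
        "mesHMLE": {"GAPDH": 1000.0, "CDH1": 2.0, "ZEB1": 60.0, "eRNA": 2.0},
        "MDA-MB-468": {"GAPDH": 1000.0, "CDH1": 150.0, "ZEB1": 0.4, "eRNA": 1.5},
        "MDA-MB-231": {"GAPDH": 1000.0, "CDH1": 1.0, "ZEB1": 80.0, "eRNA": 0.8},
    }
    return CtSimConfig(
        slope=-3.3219, intercept=33.0, noise_sd=noise_sd, design=design,
        n_replicates=3, seed=seed,
    )
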