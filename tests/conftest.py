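import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ripchip import seeds

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ripchip.arrays import ExperimentDesign, SignalMatrix
from ripchip.simulate import RipChipSimConfig, generate_ripchip

MIR155 = "UUAAUGCUAAUCGUGAUAGGGGU"


@pytest.fixture(scope="session")
def mir155_catalog():
    return seeds.derive_sites(seeds.MatureMiRNA("hsa-miR-155-5p", MIR155))


@pytest.fixture(scope="session")
def zero_noise_experiment():
    cfg = RipChipSimConfig(
        n_genes=300,
        n_planted_targets=10,
        ip_enrichment_fold_targets=4.0,
        noise_sd_log2=0.0,
        dye_effect_sd_log2=0.0,
        detection_dropout_rate=0.0,
        rng_seed=7,
    )
    return generate_ripchip(cfg)


@pytest.fixture(scope="session")
def noisy_experiment():
    cfg = RipChipSimConfig(
        n_genes=500,
        n_planted_targets=20,
        ip_enrichment_fold_targets=4.0,
        noise_sd_log2=0.2,
        dye_effect_sd_log2=0.05,
        detection_dropout_rate=0.05,
        rng_seed=11,
    )
    return generate_ripchip(cfg)


def small_matrix(values: dict[str, list[float]], flags=None) -> SignalMatrix:
    signal = pd.DataFrame(values, dtype=float)
    signal.index = [f"P{i}" for i in range(len(signal))]
    detected = None
    if flags is not None:
        detected = pd.DataFrame(flags).astype(bool)
        detected.index = signal.index
    return SignalMatrix(signal=signal, detected=detected)


def paired_design(cell_line="CL", constructs=("control", "overexpression")) -> ExperimentDesign:
    rows = []
    for construct in constructs:
        for fraction in ("T", "IP"):
            for dye in ("Cy3", "Cy5"):
                rows.append(
                    {
                        "sample_channel_id": f"{cell_line}.{construct}.{fraction}.{dye}",
                        "cell_line": cell_line,
                        "construct": construct,
                        "fraction": fraction,
                        "dye": dye,
                        "replicate": "r1",
                    }
                )
    return ExperimentDesign(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
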