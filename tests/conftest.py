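import numpy as np
import pandas as pd
import pytest

from taxoflux import SimConfig, TreatmentConfig, simulate_dataset


def traits_from_truth(truth) -> pd.DataFrame:
    """Genome-trait table carrying the generator's exact per-taxon traits."""
    return pd.DataFrame({
        "asv_id": truth.taxon_ids,
        "copy_number": truth.copies_per_cell,
        "genome_bp": truth.genome_bp,
        "cell_mass_g": truth.cell_mass_g,
    })


def truth_bounds(config) -> dict:
    """Explicit per-group CUE bounds from the generator configuration."""
    return {(e, t): (trt.cue_min, trt.cue_max)
            for e in config.ecosystems
            for t, trt in config.treatments.items()}


@pytest.fixture(scope="session")
def noiseless_ds():
    """Small zero-noise experiment: one ecosystem, all three treatments,
    13C samples included."""
    cfg = SimConfig(n_taxa=60, seed=11, ecosystems=("E1",),
                    simulate_13c=True).noiseless()
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_ds():
    """Small experiment at the default noise levels (control soils only)."""
    cfg = SimConfig(n_taxa=80, seed=23, ecosystems=("E1",),
                    treatments={"control": TreatmentConfig()},
                    simulate_13c=False)
    return simulate_dataset(cfg)
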