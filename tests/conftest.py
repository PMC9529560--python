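import pytest

from vrascreen.peptides import load_amino_acids, enumerate_dipeptides
from vrascreen.simulate import SimConfig, generate_library, generate_measurements
from vrascreen.viscosity import fit_baseline


@pytest.fixture(scope="session")
def amino_acids():
    return load_amino_acids()


@pytest.fixture(scope="session")
def aa_by_code(amino_acids):
    return {a.code: a for a in amino_acids}


@pytest.fixture(scope="session")
def dipeptides(amino_acids):
    return enumerate_dipeptides(amino_acids)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across read-only tests."""
    cfg = SimConfig(seed=7)
    library = generate_library(cfg)
    measurements, truth = generate_measurements(library, cfg)
    fits = {
        mab: fit_baseline([m for m in measurements if m.mab_id == mab])
        for mab in cfg.mab_params
    }
    return cfg, library, measurements, truth, fits
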