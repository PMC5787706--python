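import numpy as np
import pytest

from galnet import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def no_feedback_params(params):
    """Network with feedback severed: Delta-alpha = 0 for every gene, so each
    gene is an independent leaky birth-death process."""
    from dataclasses import replace

    genes = tuple(replace(g, delta_alpha=0.0) for g in params.genes)
    return type(params)(genes=genes, shared=params.shared)


@pytest.fixture(scope="session")
def gradual_params(params):
    """Parameter set printed for the gradual-regime example."""
    return params.with_gal3(rho=140.0, kgal=0.055)


@pytest.fixture(scope="session")
def binary_params(params):
    """Parameter set printed for the binary-regime example."""
    return params.with_gal3(rho=40.0, kgal=0.055)


@pytest.fixture(scope="session")
def small_study(params):
    """Synthetic two-strain study shared by cytometry/pipeline tests."""
    from galnet import synth

    design = synth.StudyDesign(
        strains={"REF": (140.0, 0.055), "VAR": (40.0, 0.055)},
        concentrations=(0.05, 0.5),
        time_grid=synth.SIX_POINT_GRID,
        replicates=2,
        events_per_sample=4000,
        plate_offsets={"P1": 0.0, "P2": 10.0},
        seed=3,
    )
    events, controls, truth, meta = synth.generate_study(
        design, params, sim_cells=400)
    return dict(design=design, events=events, controls=controls,
                truth=truth, meta=meta)
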