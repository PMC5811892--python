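"""Shared fixtures: the default 7 T acquisition, MM ground truth, a
parameterized MM model and bases built from it.  Session-scoped where
construction is expensive."""

import numpy as np
import pytest

import mrsmm as M


@pytest.fixture(scope="session")
def acq():
    return M.default_acquisition()


@pytest.fixture(scope="session")
def mm_truth(acq):
    return M.MMTruth.default(acq, seed=3)


@pytest.fixture(scope="session")
def mm_model_amares(acq, mm_truth):
    """AMARES MM model parameterized from a clean synthetic nulled FID."""
    nulled = M.generate_metabolite_nulled_spectrum(mm_truth, 0.0, acq)
    return M.parameterize_mm_amares(nulled)


@pytest.fixture(scope="session")
def ratio_priors(acq, mm_truth):
    sd = M.mm_noise_sd_for_snr(mm_truth, acq, 50.0)
    fids = [
        M.generate_metabolite_nulled_spectrum(mm_truth, 0.0, acq, seed=100 + i, noise_sd=sd)
        for i in range(6)
    ]
    return M.derive_ratio_priors(fids)


@pytest.fixture(scope="session")
def basis_ind(acq, mm_model_amares):
    return M.build_basis(M.default_metabolite_groups(), mm_model_amares, acq)


@pytest.fixture(scope="session")
def basis_con(acq, mm_model_amares, ratio_priors):
    con = mm_model_amares.with_ratio_priors(ratio_priors)
    return M.build_basis(M.default_metabolite_groups(), con, acq)


@pytest.fixture(scope="session")
def small_phantom(acq, mm_truth):
    """Noiseless 16x16 phantom without lipids or frequency offsets."""
    return M.generate_mrsi_phantom(
        matrix=16, acq=acq, noise_sd=0.0, seed=5, lipid_ring=False,
        mm_truth=mm_truth, freq_offset_max_hz=0.0,
    )
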