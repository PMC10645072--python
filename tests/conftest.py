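"""Shared fixtures: toy structures, simulated scans, reference profiles."""

import numpy as np
import pytest

from reesfit.csm import CSMProfile
from reesfit.model import REESConstants, REESParams, model_csm
from reesfit.sasa import shrake_rupley
from reesfit.spectra_io import EmissionSpectrum, SampleScan
from reesfit.synthetic import CohortSpec, GroupSpec, NoiseSpec, make_toy_structure

LAMBDA_EX = np.arange(292.0, 311.0)  # default 19-point excitation grid
EMISSION = np.arange(325.0, 501.0)


@pytest.fixture(scope="session")
def constants():
    return REESConstants()


@pytest.fixture
def gaussian_scan():
    """19-spectrum scan of Gaussian bands drifting red with excitation."""
    spectra = []
    for i, lx in enumerate(LAMBDA_EX):
        center = 353.0 + 0.15 * i
        f = np.exp(-0.5 * ((EMISSION - center) / 25.0) ** 2)
        spectra.append(EmissionSpectrum(float(lx), EMISSION, f))
    return SampleScan(
        sample_id="s1", group_label="G", replicate_index=1, spectra=tuple(spectra), n_trp=22
    )


def profile_from_params(params, sample_id="s", group="G", replicate=1,
                        constants=REESConstants(), lx=LAMBDA_EX):
    """Noise-free CSM profile evaluated directly from the sigmoid."""
    return CSMProfile(
        sample_id=sample_id,
        group_label=group,
        replicate_index=replicate,
        excitation_wavelengths=np.asarray(lx, dtype=float),
        csm=model_csm(np.asarray(lx, dtype=float), params, constants),
    )


@pytest.fixture
def reference_params():
    """Parameters at the scale of the measured antibody profiles."""
    return REESParams(csm_fc=352.9, m=470.0, lambda50=320.0, csm_r=418.9)


@pytest.fixture
def noise_free_spec():
    return CohortSpec(
        groups=(GroupSpec("G", 1, (352.9, 0.0), (470.0, 0.0), (320.0, 0.0), 418.9),),
        noise=NoiseSpec(),
    )


@pytest.fixture(scope="session")
def toy_sasa():
    """Toy structures with their per-atom SASA, computed once."""
    out = {}
    for kind in ("isolated-trp", "two-isolated-trp", "buried-trp", "homodimer-two-rotamers"):
        structure = make_toy_structure(kind)
        out[kind] = (structure, shrake_rupley(structure))
    return out
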