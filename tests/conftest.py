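import numpy as np
import pytest

from qsmcohort import (AcquisitionParams, build_phantom, phantom_recon_config,
                       reconstruct_qsm, simulate_cohort, simulate_gre,
                       two_sphere_scene)
from qsmcohort.phantom import CohortSpec, external_chi

TRUE_CHI = {"paramagnetic_nucleus": 0.10, "diamagnetic_nucleus": -0.015}


@pytest.fixture(scope="session")
def two_sphere_truth():
    spec = two_sphere_scene(64)
    return spec, build_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_recon(two_sphere_truth):
    """Noiseless end-to-end reconstruction of the reference phantom."""
    spec, truth = two_sphere_truth
    gre = simulate_gre(truth, AcquisitionParams(snr=np.inf), external_chi(spec))
    result = reconstruct_qsm(gre, truth.brain_mask, truth.ventricle_mask,
                             phantom_recon_config(), return_intermediates=True)
    return spec, truth, gre, result


@pytest.fixture(scope="session")
def cohort_table():
    return simulate_cohort(CohortSpec(seed=42))
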