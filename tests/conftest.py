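import numpy as np
import pytest

from lungt1dce import phantom as ph
from lungt1dce.pipeline import RunConfig, make_subject


@pytest.fixture(scope="session")
def truth_2d():
    """Noiseless-parameter phantom truth on a 64x64 UTE grid."""
    return ph.make_phantom(ph.default_ute_grid(64),
                           ph.PhantomParams(defect_fraction=0.2), seed=1)


@pytest.fixture(scope="session")
def noiseless_config():
    return RunConfig(snr=0.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_config):
    """One noiseless phantom subject with a designed 20% defect fraction."""
    return make_subject(noiseless_config, seed=42, subject_id=0,
                        params=ph.PhantomParams(defect_fraction=0.20))


@pytest.fixture(scope="session")
def dce_chain(noiseless_config, noiseless_subject):
    """Concentration, AIF, residuals, and PBF for the noiseless subject."""
    from lungt1dce import dce_perfusion as dp

    conc = dp.to_concentration(noiseless_subject.dce_series,
                               noiseless_config.n_baseline)
    aif = dp.detect_aif(conc, noiseless_subject.dce_body_mask)
    resid = dp.deconvolve(conc, aif, noiseless_subject.dce_segmentation,
                          noiseless_config.svd_lambda)
    pbf = dp.compute_pbf(resid)
    return {"conc": conc, "aif": aif, "resid": resid, "pbf": pbf}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)
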