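import warnings

import pytest
from hypothesis import settings

from wormsrna.simulate import scaled_config, simulate_dataset

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_dataset():
    """One scaled synthetic study shared across tests (fixed seed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(scaled_config(seed=11))


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """A complete scaled pipeline run: every stage output on disk."""
    from wormsrna.cli import run_all

    outdir = tmp_path_factory.mktemp("pipeline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_all(outdir, seed=11, sim_config=scaled_config())
    return outdir
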