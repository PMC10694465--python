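import numpy as np
import pytest

from heatlabor.erf import ERFParams
from heatlabor.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def truth_params():
    """A known exposure-response truth set used to generate tables."""
    return ERFParams(
        prodmean={200: 36.0, 300: 33.0, 400: 31.0},
        prodsd={200: 4.5, 300: 4.0, 400: 3.5},
        provenance="synthetic-truth",
    )


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    """One full pipeline run on the toy domain, shared across tests.

    8x8 grid, 2 pseudo-GCMs, 1986-2100 sampled every 5th year, all three
    emission scenarios, default seed.
    """
    outdir = tmp_path_factory.mktemp("run") / "std"
    cfg = RunConfig(outdir=str(outdir), seed=0)
    manifest = run_pipeline(cfg)
    return cfg, manifest


def rng(seed=0):
    return np.random.default_rng(seed)
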