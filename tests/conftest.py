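import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tsgkit.pipeline import PipelineConfig, run_pipeline
from tsgkit.simulate import SyntheticConfig, simulate_study

#: one fixed seed for the shared study bundle used across the suite
BUNDLE_SEED = 20260922


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A default synthetic study bundle shared by the whole session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_study(SyntheticConfig(seed=BUNDLE_SEED), outdir)


@pytest.fixture(scope="session")
def pipeline_report(bundle, tmp_path_factory):
    """A full pipeline run over the shared bundle."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig.from_bundle(bundle, outdir)
    return run_pipeline(config)
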