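import pytest

from crelicense import SyntheticConfig, generate
from crelicense.cli import write_bundle_config
from crelicense.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Noise-free planted bundle: 100 genes, 10 licensed, 5 per partial class."""
    outdir = tmp_path_factory.mktemp("bundle")
    b = generate(SyntheticConfig(seed=11), outdir)
    write_bundle_config(b, outdir / "config.yaml")
    return b


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    config = PipelineConfig.from_yaml(bundle.paths["gene_table"].parent / "config.yaml")
    return run_pipeline(config)
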