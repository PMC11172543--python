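import numpy as np
import pytest

from burdenscan.synthetic import GroupSpec, SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A 50-sample x 200-locus bundle with 20 planted deleterious loci."""
    cfg = SyntheticConfig(n_samples=50, n_loci=200, n_dsnp=20, seed=7)
    return cfg, generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    _, bundle = small_bundle
    outdir = tmp_path_factory.mktemp("bundle")
    return bundle, bundle.write(outdir)


@pytest.fixture(scope="session")
def grouped_bundle():
    """A bundle with planted group effects and zero-burden samples."""
    cfg = SyntheticConfig(
        n_samples=120,
        n_loci=400,
        n_dsnp=40,
        seed=11,
        groups=(
            GroupSpec("Landrace", 60, effect=0.5),
            GroupSpec("Cultivar", 60, effect=0.0),
        ),
        n_zero_burden=5,
    )
    return cfg, generate_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
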