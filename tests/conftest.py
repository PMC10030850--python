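import numpy as np
import pytest

from omicsubtyper.autoencoder import AEArchitecture, AETrainConfig, encode, train_autoencoder
from omicsubtyper.preprocess import PreprocessConfig, preprocess_omic, stack_omics
from omicsubtyper.simulate import SimConfig, simulate_clinical, simulate_multiomics
from omicsubtyper.types import OmicKind, OmicMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_omic(values, kind=OmicKind.F4_PROTEIN, sample_prefix="s", feature_prefix="f"):
    values = np.asarray(values, dtype=float)
    return OmicMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(values.shape[0])],
        feature_ids=[f"{feature_prefix}{j}" for j in range(values.shape[1])],
        values=values,
        kind=kind,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Shared end-to-end run on the 5-cluster synthetic dataset (n=300,
    effect 3): simulate -> preprocess -> AE -> latent. Session-scoped because
    several acceptance checks reuse it."""
    cfg = SimConfig(n_samples=300, effect_size=3.0, seed=1)
    omics, truth = simulate_multiomics(cfg)
    pp = PreprocessConfig(top_n_variable=200)
    processed = {k: preprocess_omic(m, pp) for k, m in omics.items()}
    stack = stack_omics(list(processed.values()))
    arch = AEArchitecture(encoder_widths=[64, 32], latent_width=16)
    enc = train_autoencoder(stack, arch, AETrainConfig(max_epochs=50, patience=5, seed=2))
    latent = encode(enc, stack)
    return {
        "config": cfg,
        "omics": omics,
        "processed": processed,
        "truth": truth,
        "stack": stack,
        "latent": latent,
    }
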