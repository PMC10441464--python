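import numpy as np
import pytest

from autosurv.pathways import PathwayMask
from autosurv.simulate import SyntheticSpec, generate
from autosurv.vae import KLPMVAE, VAEConfig


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-signal cohort shared by read-only tests."""
    spec = SyntheticSpec(
        n_samples=120, n_genes=60, n_mirnas=12, n_pathways=8,
        genes_per_pathway_range=(6, 10), seed=11,
    )
    return generate(spec)


@pytest.fixture()
def toy_mask():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(10)]
    pws = [f"p{j}" for j in range(3)]
    mask = (rng.random((10, 3)) < 0.4).astype(float)
    mask[0, :] = 1.0  # ensure no empty pathway / orphan gene row 0
    return PathwayMask(genes, pws, mask)


@pytest.fixture()
def toy_vae(toy_mask):
    """Briefly trained small two-omics VAE."""
    cfg = VAEConfig(n_latent=3, trunk_hidden=6, epochs=8, batch_size=16,
                    learning_rate=5e-3)
    model = KLPMVAE(toy_mask, 4, cfg, seed=7)
    rng = np.random.default_rng(8)
    xg = rng.random((40, toy_mask.n_genes))
    xm = rng.random((40, 4))
    model.fit(xg, xm, seed=9)
    return model, xg, xm
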