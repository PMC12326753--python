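"""Shared fixtures: small simulated datasets and reference matrices."""

import numpy as np
import pytest

import mclogdet as mc


def random_spd(n: int, kappa: float, seed: int = 0) -> np.ndarray:
    """Random SPD matrix with log-uniform spectrum and condition ~kappa."""
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    lam = np.exp(np.linspace(0.0, np.log(kappa), n)) / np.sqrt(kappa)
    M = (Q * lam) @ Q.T
    return 0.5 * (M + M.T)


@pytest.fixture(scope="session")
def trio_ped() -> mc.Pedigree:
    """Two unrelated founders and their offspring."""
    return mc.Pedigree(sire=np.array([0, 0, 1]), dam=np.array([0, 0, 2]))


@pytest.fixture(scope="session")
def small_frame() -> mc.ModelFrame:
    """~380-animal single-step dataset (animal model + contemporary groups)."""
    spec = mc.SimSpec(
        n_founders=60, n_generations=4, n_offspring=80, n_snp=300,
        prop_genotyped=0.2, n_cg=10, seed=42,
        true_varcomps={"animal": 0.3, "residual": 0.7},
    )
    return mc.simulate_dataset(spec)


@pytest.fixture(scope="session")
def pedigree_frame() -> mc.ModelFrame:
    """Pedigree-only dataset (no genotypes) for A-based models."""
    spec = mc.SimSpec(
        n_founders=50, n_generations=4, n_offspring=70, n_snp=10,
        prop_genotyped=0.0, n_cg=8, seed=7,
        true_varcomps={"animal": 0.4, "residual": 0.6},
    )
    return mc.simulate_dataset(spec)


@pytest.fixture(scope="session")
def ped200() -> mc.Pedigree:
    spec = mc.SimSpec(n_founders=40, n_generations=4, n_offspring=40, seed=5)
    return mc.simulate_pedigree(spec)
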