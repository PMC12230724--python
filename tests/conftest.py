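import numpy as np
import pytest

from cdsk.deconv import BasisMatrixSet, SSVector, evaluate_model
from cdsk.synthetic import SynthConfig, gen_basis_truth, gen_reference_set


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    rho = np.nonzero(u - css / idx > 0)[0][-1]
    return np.maximum(v - css[rho] / (rho + 1), 0.0)


def fista_simplex_lstsq(B: np.ndarray, y: np.ndarray, iters: int = 4000) -> np.ndarray:
    """Independent QP oracle: accelerated projected gradient on the simplex."""
    G = B.T @ B
    h = B.T @ y
    L = float(np.linalg.eigvalsh(G).max()) + 1e-12
    x = np.full(B.shape[1], 1.0 / B.shape[1])
    z = x.copy()
    t = 1.0
    for _ in range(iters):
        x_new = project_simplex(z - (G @ z - h) / L)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + (t - 1.0) / t_new * (x_new - x)
        x, t = x_new, t_new
    return x


@pytest.fixture(scope="session")
def truth_model() -> BasisMatrixSet:
    """Ground-truth quadratic basis-matrix set (190-250 nm)."""
    return gen_basis_truth(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def small_refset(truth_model):
    """12-protein noiseless reference set on the truth model's grid."""
    cfg = SynthConfig(seed=42, n_proteins=12, noise_sigma=0.0)
    return gen_reference_set(cfg, truth_model)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exact_spectrum(truth_model):
    """A noise-free spectrum with known composition."""
    ss = SSVector(np.array([0.30, 0.10, 0.05, 0.10, 0.05, 0.10, 0.10, 0.20]))
    return ss, evaluate_model(truth_model, ss)
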