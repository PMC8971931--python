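import numpy as np
import pytest

from allostate.synthetic_data import (
    ElasticNetworkSpec,
    generate_enm_ensemble,
    two_domain_spec,
)


@pytest.fixture(scope="session")
def bent_three_bead_spec() -> ElasticNetworkSpec:
    """Non-collinear 3-bead chain with unit springs at 300 K."""
    pos = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [5.5, 3.0, 1.0]])
    return ElasticNetworkSpec(
        n_residues=3,
        positions0=pos,
        spring_pairs=[(0, 1, 1.0), (1, 2, 1.0)],
        temperature=300.0,
    )


@pytest.fixture(scope="session")
def three_bead_ensemble(bent_three_bead_spec):
    """10^5-frame sample plus its analytic covariance."""
    return generate_enm_ensemble(bent_three_bead_spec, n_frames=100_000, seed=1)


@pytest.fixture(scope="session")
def two_domain_system():
    """Planted two-domain elastic network and a 20k-frame sample."""
    spec = two_domain_spec()
    ens, cov = generate_enm_ensemble(spec, n_frames=20_000, seed=3)
    return spec, ens, cov


def brute_force_rmsd(mobile: np.ndarray, reference: np.ndarray, n: int = 100_000):
    """Minimum RMSD over SO(3): dense random rotation sampling followed by
    simplex refinement of the best rotation vector, with the optimal
    translation (centroid matching) — an independent oracle for the
    Kabsch fit that never touches the SVD construction."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((mc @ R.T - rc) ** 2, axis=1))))

    rots = Rotation.random(n, random_state=0)
    fitted = np.einsum("rij,nj->rni", rots.as_matrix(), mc)
    rms = np.sqrt(np.mean(np.sum((fitted - rc) ** 2, axis=2), axis=1))
    start = rots[int(np.argmin(rms))].as_rotvec()
    res = minimize(cost, start, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return float(res.fun)
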