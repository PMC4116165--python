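import numpy as np
import pytest

from nemagrn import gene_circuit as gc
from nemagrn import synthetic_data as sd
from nemagrn.morphology import annulus_morphology


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def annulus():
    """Circular cell layer centered on a 200x200 canvas, oral pole right."""
    return annulus_morphology(center=(100.0, 100.0), r_inner=40.0, r_outer=60.0,
                              n_points=128, stage_hours=24.0)


@pytest.fixture
def two_gene_reference():
    """Noiseless reference simulated from a known strongly-coupled circuit."""
    truth = gc.GeneCircuitParams(
        ("A", "B"),
        T=np.array([[-4.5, -4.5], [4.5, -4.5]]),
        m=np.array([4.5, -4.5]),
        h=np.array([-1.0, -1.0]),
        lam=np.array([0.6, 1.0]),
    )
    maternal = sd.make_template("maternal", n_points=30).values
    ref = sd.generate_reference_from_circuit(truth, maternal, (0.0, 25.0, 50.0))
    return truth, ref


@pytest.fixture
def three_gene_reference():
    """Noiseless 3-gene reference from the demonstration gut circuit."""
    truth = sd.demo_gut_circuit()
    maternal = sd.make_template("maternal", n_points=25).values
    ref = sd.generate_reference_from_circuit(truth, maternal, (0.0, 25.0, 50.0))
    return truth, ref


def random_params(rng, n=3, gene_names=None, lam_range=(0.05, 1.0), scale=3.0):
    """Random circuit parameters within the fitting bounds."""
    names = gene_names or tuple(f"g{i}" for i in range(n))
    return gc.GeneCircuitParams(
        names,
        T=rng.uniform(-scale, scale, (n, n)),
        m=rng.uniform(-scale, scale, n),
        h=rng.uniform(-scale, scale, n),
        lam=rng.uniform(*lam_range, n),
    )
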