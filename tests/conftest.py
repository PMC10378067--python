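import numpy as np
import pytest

from thermoparam import pipeline
from thermoparam.io import TemperatureMesh, ThermogramCurve
from thermoparam.simulate import GeneratorConfig, generate_cohort


def gaussian_mix_curve(
    centers=(63.0, 70.0, 75.0),
    sigmas=(1.8, 1.6, 2.2),
    amps=(0.26, 0.30, 0.10),
    sample_id="fixture",
    baseline=0.0,
):
    """Noise-free sum-of-Gaussians thermogram on the canonical mesh."""
    mesh = TemperatureMesh.canonical()
    t = mesh.values
    cp = np.full(t.size, float(baseline))
    for mu, sig, a in zip(centers, sigmas, amps):
        cp = cp + a * np.exp(-((t - mu) ** 2) / (2.0 * sig**2))
    return ThermogramCurve(sample_id, mesh, cp)


@pytest.fixture(scope="session")
def canonical_mesh():
    return TemperatureMesh.canonical()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def cohort_table(default_cohort):
    return pipeline.build_cohort_table(
        default_cohort.curves, default_cohort.clinical, n_pcs=5
    )
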