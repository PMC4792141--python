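import numpy as np
import pytest

from regulonminer.model import Genome, Operon, Pwm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_pwm(rng, width, sharp=False):
    """A random column-stochastic PWM; sharp=True gives consensus-like columns."""
    alpha = np.full(4, 0.3) if sharp else np.ones(4)
    return Pwm(matrix=rng.dirichlet(alpha, size=width))


def site_pwm(rng, width, n_sites=10):
    """PWM estimated from random aligned sites (the similarity-null object)."""
    sites = rng.integers(0, 4, size=(n_sites, width))
    counts = np.full((width, 4), 0.5)
    for j in range(width):
        counts[j] += np.bincount(sites[:, j], minlength=4)
    return Pwm(matrix=counts / counts.sum(axis=1, keepdims=True), n_instances=n_sites)


@pytest.fixture
def toy_genome():
    """Two-operon plus-strand genome with a 150 bp intergenic gap."""
    seq = "A" * 850 + "C" * 149 + "G" * 501
    ops = [
        Operon("opA", "g", ("a1",), "+", 1, 850),
        Operon("opB", "g", ("b1", "b2"), "+", 1000, 1400),
    ]
    return Genome(genome_id="g", sequence=seq, operons=ops)


# --- shared end-to-end runs (expensive; session scope) ---------------------


@pytest.fixture(scope="session")
def standard_run():
    """The canonical benchmark dataset and one full pipeline run on it."""
    from regulonminer.pipeline import RunConfig, run_pipeline
    from regulonminer.simulate import standard_fixture

    fx = standard_fixture()
    res = run_pipeline(
        fx.target_genome, fx.ref_operons, fx.orthology, fx.ref_promoters, RunConfig()
    )
    return fx, res
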