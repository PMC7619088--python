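import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_class_scores():
    """Scores drawn from three well-separated Gaussians, with labels."""
    rng = np.random.default_rng(7)
    x = np.concatenate(
        [
            rng.normal(-8.0, 0.5, 1000),
            rng.normal(-4.0, 0.5, 1000),
            rng.normal(0.0, 0.5, 1000),
        ]
    )
    labels = np.repeat(["impactful", "mild", "neutral"], 1000)
    return x, labels


@pytest.fixture()
def toy_msa_file(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">q\nACDE\n>h1\nACDE\n>h2\nAC-E\n>h3\nGCDE\n")
    return path


@pytest.fixture(scope="session")
def dimer_structure(tmp_path_factory):
    from proteocast.simulate import generate_toy_structure

    path = tmp_path_factory.mktemp("pdb") / "dimer.pdb"
    path.write_text(
        generate_toy_structure("ACDEFWKLMNPQRST", "extended", n_chains=2)
    )
    return path
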