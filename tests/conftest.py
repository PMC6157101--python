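import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_spd(rng, n, cond=10.0):
    """Random symmetric positive-definite matrix with bounded conditioning."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    w = np.exp(rng.uniform(0, np.log(cond), n))
    return (Q * w) @ Q.T


@pytest.fixture
def spd_factory(rng):
    return lambda n, cond=10.0: random_spd(rng, n, cond)


@pytest.fixture
def three_generation_ped():
    """Founders A,B,C,D; sibs E,F (A x B); G (C x D); cousins via E x G."""
    from jcar.kinship import Pedigree

    ids = ["A", "B", "C", "D", "E", "F", "G", "H", "I"]
    father = {i: None for i in "ABCD"}
    mother = {i: None for i in "ABCD"}
    for child in ("E", "F"):
        father[child], mother[child] = "A", "B"
    father["G"], mother["G"] = "C", "D"
    # H: child of E and G; I: child of F and a founder-unknown mate
    father["H"], mother["H"] = "E", "G"
    father["I"], mother["I"] = "F", None
    return Pedigree(ids=ids, father=father, mother=mother)
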