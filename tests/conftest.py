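import numpy as np
import pytest

from rebelscan import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_superfamily():
    """6 members, 80-residue core, one 12-residue insertion in member 3."""
    spec = sd.SyntheticSpec(
        n_members=6, core_length=80, noise_sd=0.3,
        outlier_plan=((3, (sd.Perturbation.insertion(40, 12),)),),
        seed=7)
    return sd.make_superfamily(spec)


@pytest.fixture(scope="session")
def planted_superfamily():
    """10 members, 120-residue core, canonical two-hinge outlier on mem00."""
    spec = sd.SyntheticSpec(
        n_members=10, core_length=120, noise_sd=0.3,
        outlier_plan=((0, sd.plant_two_hinge_outlier(120)),),
        seed=11)
    return sd.make_superfamily(spec)


def write_pdb(path, text):
    path.write_text(text)
    return path


@pytest.fixture
def three_ca_pdb(tmp_path):
    """Minimal fixture: 3 CA records at (0,0,0), (3.8,0,0), (7.6,0,0)."""
    text = "\n".join([
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",  # noqa: E501
        "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C",  # noqa: E501
        "ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C",  # noqa: E501
        "END",
    ]) + "\n"
    return write_pdb(tmp_path / "three.pdb", text)
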