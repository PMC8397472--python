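import pytest

from peptidology import TriadSpec, fixture_pashinintides, generate_triad


@pytest.fixture(scope="session")
def pashinintides():
    """(triads, property tables) for the two published cyclopeptides."""
    return fixture_pashinintides()


@pytest.fixture(scope="session")
def triad_a(pashinintides):
    return pashinintides[0][0]


@pytest.fixture(scope="session")
def triad_b(pashinintides):
    return pashinintides[0][1]


@pytest.fixture
def small_spec():
    """A 3-atom synthetic spec with known Fukui targets and deviations."""
    return TriadSpec(
        molecule_id="toy",
        n_atoms=3,
        eps_H=-6.0,
        eps_L=-1.5,
        delta_I=0.02,
        delta_A=0.05,
        somo_offset=-0.1,
        f_plus_target=(0.6, 0.3, 0.1),
        f_minus_target=(0.2, 0.5, 0.3),
        seed=7,
    )


@pytest.fixture
def small_triad(small_spec):
    return generate_triad(small_spec)
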