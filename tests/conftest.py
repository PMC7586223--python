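import pytest

from cbhkin import presets, simulate


@pytest.fixture(scope="session")
def intact_truth():
    return presets.intact_truth()


@pytest.fixture(scope="session")
def small_field():
    """20 single-bundle fibrils, ~5 um, for trajectory simulations."""
    return simulate.make_fibril_field(20, 5.0, 1.0, {1: 1.0}, seed=11)


@pytest.fixture(scope="session")
def dwell_movie():
    """Bleach-free binding movie at a concentration giving ~7500 dwells."""
    return presets.binding_movie(bleach_rate=0.0, enzyme_conc=2e-10)


@pytest.fixture(scope="session")
def dwell_field():
    return simulate.make_fibril_field(50, 5.0, 1.0, {1: 1.0}, seed=7)


@pytest.fixture(scope="session")
def intact_events(intact_truth, dwell_field, dwell_movie):
    """A large bleach-free event table from the full-length-enzyme truth."""
    return simulate.simulate_binding(intact_truth, dwell_field, dwell_movie, seed=13)


@pytest.fixture(scope="session")
def intact_trajectories(intact_truth, small_field):
    """500 purely processive tracks at 1 fps with realistic noise."""
    cond = presets.motility_movie()
    traj = simulate.simulate_trajectories(
        intact_truth, small_field, cond, n_tracks=500, frac_processive=1.0, seed=17
    )
    return traj, cond
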