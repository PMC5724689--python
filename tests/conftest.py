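import numpy as np
import pytest

from exflex.benchmark import build_complex_templates, ensemble_scenario, spectra_scenario
from exflex.synthetic import EnsembleScenario, generate_ensemble, generate_titration


@pytest.fixture(scope="session")
def mc18_templates():
    return build_complex_templates("MC18")


@pytest.fixture(scope="session")
def noiseless_series_L():
    return generate_titration(spectra_scenario("L", seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_two_state_traj():
    """10k-frame two-state ensemble with well-separated states, no stickiness."""
    templates, names, groups = build_complex_templates("MC18")
    scn = EnsembleScenario(
        state_templates=templates,
        state_populations=np.array([0.7, 0.3]),
        atom_groups=groups,
        atom_names=names,
        jitter_sd=0.05,
        n_frames=10_000,
        markov_stickiness=0.0,
        seed=42,
    )
    return scn, generate_ensemble(scn)
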