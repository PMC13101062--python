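import numpy as np
import pytest

from oraltriage import CohortConfig, LesionEffect, generate_cohort, render_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-label high-prevalence cohort with rendered captures."""
    cfg = CohortConfig(
        cohort="high_prevalence",
        n_patients=8,
        sites_per_patient=3,
        exact_refer_sites=10,
        exact_contralateral=2,
        captures_per_site=(1, 2),
        image_size=64,
        lesion_effect=LesionEffect(wl_contrast=0.5, af_loss=0.6),
        seed=7,
    )
    patients, sites = generate_cohort(cfg)
    pairs = render_cohort(sites, cfg)
    return cfg, patients, sites, pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One full tiny-profile pipeline run shared across tests."""
    from oraltriage.pipeline import run_all, tiny_ci_profile

    out = tmp_path_factory.mktemp("tiny_run")
    config = tiny_ci_profile(str(out), seed=0)
    state = run_all(config)
    return config, state
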