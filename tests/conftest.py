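import numpy as np
import pytest

from admixld import forward, psd


@pytest.fixture(scope="session")
def small_linked_world():
    """Tiny shared scenario for linked-locus module tests."""
    gmap = forward.GeneticMap.uniform(300, 50_000_000, 1e-8)
    rng = np.random.default_rng(101)
    p_anc = rng.uniform(0.2, 0.8, gmap.n_loci)
    freqs = forward.ancestral_freqs(p_anc, (0.15, 0.15), seed=rng, clip=1 / 1200)
    panels = [
        forward.simulate_panel(freqs.freqs[l], gmap, 0.05, 600, seed=rng,
                               label=f"anc{l}", fst=0.15)
        for l in range(2)
    ]
    return {"gmap": gmap, "freqs": freqs, "panels": panels}


@pytest.fixture(scope="session")
def psd_cohort():
    rng = np.random.default_rng(7)
    g = rng.uniform(0.1, 0.9, size=(2, 40))
    return psd.simulate_cohort(1500, 40, ("dirichlet", (8.0, 2.0)), g, seed=42)


# --- session-scoped experiment reports shared by the acceptance tests ------


@pytest.fixture(scope="session")
def power_report():
    from admixld.experiments import run_power_experiment

    return run_power_experiment(seed=1)


@pytest.fixture(scope="session")
def concordance_report():
    from admixld.experiments import run_concordance_experiment

    return run_concordance_experiment(seed=1)


@pytest.fixture(scope="session")
def ld_report():
    from admixld.experiments import run_ld_experiment

    return run_ld_experiment(seed=1)
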