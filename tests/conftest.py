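import numpy as np
import pandas as pd
import pytest

from ftx import diffexpr, simulate


@pytest.fixture(scope="session")
def small_config():
    """Compact study: fast enough for per-test simulation."""
    return simulate.SimulationConfig(seed=7, n_genes=400, frac_de_28m=0.1, n_coupled=30)


@pytest.fixture(scope="session")
def sim_study(small_config):
    fn, counts, meta, truth = simulate.simulate_study(small_config)
    return {"fn": fn, "counts": counts, "meta": meta, "truth": truth, "config": small_config}


@pytest.fixture(scope="session")
def contrast_28m(sim_study):
    """DE inputs for the 6m-vs-28m contrast (run 2 samples)."""
    meta = sim_study["meta"]
    sel = meta[meta["run"] == 2]
    counts = diffexpr.CountMatrix(sim_study["counts"][sel.index])
    factors = diffexpr.size_factors(counts)
    disp = diffexpr.estimate_dispersions(counts, factors, sel["age_group"].to_numpy())
    de = diffexpr.wald_test(counts, factors, disp, sel["age_group"].to_numpy(), reference="6m")
    norm = diffexpr.normalized_log2(counts, factors)
    return {"meta": sel, "counts": counts, "factors": factors, "disp": disp, "de": de, "norm": norm}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
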