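import numpy as np
import pytest

from mitomethyl import medip, synthetic


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy array simulation shared by several tests."""
    cfg = synthetic.SimConfig(
        n_genes=200, probes_per_gene=2, noise_sd=0.3, n_replicates=2, rng_seed=11
    )
    truth = synthetic.default_truth(cfg, n_per_line=5, seed=12)
    arrays, annotation, truth_table = synthetic.gen_cpg_arrays(cfg, truth)
    return cfg, truth, arrays, annotation, truth_table


def arrays_by_line(arrays, cfg, lines=synthetic.LINES):
    return {ln: [arrays[(ln, r)] for r in range(cfg.n_replicates)] for ln in lines}


@pytest.fixture(scope="session")
def zero_noise_calls():
    """Full zero-noise pipeline run: calls, exclusive sets, truth."""
    cfg = synthetic.SimConfig(
        n_genes=300, probes_per_gene=2, noise_sd=0.0, n_replicates=2, rng_seed=5
    )
    truth = synthetic.default_truth(cfg, n_per_line=10, seed=6)
    arrays, annotation, truth_table = synthetic.gen_cpg_arrays(cfg, truth)
    calls, exclusive, shared = medip.call_per_line(
        arrays_by_line(arrays, cfg), annotation
    )
    return cfg, truth, truth_table, calls, exclusive, shared
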