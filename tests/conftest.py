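import numpy as np
import pytest

import methylctcf as m


@pytest.fixture(scope="session")
def ctcf_motif():
    return m.load_ctcf_motif()


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic epigenome at default conditions, shared read-only."""
    return m.simulate_all(m.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_consensus(default_sim):
    n_rep = default_sim.config.replicates_per_condition
    return m.consensus_sites(
        [default_sim.peaks[("WT", r)] for r in range(n_rep)],
        [default_sim.peaks[("DKO", r)] for r in range(n_rep)],
    )


@pytest.fixture(scope="session")
def default_motif_sites(default_sim, default_consensus, ctcf_motif):
    return m.scan_motifs(
        [c for c in default_consensus if c.category in ("common", "lost")],
        default_sim.bundle.sequences,
        ctcf_motif,
    )


@pytest.fixture(scope="session")
def default_occupancy(default_sim):
    n_rep = default_sim.config.replicates_per_condition
    cl = default_sim.bundle.chrom_lengths
    wt = m.occupancy_track([default_sim.fragments[("WT", r)] for r in range(n_rep)], cl)
    dko = m.occupancy_track([default_sim.fragments[("DKO", r)] for r in range(n_rep)], cl)
    return wt, dko


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
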