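import warnings

import numpy as np
import pytest

from meiorec import binning
from meiorec.binning import BinTable, make_bins
from meiorec.contacts import ContactMatrix
from meiorec.simulate import (
    SimConfig,
    simulate_contacts,
    simulate_genome,
    simulate_peaks_and_tracks,
)


@pytest.fixture(scope="session")
def small_bins() -> BinTable:
    """Two tiny chromosomes, 5-kb bins (last bin truncated on chrB)."""
    return make_bins({"chrA": 50_000, "chrB": 42_001}, 5000)


@pytest.fixture(scope="session")
def mini_config() -> SimConfig:
    """Reduced synthetic genome used across unit tests: one 20-Mb
    chromosome, scaled-down depth and peak counts."""
    return SimConfig(
        chrom_lengths=(20_000_000,),
        n_prdm9_peaks=600,
        n_crossovers=400,
        read_depth=1.6e6,
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_genome(mini_config):
    return simulate_genome(mini_config)


@pytest.fixture(scope="session")
def mini_contacts(mini_config, mini_genome):
    bins, truth, _, _ = mini_genome
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_contacts(bins, truth, mini_config, "zygonema")


@pytest.fixture(scope="session")
def mini_peaks(mini_config, mini_genome):
    bins, truth, _, _ = mini_genome
    return simulate_peaks_and_tracks(bins, truth, mini_config)


@pytest.fixture(scope="session")
def mini_activity_ref(mini_genome):
    bins, _, chromhmm, _ = mini_genome
    states = binning.chromhmm_overlap_tracks(chromhmm, bins)
    return binning.BinnedTrack(
        "activity_ref",
        np.sum([states[s].values for s in binning.ACTIVE_STATES], axis=0),
    )


def dense_contact_matrix(values: np.ndarray, trans=None, bin_size=5000) -> ContactMatrix:
    """Wrap one dense symmetric matrix as a single-chromosome ContactMatrix."""
    n = values.shape[0]
    bins = make_bins({"chr1": n * bin_size}, bin_size)
    cis = values.sum(axis=1)
    if trans is None:
        trans = np.zeros(n)
    return ContactMatrix(
        bins, {"chr1": values}, cis, np.asarray(trans, dtype=float),
        valid=np.ones(n, dtype=bool),
    )
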