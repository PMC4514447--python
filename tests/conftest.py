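"""Shared fixtures: the standard simulated benchmark and trained models.

Training runs are expensive relative to the rest of the suite, so each is a
session-scoped fixture reused by every test that needs it.
"""

from __future__ import annotations

import numpy as np
import pytest

from countseg import ChromatinHMM, match_accuracy
from countseg.binning import count_positions, make_bins
from countseg.synthetic import (
    make_default_fixture,
    simulate,
    simulate_read_positions,
    simulate_replicates,
)

FIXTURE_SEED = 11
FIT_SEED = 7


@pytest.fixture(scope="session")
def fixture_spec():
    return make_default_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_data(fixture_spec):
    """(counts, truth segmentation) of the 3-state / 4-mark benchmark."""
    return simulate(fixture_spec)


@pytest.fixture(scope="session")
def fixture_results(fixture_data):
    """NM-HMM fitted on the benchmark counts."""
    counts, _ = fixture_data
    return ChromatinHMM(counts, 3).fit(seed=FIT_SEED)


@pytest.fixture(scope="session")
def replicate_results(fixture_spec):
    """Truth path plus two models fitted on independent emission replicates."""
    truth, (rep_a, rep_b) = simulate_replicates(fixture_spec, 2)
    res_a = ChromatinHMM(rep_a, 3).fit(seed=FIT_SEED)
    res_b = ChromatinHMM(rep_b, 3).fit(seed=FIT_SEED)
    return truth, res_a, res_b


@pytest.fixture(scope="session")
def unrelated_results(fixture_spec):
    """A model fitted on a simulation with an unrelated hidden path."""
    spec = make_default_fixture(FIXTURE_SEED + 1000)
    counts, truth = simulate(spec)
    return truth, ChromatinHMM(counts, 3).fit(seed=FIT_SEED)


@pytest.fixture(scope="session")
def binshift_results(fixture_data):
    """Segmentations of the same reads binned at offsets 0 and 100."""
    counts, _ = fixture_data
    positions = simulate_read_positions(counts, np.random.default_rng(FIXTURE_SEED + 1))
    scheme0 = counts.scheme
    scheme100 = make_bins(scheme0.lengths, bin_size=scheme0.bin_size, offset=100)
    counts0 = count_positions(positions, scheme0, counts.mark_names)
    counts100 = count_positions(positions, scheme100, counts.mark_names)
    assert all(
        np.array_equal(counts0.counts[c], counts.counts[c]) for c in scheme0.chrom_names
    )
    res0 = ChromatinHMM(counts0, 3).fit(seed=FIT_SEED)
    res100 = ChromatinHMM(counts100, 3).fit(seed=FIT_SEED)
    return res0.decode(), res100.decode()


@pytest.fixture(scope="session")
def fixture_accuracy(fixture_results, fixture_data):
    _, truth = fixture_data
    return match_accuracy(fixture_results.decode(), truth)
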