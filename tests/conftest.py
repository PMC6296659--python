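import itertools

import numpy as np
import pytest

from exocnv import make_capture_design, simulate_counts
from exocnv.depth import hmm_log_params


@pytest.fixture(scope="session")
def design4():
    """Small four-chromosome design (chr1, chr2, chrX, chrY)."""
    return make_capture_design(4, 60, 200, seed=11)


@pytest.fixture(scope="session")
def design_wide():
    """26-chromosome design: each chromosome is ~4% of the capture, close
    to the share of a real small chromosome in an exome."""
    return make_capture_design(26, 20, 200, seed=13)


@pytest.fixture(scope="session")
def null_cohort(design4):
    """Event-free mixed-sex cohort at the default depth regime."""
    return simulate_counts(design4, 12, mean_depth=62, dispersion=0.01, seed=5,
                           sexes=["M"] * 6 + ["F"] * 6)


def enumerate_best_path(log_emissions: np.ndarray, q: float, L: float):
    """Exhaustive maximum-likelihood path search over all 3^W state paths.

    Independent of the Viterbi recursion: scores every path by direct
    summation (vectorised over the full path enumeration).  Returns
    (best copy-number path, best log-probability, is_unique).
    """
    log_pi, log_T = hmm_log_params(q, L)
    W = log_emissions.shape[0]
    paths = np.array(list(itertools.product(range(3), repeat=W)), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        scores = log_pi[paths[:, 0]] + log_emissions[0, paths[:, 0]]
        for w in range(1, W):
            scores = scores + log_T[paths[:, w - 1], paths[:, w]] \
                + log_emissions[w, paths[:, w]]
    best = int(np.argmax(scores))
    best_score = scores[best]
    unique = int((scores >= best_score - 1e-12).sum()) == 1
    states = np.array([1, 2, 3], dtype=np.int8)
    return states[paths[best]], float(best_score), unique


def path_log_prob(path_cn: np.ndarray, log_emissions: np.ndarray, q: float, L: float):
    """Direct log-probability of one copy-number path."""
    log_pi, log_T = hmm_log_params(q, L)
    idx = np.asarray(path_cn) - 1
    lp = log_pi[idx[0]] + log_emissions[0, idx[0]]
    for w in range(1, len(idx)):
        lp += log_T[idx[w - 1], idx[w]] + log_emissions[w, idx[w]]
    return float(lp)
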