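import numpy as np
import pytest

import prizeforest as pf


@pytest.fixture(scope="session")
def default_cfg() -> pf.SynthConfig:
    """The default synthetic study configuration at seed 7."""
    return pf.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def planted_counts(default_cfg):
    """Count matrix + truth labels for the planted-DE study (seed 7)."""
    return pf.make_counts(default_cfg)


@pytest.fixture(scope="session")
def planted_interactome(default_cfg):
    """(interactome, module_nodes, prized_module_nodes) for seed 7."""
    return pf.make_interactome(default_cfg)


def bh_oracle(pvals):
    """From-definition Benjamini-Hochberg adjusted p-values.

    q_(i) = min over j >= i of p_(j) * m / j, computed on the sorted vector
    and mapped back to the original order.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
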