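import numpy as np
import pandas as pd
import pytest

from spikegraph import reference_data


def adj_from_edges(n, edges, labels=None):
    """Small labelled adjacency builder used across test modules."""
    labels = list(labels) if labels is not None else list(range(n))
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[labels.index(i) if labels != list(range(n)) else i,
          labels.index(j) if labels != list(range(n)) else j] = 1
    return pd.DataFrame(a, index=labels, columns=labels)


@pytest.fixture(scope="session")
def rate_table_published():
    return reference_data.firing_rate_table()


@pytest.fixture(scope="session")
def retained_rates(rate_table_published):
    """Rates restricted to the 29 channels kept by the outlier screen."""
    return rate_table_published.drop(index=[4, 5, 29])
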