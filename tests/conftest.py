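"""Shared fixtures.

The catalogue searches are expensive (the 4-reaction type-II sweep takes a
couple of minutes), so they run once per session and are shared between the
tests that interrogate them.
"""

import pytest

from turingmin.search import SearchConfig, find_minimal_schemes


@pytest.fixture(scope="session")
def typeI_search():
    """Full search over 3-reaction classes for type-I instability."""
    return find_minimal_schemes(SearchConfig(n_reactions=3, pattern_type="I"))


@pytest.fixture(scope="session")
def typeII_search():
    """Full search over 4-reaction classes for type-II instability."""
    return find_minimal_schemes(SearchConfig(n_reactions=4, pattern_type="II"))
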