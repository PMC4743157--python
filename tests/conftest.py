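import pytest

from termclouds.enrich import EnrichedTerm
from termclouds.synthetic import make_annotation


def make_term(
    term_id: str,
    p: float = 0.01,
    size: int = 100,
    name: str | None = None,
    source: str = "BP",
    p_raw: float | None = None,
) -> EnrichedTerm:
    """Build a minimal enrichment record for filter/cloud tests."""
    return EnrichedTerm(
        term_id=term_id,
        term_name=name or term_id,
        source=source,
        N=10000, K=size, n=200, k=min(size, 20),
        p_raw=p if p_raw is None else p_raw,
        p_adj=p,
    )


@pytest.fixture(scope="session")
def annotation():
    """A mid-size synthetic annotation shared across tests."""
    return make_annotation(n_terms=120, n_genes=3000, depth=3, seed=11)
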