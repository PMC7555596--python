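import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from leadergene import ScoreDist, TierSpec, generate_network

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_network():
    """Three panel genes: two supra-tau edges (0.95, 0.91) and one weak (0.50)."""
    g = nx.Graph()
    g.add_edge("A", "B", score=0.95)
    g.add_edge("B", "C", score=0.91)
    g.add_edge("A", "C", score=0.50)
    return g


def crisp_tiers():
    """Tiers meeting the stated separation conditions for recovery tests.

    Three disconnected cliques with supra-tau scores and a sub-tau orphan
    block.  Tier mean WNLs ~10.45 / 2.79 / 1.81: leader mean >= 3x the next
    tier, within-tier spreads (0.01-0.02) far under 20% of the inter-tier
    gaps.  Score concentrations are chosen so the within-cluster dispersion
    is comparable across tiers — when one tier holds nearly all the
    within-SS, the gap statistic's 1-SE rule over-splits that tier (see the
    methods note).
    """
    return [
        TierSpec("leader", 12, intra_p=1.0, score_high=ScoreDist(0.95, 150.0)),
        TierSpec("t2", 4, intra_p=1.0, score_high=ScoreDist(0.93, 11.0)),
        TierSpec("t3", 3, intra_p=1.0, score_high=ScoreDist(0.905, 4.0)),
        TierSpec("orphan", 10, intra_p=0.2, score_low=ScoreDist(0.4, 8.0)),
    ]


@pytest.fixture
def crisp_truth():
    return generate_network(crisp_tiers(), tau=0.9, seed=11)
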