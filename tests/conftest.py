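import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

KGML_TWO_REACTIONS = """\
<pathway name="path:syn00010" title="toy metabolism">
 <entry id="1" name="gene:G1" type="gene" reaction="rn:R1"/>
 <entry id="2" name="gene:G2 gene:G3" type="gene" reaction="rn:R2"/>
 <entry id="3" name="cpd:M1" type="compound"/>
 <reaction id="10" name="rn:R1" type="irreversible">
  <substrate id="4" name="cpd:M0"/>
  <product id="3" name="cpd:M1"/>
 </reaction>
 <reaction id="11" name="rn:R2" type="reversible">
  <substrate id="3" name="cpd:M1"/>
  <product id="5" name="cpd:M2"/>
 </reaction>
</pathway>
"""

KGML_SIGNALING = """\
<pathway name="path:syn04010" title="toy signaling">
 <entry id="1" name="gene:GA" type="gene"/>
 <entry id="2" name="gene:GB" type="gene"/>
 <relation entry1="1" entry2="2" type="PPrel"/>
</pathway>
"""


@pytest.fixture
def kgml_two_reactions():
    return KGML_TWO_REACTIONS


@pytest.fixture
def kgml_signaling():
    return KGML_SIGNALING


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connected_net(n_nodes, rng, extra_edge_prob=0.3, pathway_id="t"):
    """Small random connected network for oracle comparisons (test-local
    generator, independent of the package's fixture module)."""
    import pathwave as pw

    a = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        j = order[int(rng.integers(0, i))]
        a[order[i], j] = a[j, order[i]] = 1
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if not a[i, j] and rng.random() < extra_edge_prob:
                a[i, j] = a[j, i] = 1
    nodes = [f"{pathway_id}{i}" for i in range(n_nodes)]
    return pw.PathwayNetwork(
        pathway_id=pathway_id, nodes=nodes,
        node_genes={v: frozenset() for v in nodes}, adjacency=a,
    )
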