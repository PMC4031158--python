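"""Pathway preprocessing: network construction plus grid arrangement.

This step is independent of expression data and needs to run only once
per pathway collection; the result can be serialized (see `pathwave.io`)
and reused across analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .embedding import DEFAULT_EXACT_LIMIT, GridEmbedding, embed
from .network import PathwayNetwork

__all__ = ["PreprocessedPathway", "preprocess_networks"]


@dataclass
class PreprocessedPathway:
    """A pathway network together with its lattice-grid embedding."""

    network: PathwayNetwork
    embedding: GridEmbedding

    @property
    def pathway_id(self) -> str:
        return self.network.pathway_id

    @property
    def title(self) -> str:
        return self.network.title


def preprocess_networks(
    networks: list[PathwayNetwork],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    seed: int = 0,
    time_limit: float | None = None,
) -> list[PreprocessedPathway]:
    """Arrange each network on its near-square grid (exact up to
    ``exact_limit`` nodes, simulated annealing beyond)."""
    return [
        PreprocessedPathway(
            network=net,
            embedding=embed(net, exact_limit=exact_limit, seed=seed, time_limit=time_limit),
        )
        for net in networks
    ]
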