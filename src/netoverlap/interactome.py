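"""+1 interactomes: a seed gene set plus all first-degree interactors."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from netoverlap.data_io import GeneList, InteractionNetwork
from netoverlap.errors import EmptyInteractomeError

__all__ = ["PlusOneInteractome", "plus_one", "overlap"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlusOneInteractome:
    """A seed set together with every gene adjacent to at least one seed.

    Seeds are always members of their own +1 interactome; ``size`` counts
    member genes, not interactions.  Input seeds absent from the network are
    excluded and reported in ``dropped_seeds``.
    """

    seeds: frozenset[str]
    members: frozenset[str]
    dropped_seeds: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)

    def __post_init__(self):
        if not self.seeds <= self.members:
            raise ValueError("seeds must be a subset of members")


def plus_one(network: InteractionNetwork, seeds: GeneList | Iterable[str]) -> PlusOneInteractome:
    """Build the +1 interactome of ``seeds`` on ``network``.

    Raises :class:`EmptyInteractomeError` when no seed is present in the
    network (an empty interactome is undefined downstream).
    """
    seed_symbols = [s.strip().upper() for s in seeds]
    present = [s for s in seed_symbols if s in network]
    dropped = tuple(s for s in seed_symbols if s not in network)
    if dropped:
        logger.info("plus_one: dropped %d seed(s) absent from the network", len(dropped))
    if not present:
        raise EmptyInteractomeError("no seed gene is present in the network")
    members: set[str] = set()
    for s in present:
        members |= network.plus_one_members(s)
    return PlusOneInteractome(
        seeds=frozenset(present), members=frozenset(members), dropped_seeds=dropped
    )


def overlap(a: PlusOneInteractome, b: PlusOneInteractome) -> int:
    """Number of genes common to both member sets."""
    return len(a.members & b.members)
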